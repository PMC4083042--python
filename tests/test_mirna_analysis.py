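"""Folding engine vs exhaustive enumeration, miRNA counting rules,
family logic and novel hairpin discovery."""

import numpy as np
import pytest

from smrnapipe.io_formats import CollapsedRead, SmallRNALibrary
from smrnapipe.mirna_analysis import (
    MIN_LOOP,
    PAIR_SCORES,
    HairpinCriteria,
    MiRNACatalogEntry,
    discover_novel,
    family_divergence,
    fold_rna,
    pair_table,
    parse_family,
    quantify_known,
)


def enumerate_best_score(seq: str) -> float:
    """Independent oracle: enumerate every legal nested structure."""

    def structures(i, j):
        if i >= j:
            yield frozenset()
            return
        for s in structures(i + 1, j):
            yield s
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in PAIR_SCORES:
                for s1 in structures(i + 1, k - 1):
                    for s2 in structures(k + 1, j):
                        yield s1 | s2 | {(i, k)}

    return max(
        (sum(PAIR_SCORES[(seq[i], seq[j])] for i, j in s) for s in structures(0, len(seq) - 1)),
        default=0,
    )


class TestFoldRNA:
    def test_gc_hairpin_core(self):
        structure, score = fold_rna("GGGAAACCC", enforce_length=False)
        assert score == -9.0
        assert structure == "(((...)))"
        assert enumerate_best_score("GGGAAACCC") == 9

    def test_homopolymer_has_no_pairs(self):
        structure, score = fold_rna("A" * 60)
        assert score == 0.0
        assert structure == "." * 60

    def test_u_and_lowercase_accepted(self):
        s1 = fold_rna("gggaaaccc", enforce_length=False)
        s2 = fold_rna("GGGAAACCC", enforce_length=False)
        s3 = fold_rna("GGGAAACCCU" [:9], enforce_length=False)
        assert s1 == s2 == s3

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            fold_rna("ACGT" * 5)  # 20 nt < 40
        with pytest.raises(ValueError):
            fold_rna("ACGT" * 200)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        for _ in range(60):
            n = int(rng.integers(5, 15))
            seq = "".join(rng.choice(bases, size=n))
            _, score = fold_rna(seq, enforce_length=False)
            assert -score == enumerate_best_score(seq), seq

    def test_traceback_structure_is_consistent(self):
        """The reported structure is balanced, respects the minimum loop,
        uses only legal pairs, and its pair scores sum to the optimum."""
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            seq = "".join(rng.choice(bases, size=80))
            structure, score = fold_rna(seq)
            table = pair_table(structure)
            total = 0
            for i, j in table.items():
                if i < j:
                    assert j - i - 1 >= MIN_LOOP
                    assert (seq[i], seq[j]) in PAIR_SCORES
                    total += PAIR_SCORES[(seq[i], seq[j])]
            assert total == -score

    def test_planted_hairpin_pairs_recovered(self, small_study):
        """A designed inverted repeat folds with >= arm_length - mismatches pairs
        between its arms."""
        planted = small_study.config.planted_mirna_spec[0]
        chrom = {g.name: g.seq for g in small_study.genome}[planted.locus.chrom]
        hairpin = chrom[planted.locus.start : planted.locus.end]
        structure, _ = fold_rna(hairpin, enforce_length=False)
        table = pair_table(structure)
        arm = range(0, 21)  # mature arm of the designed hairpin
        cross = sum(1 for i in arm if i in table and table[i] >= 33)
        assert cross >= 21 - 2


def make_library(counts: dict[str, int]) -> SmallRNALibrary:
    reads = [CollapsedRead(s, c) for s, c in sorted(counts.items())]
    lib = SmallRNALibrary(reads)
    return lib


MATURE_A = "ACGGTTCAATGCCTAGCTAGA"
MATURE_B = "TTGACCGGATTCACGGGATCA"
MATURE_C = "GGATCCATTGCACGTTAGACC"


def pad(lib_counts, total):
    """Pad a library to a fixed clean-read total with an inert sequence."""
    counts = dict(lib_counts)
    counts["TGCA" * 6] = total - sum(counts.values())
    return make_library(counts)


class TestQuantifyKnown:
    catalog = [
        MiRNACatalogEntry("osa-miR901", MATURE_A),
        MiRNACatalogEntry("osa-miR395p", MATURE_B),
        MiRNACatalogEntry("osa-miR395s", MATURE_C),
    ]

    def test_planted_ratios_classified(self):
        mut = pad({MATURE_A: 900, MATURE_B: 50, MATURE_C: 420}, 100_000)
        wt = pad({MATURE_A: 100, MATURE_B: 280, MATURE_C: 100}, 100_000)
        q = quantify_known(mut, wt, self.catalog).set_index("name")
        assert q.loc["osa-miR901", "pattern"] == "up"
        assert q.loc["osa-miR395p", "pattern"] == "down"
        assert q.loc["osa-miR395s", "pattern"] == "up"
        assert q.loc["osa-miR901", "ratio"] > 8

    def test_swapping_genotypes_maps_up_down(self):
        mut = pad({MATURE_A: 900, MATURE_B: 50, MATURE_C: 100}, 100_000)
        wt = pad({MATURE_A: 100, MATURE_B: 280, MATURE_C: 101}, 100_000)
        fwd = quantify_known(mut, wt, self.catalog).set_index("name")["pattern"]
        rev = quantify_known(wt, mut, self.catalog).set_index("name")["pattern"]
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert all(rev[n] == swap[fwd[n]] for n in fwd.index)

    def test_pattern_partition(self):
        mut = pad({MATURE_A: 900, MATURE_B: 50}, 100_000)
        wt = pad({MATURE_A: 100, MATURE_B: 280}, 100_000)
        q = quantify_known(mut, wt, self.catalog)
        assert set(q["pattern"]) <= {"up", "down", "unchanged"}
        assert len(q) == len(self.catalog)

    def test_equal_abundance_is_unchanged(self):
        mut = pad({MATURE_A: 200}, 100_000)
        wt = pad({MATURE_A: 200}, 100_000)
        q = quantify_known(mut, wt, self.catalog).set_index("name")
        assert q.loc["osa-miR901", "pattern"] == "unchanged"
        assert q.loc["osa-miR395p", "pattern"] == "unchanged"  # zero counts

    def test_isomir_3prime_rule(self):
        variants = {
            MATURE_A[:-2]: 10,       # trimmed by 2: counts
            MATURE_A + "GT": 5,      # extended by 2: counts
            MATURE_A[:-3]: 7,        # trimmed by 3: ignored
            "T" + MATURE_A[1:]: 3,   # 5' mismatch: ignored
        }
        mut = pad(variants, 10_000)
        wt = pad({MATURE_A: 1}, 10_000)
        q = quantify_known(mut, wt, self.catalog).set_index("name")
        assert q.loc["osa-miR901", "count_mut"] == 15

    def test_shared_mature_counted_toward_every_name(self):
        catalog = [
            MiRNACatalogEntry("miR1a", MATURE_A),
            MiRNACatalogEntry("miR1b", MATURE_A),
        ]
        mut = pad({MATURE_A: 50}, 10_000)
        wt = pad({MATURE_A: 50}, 10_000)
        q = quantify_known(mut, wt, catalog).set_index("name")
        assert q.loc["miR1a", "count_mut"] == q.loc["miR1b", "count_mut"] == 50
        assert q["shared_mature"].all()

    def test_ttest_path_with_replicate_libraries(self):
        muts = [pad({MATURE_A: c}, 10_000) for c in (400, 420, 380)]
        wts = [pad({MATURE_A: c}, 10_000) for c in (100, 110, 90)]
        q = quantify_known(muts, wts, self.catalog).set_index("name")
        assert q.loc["osa-miR901", "pattern"] == "up"
        assert q.loc["osa-miR901", "p_value"] < 0.05


class TestFamilies:
    def test_family_parsing(self):
        assert parse_family("osa-miR395p") == "miR395"
        assert parse_family("osa-MIR168a") == "miR168"
        assert parse_family("weird-name") == "weird-name"

    def _quants(self, patterns):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [f"osa-miR9{i}{c}" for i, (fam, c, _) in enumerate(patterns)],
                "family": [fam for fam, _, _ in patterns],
                "pattern": [p for _, _, p in patterns],
            }
        )

    def test_opposite_directions_reported(self):
        q = self._quants([("miR395", "p", "down"), ("miR395", "s", "up")])
        out = family_divergence(q)
        assert list(out["family"]) == ["miR395"]

    def test_up_plus_unchanged_not_reported(self):
        q = self._quants([("miR395", "p", "up"), ("miR395", "s", "unchanged")])
        assert family_divergence(q).empty

    def test_singletons_never_reported(self):
        q = self._quants([("miR1", "a", "up")])
        assert family_divergence(q).empty


class TestDiscoverNovel:
    def test_planted_hairpins_recovered_with_family_and_guide(
        self, small_study, small_candidates
    ):
        candidates = small_candidates
        truth = small_study.truth.novel
        matched = []
        for _, t in truth.iterrows():
            hit = [
                c
                for c in candidates
                if c.locus.chrom == t["chrom"]
                and c.locus.start < t["end"]
                and c.locus.end > t["start"]
            ]
            assert hit, f"planted locus {t['start']} not recovered"
            matched.append(hit[0])
        families = {c.family for c in matched}
        assert len(families) == 1  # identical mature -> one family of 3 loci
        assert all(c.guide_arm == "5p" for c in matched)
        assert all(c.mature_seq == truth["mature_seq"].iloc[0] for c in matched)
        assert all(c.reads_5p > c.reads_3p for c in matched)

    def test_no_candidate_overlaps_annotated_smrna_loci(
        self, small_study, small_candidates
    ):
        candidates = small_candidates
        blocked = [
            r.interval
            for r in small_study.annotation
            if r.feature_class
            in ("known_miRNA_locus", "rRNA", "tRNA", "snoRNA", "snRNA")
        ]
        for c in candidates:
            for iv in blocked:
                assert not c.locus.overlaps(iv), (
                    f"candidate at {c.locus} overlaps annotated locus {iv}"
                )

    def test_empty_result_allowed(self):
        from conftest import random_genome

        rng = np.random.default_rng(2)
        genome = random_genome(rng, [2_000])
        assert discover_novel([], [], genome, HairpinCriteria()) == []
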