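"""Bisulfite alignment vs a brute-force DP oracle, context classification
vs a regex oracle, and summary/difference semantics."""

import re

import numpy as np
import pytest

from smrnapipe.io_formats import revcomp
from smrnapipe.methylation import (
    GAP_COST,
    MISMATCH_COST,
    align_clone,
    call_sites,
    classify_context,
    diff_genotypes,
    lollipop_report,
    summarize_locus,
)


def oracle_cost(ref: str, clone: str) -> float:
    """Brute-force global alignment cost under the bisulfite rule."""

    def sub(a, b):
        if a == b or (a == "C" and b == "T"):
            return 0.0
        return MISMATCH_COST

    n, m = len(ref), len(clone)
    D = np.zeros((n + 1, m + 1))
    D[:, 0] = np.arange(n + 1) * GAP_COST
    D[0, :] = np.arange(m + 1) * GAP_COST
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + sub(ref[i - 1], clone[j - 1]),
                D[i - 1, j] + GAP_COST,
                D[i, j - 1] + GAP_COST,
            )
    return D[n, m]


class TestAlignClone:
    def test_identical_clone_costs_zero(self):
        ref = "ACGTCAGGTC" * 3
        aln = align_clone(ref, ref)
        assert aln.cost == 0.0 and aln.accepted
        assert aln.ref_to_clone == list(ref)

    def test_fully_converted_clone_costs_zero(self):
        ref = "ACGTCAGGTC" * 3
        clone = ref.replace("C", "T")
        aln = align_clone(clone, ref)
        assert aln.cost == 0.0 and aln.accepted and aln.identity == 1.0

    def test_single_mismatch_recorded_but_accepted(self):
        ref = "ACGTAAGGTC" * 4
        clone = ref[:5] + "C" + ref[6:]  # A -> C at position 5
        aln = align_clone(clone, ref)
        assert aln.cost == MISMATCH_COST and aln.accepted
        assert aln.identity == pytest.approx(1 - 1 / len(ref), abs=1e-6)

    def test_reverse_orientation_detected(self):
        ref = "ACGTTAGGCCAATCGGAT" * 3
        aln = align_clone(revcomp(ref), ref)
        assert aln.reversed_orientation and aln.accepted

    def test_low_identity_clone_rejected(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        ref = "".join(rng.choice(bases, size=60))
        clone = "".join(rng.choice(bases, size=60))
        aln = align_clone(clone, ref)
        assert not aln.accepted

    def test_length_bounds_rejected(self):
        ref = "ACGT" * 20
        assert not align_clone(ref[:30], ref).accepted

    def test_score_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        for _ in range(25):
            n = int(rng.integers(15, 30))
            ref = "".join(rng.choice(bases, size=n))
            clone = list(ref)
            for _ in range(rng.integers(0, 4)):  # substitutions
                clone[rng.integers(n)] = bases[rng.integers(4)]
            if rng.integers(2) and n > 16:  # one deletion
                del clone[rng.integers(n - 1)]
            clone = "".join(clone)
            aln = align_clone(clone, ref, min_identity=0.0)
            oriented = revcomp(clone) if aln.reversed_orientation else clone
            assert aln.cost == oracle_cost(ref, oriented), (ref, clone)


class TestContext:
    def test_cg_example(self):
        sites = call_sites([align_clone("ACGT", "ACGT")], "ACGT")
        assert len(sites) == 1
        assert sites[0].position == 1 and sites[0].context == "CG"
        assert sites[0].states["clone"] == "methylated"

    def test_ccagg_contexts(self):
        # first C: next is C (not G), then A (not G) -> CHH
        # second C: next is A, then G -> CHG
        assert classify_context("CCAGG", 0) == "CHH"
        assert classify_context("CCAGG", 1) == "CHG"

    def test_end_of_locus_context_undefined(self):
        assert classify_context("AAC", 2) is None  # no base after the C
        assert classify_context("AACA", 2) is None  # CHG/CHH undecidable

    def test_clone_t_is_unmethylated(self):
        ref = "ACGTA"
        sites = call_sites([align_clone("ATGTA", ref)], ref)
        assert sites[0].states["clone"] == "unmethylated"

    def test_context_partition_matches_regex_oracle(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            ref = "".join(rng.choice(bases, size=60))
            by_regex = {}
            for ctx, pat in (
                ("CG", r"C(?=G)"),
                ("CHG", r"C(?=[ACT]G)"),
                ("CHH", r"C(?=[ACT][ACT])"),
            ):
                for m in re.finditer(pat, ref):
                    by_regex[m.start()] = ctx
            mine = {
                i: classify_context(ref, i)
                for i in range(len(ref))
                if ref[i] == "C" and classify_context(ref, i) is not None
            }
            assert mine == by_regex
            # partition: every in-bounds C gets exactly one context
            in_bounds = [i for i in range(len(ref) - 2) if ref[i] == "C"]
            assert set(mine) >= set(in_bounds)


class TestSummaries:
    def test_fully_methylated_is_100(self):
        ref = "ACGACGACGT" * 3
        alns = [align_clone(ref, ref, clone_id=f"c{i}") for i in range(5)]
        summ = summarize_locus(call_sites(alns, ref), "mut")
        assert summ.percent("CG") == 100.0

    def test_fully_converted_is_0(self):
        ref = "ACGACGACGT" * 3
        clone = ref.replace("C", "T")
        alns = [align_clone(clone, ref, clone_id=f"c{i}") for i in range(5)]
        summ = summarize_locus(call_sites(alns, ref), "wt")
        assert summ.percent("CG") == 0.0

    def test_missing_context_omitted(self):
        ref = "ACGTAG"  # contains a CG site but no CHH
        summ = summarize_locus(call_sites([align_clone(ref, ref)], ref), "mut")
        assert summ.percent("CHH") is None

    def test_diff_delta_points(self):
        ref = "ACGACGACGA"  # CG sites only (in-bounds)
        meth = align_clone(ref, ref, clone_id="m")
        conv = align_clone(ref.replace("C", "T"), ref, clone_id="u")
        s_mut = summarize_locus(call_sites([meth, conv], ref), "mut")  # 50%
        s_wt = summarize_locus(call_sites([meth], ref), "wt")  # 100%
        diff = diff_genotypes(s_mut, s_wt).set_index("context")
        assert diff.loc["CG", "delta_points"] == pytest.approx(-50.0)

    def test_equal_percents_delta_zero(self):
        ref = "ACGACGACGA"
        aln = align_clone(ref, ref)
        s1 = summarize_locus(call_sites([aln], ref), "mut")
        s2 = summarize_locus(call_sites([aln], ref), "wt")
        diff = diff_genotypes(s1, s2).set_index("context")
        assert diff.loc["CG", "delta_points"] == 0.0

    def test_planted_difference_significant(self, small_study):
        """0.7 vs 0.2 CHH at 12 clones on a 300 bp locus is detected."""
        from smrnapipe.methylation import align_clone, call_sites, summarize_locus

        entry = small_study.bisulfite["TEb_5p"]
        summaries = {}
        for genotype in ("mut", "wt"):
            alns = [
                align_clone(seq, entry["ref"], clone_id=name)
                for name, seq in entry["clones"][genotype]
            ]
            summaries[genotype] = summarize_locus(
                call_sites(alns, entry["ref"]), genotype
            )
        diff = diff_genotypes(summaries["mut"], summaries["wt"]).set_index("context")
        assert diff.loc["CHH", "delta_points"] > 20
        assert diff.loc["CHH", "p_value"] < 0.01

    def test_lollipop_report_layout(self, tmp_path):
        ref = "ACGTCAGTCA"
        aln = align_clone(ref, ref, clone_id="c1")
        path = tmp_path / "lolli.txt"
        lollipop_report(call_sites([aln], ref), path)
        text = path.read_text()
        assert "c1" in text and "●" in text
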