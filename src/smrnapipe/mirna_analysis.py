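"""Known-miRNA quantification, family divergence, and novel miRNA discovery
by stem-loop structure prediction with 5p/3p guide-strand assignment.

Folding model
-------------
:func:`fold_rna` maximizes a simple additive base-pair score (GC 3, AU 2,
GU 1 model units; Watson-Crick plus wobble pairs; minimum hairpin loop of
3 unpaired bases) by Nussinov-style dynamic programming with a
deterministic traceback.  The negated optimum is reported as
``fold_score`` so that lower means more stable; reports label the column
"mfe" but the units are those of this scoring model, not kcal/mol.  The
model is deliberately self-contained and exactly checkable against
exhaustive enumeration — full nearest-neighbour thermodynamics is out of
scope.

Counting model
--------------
A library read counts toward a catalogue entry if it matches the mature
sequence exactly or as a 3'-end isomiR (trimmed or extended by at most
2 nt, 5' end identical).  Abundances are RPM on clean-read totals.  With
one library per genotype, significance comes from a two-sided binomial
test of the mutant read count against the expectation under equal
abundance given both library totals ("count-test"); with two or more
libraries per genotype a Welch t-test on per-library RPMs is used
instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import (
    AnnotationRecord,
    GenomeSequence,
    Interval,
    SmallRNALibrary,
    read_fasta,
    revcomp,
)
from .read_mapping import ReadPlacement

__all__ = [
    "MiRNACatalogEntry",
    "HairpinCandidate",
    "HairpinCriteria",
    "read_catalog",
    "parse_family",
    "quantify_known",
    "family_divergence",
    "fold_rna",
    "discover_novel",
    "PAIR_SCORES",
    "MIN_LOOP",
]

#: pair scores in model units (DNA alphabet after U->T)
PAIR_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
#: minimum number of unpaired bases closing a hairpin loop
MIN_LOOP = 3

_FAMILY_RE = re.compile(r"mir-?(\d+)", re.IGNORECASE)


def parse_family(name: str) -> str:
    """Family stem parsed from a miRNA name, e.g. ``osa-miR395p`` -> ``miR395``."""
    m = _FAMILY_RE.search(name)
    return f"miR{m.group(1)}" if m else name


@dataclass(frozen=True)
class MiRNACatalogEntry:
    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        if not (19 <= len(self.mature_seq) <= 25):
            raise ValueError(
                f"mature sequence of {self.name} outside 19-25 nt: "
                f"{len(self.mature_seq)} nt"
            )

    @property
    def family(self) -> str:
        return parse_family(self.name)


def read_catalog(path, fmt: str = "fasta") -> list[MiRNACatalogEntry]:
    """Load a mature-miRNA catalogue from FASTA or two-column TSV."""
    if fmt == "fasta":
        entries = [MiRNACatalogEntry(n, s) for n, s in read_fasta(path)]
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        entries = [
            MiRNACatalogEntry(r["name"], str(r["mature_seq"]).upper().replace("U", "T"))
            for _, r in df.iterrows()
        ]
    else:
        raise ValueError(f"unknown catalogue format {fmt!r}")
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate names in miRNA catalogue")
    return entries


# ---------------------------------------------------------------------------
# Known-miRNA quantification
# ---------------------------------------------------------------------------

_KEY_LEN = 16  # shorter than any mature minus the 2 nt trimming allowance


def _is_isomir(read_seq: str, mature: str, max_shift: int = 2) -> bool:
    """3' trimmed/extended by <= max_shift nt, 5' end identical."""
    if abs(len(read_seq) - len(mature)) > max_shift:
        return False
    short, long_ = sorted((read_seq, mature), key=len)
    return long_.startswith(short)


def _count_matches(
    library: SmallRNALibrary, catalog: Sequence[MiRNACatalogEntry]
) -> dict[str, int]:
    by_key: dict[str, list[MiRNACatalogEntry]] = {}
    for entry in catalog:
        by_key.setdefault(entry.mature_seq[:_KEY_LEN], []).append(entry)
    counts = {e.name: 0 for e in catalog}
    for read in library:
        if read.length < _KEY_LEN:
            continue
        for entry in by_key.get(read.seq[:_KEY_LEN], ()):
            if _is_isomir(read.seq, entry.mature_seq):
                counts[entry.name] += read.count
    return counts


def _as_library_list(libs) -> list[SmallRNALibrary]:
    return list(libs) if isinstance(libs, (list, tuple)) else [libs]


def quantify_known(
    libs_mut,
    libs_wt,
    catalog: Sequence[MiRNACatalogEntry],
    alpha: float = 0.05,
    ratio_cutoff: float = 2.0,
    pseudocount_rpm: float = 0.5,
) -> pd.DataFrame:
    """Quantify catalogue miRNAs in mutant vs wild-type libraries.

    Returns a DataFrame with columns ``name, family, count_mut, count_wt,
    rpm_mut, rpm_wt, ratio, p_value, pattern, shared_mature``.  Pattern is
    ``up`` iff ratio >= ratio_cutoff and significant, ``down`` iff
    ratio <= 1/ratio_cutoff and significant, else ``unchanged``.
    Duplicate mature sequences are counted toward every matching name and
    flagged in ``shared_mature``.
    """
    libs_mut = _as_library_list(libs_mut)
    libs_wt = _as_library_list(libs_wt)
    mut_counts = [_count_matches(lib, catalog) for lib in libs_mut]
    wt_counts = [_count_matches(lib, catalog) for lib in libs_wt]
    mut_totals = [lib.total_reads for lib in libs_mut]
    wt_totals = [lib.total_reads for lib in libs_wt]
    seq_owner: dict[str, list[str]] = {}
    for e in catalog:
        seq_owner.setdefault(e.mature_seq, []).append(e.name)
    ttest_path = len(libs_mut) >= 2 and len(libs_wt) >= 2

    rows = []
    for entry in catalog:
        k_mut = [c[entry.name] for c in mut_counts]
        k_wt = [c[entry.name] for c in wt_counts]
        rpm_mut_l = [k * 1e6 / t for k, t in zip(k_mut, mut_totals)]
        rpm_wt_l = [k * 1e6 / t for k, t in zip(k_wt, wt_totals)]
        rpm_mut = float(np.median(rpm_mut_l))
        rpm_wt = float(np.median(rpm_wt_l))
        ratio = (rpm_mut + pseudocount_rpm) / (rpm_wt + pseudocount_rpm)
        if ttest_path:
            p = stats.ttest_ind(rpm_mut_l, rpm_wt_l, equal_var=False).pvalue
            p = 1.0 if np.isnan(p) else float(p)
        else:
            total = k_mut[0] + k_wt[0]
            if total == 0:
                p = 1.0
            else:
                p0 = mut_totals[0] / (mut_totals[0] + wt_totals[0])
                p = stats.binomtest(k_mut[0], total, p0).pvalue
        if ratio >= ratio_cutoff and p < alpha:
            pattern = "up"
        elif ratio <= 1.0 / ratio_cutoff and p < alpha:
            pattern = "down"
        else:
            pattern = "unchanged"
        rows.append(
            {
                "name": entry.name,
                "family": entry.family,
                "count_mut": sum(k_mut),
                "count_wt": sum(k_wt),
                "rpm_mut": rpm_mut,
                "rpm_wt": rpm_wt,
                "ratio": ratio,
                "p_value": p,
                "pattern": pattern,
                "shared_mature": len(seq_owner[entry.mature_seq]) > 1,
            }
        )
    return pd.DataFrame(rows)


def family_divergence(quants: pd.DataFrame) -> pd.DataFrame:
    """Families (>= 2 members) with at least one member up and one down."""
    rows = []
    for family, sub in quants.groupby("family", sort=True):
        if len(sub) < 2:
            continue
        up = sub.loc[sub["pattern"] == "up", "name"].tolist()
        down = sub.loc[sub["pattern"] == "down", "name"].tolist()
        if up and down:
            rows.append(
                {
                    "family": family,
                    "n_members": len(sub),
                    "members_up": ",".join(sorted(up)),
                    "members_down": ",".join(sorted(down)),
                }
            )
    return pd.DataFrame(rows, columns=["family", "n_members", "members_up", "members_down"])


# ---------------------------------------------------------------------------
# Secondary-structure prediction
# ---------------------------------------------------------------------------

def _pair_score_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            P[i, j] = PAIR_SCORES.get((seq[i], seq[j]), -np.inf)
    return P


def _nussinov_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    P = _pair_score_matrix(seq)
    N = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.maximum(N[i + 1, j], N[i, j - 1])
        diag = N[i + 1, j - 1] + P[i, j]
        best = np.maximum(best, np.where(np.isfinite(diag), diag, -1.0))
        for m in range(1, span):
            np.maximum(best, N[i, i + m] + N[i + m + 1, j], out=best)
        N[i, j] = best
    return N


def _traceback(seq: str, N: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic traceback: prefer pairing (i, j), then leaving i or j
    unpaired, then the bifurcation with the smallest split point."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(seq) - 1)]
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = N[i, j]
        if target <= eps:
            continue
        ps = PAIR_SCORES.get((seq[i], seq[j]))
        if ps is not None and abs(N[i + 1, j - 1] + ps - target) < eps:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if abs(N[i + 1, j] - target) < eps:
            stack.append((i + 1, j))
            continue
        if abs(N[i, j - 1] - target) < eps:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if abs(N[i, k] + N[k + 1, j] - target) < eps:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - recurrence guarantees a branch matches
            raise RuntimeError("traceback failed")
    return pairs


def fold_rna(seq: str, enforce_length: bool = True) -> tuple[str, float]:
    """Predict a secondary structure for ``seq`` (DNA or RNA alphabet).

    Returns ``(dot_bracket, fold_score)`` where ``fold_score`` is the
    negated maximal pair score (model units; lower = more stable).  The
    standard precursor length range 40-400 nt is enforced unless
    ``enforce_length`` is disabled (as for the short-sequence exhaustive
    checks).
    """
    seq = seq.upper().replace("U", "T")
    if enforce_length and not (40 <= len(seq) <= 400):
        raise ValueError(f"sequence length {len(seq)} outside 40-400 nt")
    if len(seq) <= MIN_LOOP + 1:
        return "." * len(seq), 0.0
    N = _nussinov_matrix(seq)
    pairs = _traceback(seq, N)
    structure = ["."] * len(seq)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return "".join(structure), -float(N[0, len(seq) - 1]) + 0.0


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions)."""
    stack: list[int] = []
    table: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            table[i] = j
            table[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return table


# ---------------------------------------------------------------------------
# Novel miRNA discovery
# ---------------------------------------------------------------------------

@dataclass
class HairpinCriteria:
    """Acceptance criteria for novel hairpin candidates."""

    min_reads: int = 5            # summed copies in a seed stack
    seed_len_range: tuple[int, int] = (20, 24)
    window: int = 160             # precursor window folded around a seed
    n_offsets: int = 9            # mature placements tried across the window
    max_fold_score: float = -15.0  # model units
    max_unpaired_mature: int = 4
    max_partner_span_slack: int = 8   # bulge allowance on the star arm
    merge_distance: int = 160     # seeds closer than this are one locus


@dataclass
class HairpinCandidate:
    locus: Interval
    precursor_seq: str
    structure: str
    fold_score: float
    mature_arm: str
    mature_seq: str
    star_seq: str
    reads_5p: int
    reads_3p: int
    guide_arm: str
    family: str = ""
    stack_count: int = 0


def _collect_stacks(placements: Sequence[ReadPlacement], criteria: HairpinCriteria):
    """Seed stacks: reads sharing a 5' genomic position and strand."""
    lo, hi = criteria.seed_len_range
    stacks: dict[tuple[str, int, str], dict] = {}
    for placement in placements:
        if not (lo <= placement.read.length <= hi):
            continue
        for hit in placement.hits:
            five = hit.start if hit.strand != "-" else hit.end - 1
            key = (hit.chrom, five, hit.strand)
            entry = stacks.setdefault(
                key, {"count": 0, "best": None, "best_count": -1, "hit": None}
            )
            entry["count"] += placement.read.count
            if placement.read.count > entry["best_count"]:
                entry["best_count"] = placement.read.count
                entry["best"] = placement.read.seq
                entry["hit"] = hit
    out = [
        (key, entry)
        for key, entry in stacks.items()
        if entry["count"] >= criteria.min_reads
    ]
    # largest stacks first; ties broken genomically for determinism
    out.sort(key=lambda kv: (-kv[1]["count"], kv[0]))
    return out


def _blocked_regions(annotation: Sequence[AnnotationRecord]) -> dict[str, IntervalTree]:
    allowed = {"gene"}
    trees: dict[str, IntervalTree] = {}
    for rec in annotation:
        if rec.feature_class in allowed:
            continue
        iv = rec.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rec.feature_class)
    return trees


def _hit_tree(placements: Sequence[ReadPlacement]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for placement in placements:
        for hit in placement.hits:
            trees.setdefault(hit.chrom, IntervalTree()).addi(
                hit.start, hit.end, (hit.strand, placement.read.count)
            )
    return trees


def _evaluate_window(
    window_seq: str, m0: int, m1: int, criteria: HairpinCriteria
):
    """Fold one oriented precursor window; return structural summary or None.

    ``[m0, m1)`` is the mature span in oriented window coordinates.  The
    mature must sit on one arm of a stem: at most ``max_unpaired_mature``
    of its bases unpaired, no base paired within the mature itself, its
    partners forming one compact block separated from the mature by at
    least the minimum loop.
    """
    structure, score = fold_rna(window_seq, enforce_length=False)
    if score > criteria.max_fold_score:
        return None
    table = pair_table(structure)
    partners = [table[i] for i in range(m0, m1) if i in table]
    unpaired = (m1 - m0) - len(partners)
    if unpaired > criteria.max_unpaired_mature:
        return None
    if any(m0 <= p < m1 for p in partners):
        return None  # mature pairs with itself: not a clean arm
    pmin, pmax = min(partners), max(partners)
    if pmax - pmin + 1 > (m1 - m0) + criteria.max_partner_span_slack:
        return None  # partners scattered: not one stem
    # loop separation between the mature block and the partner block
    if pmin >= m1:
        gap = pmin - m1
    else:
        gap = m0 - pmax - 1
    if gap < MIN_LOOP:
        return None
    return structure, score, pmin, pmax


def discover_novel(
    placements: Sequence[ReadPlacement],
    annotation: Sequence[AnnotationRecord],
    genome: Sequence[GenomeSequence],
    criteria: HairpinCriteria | None = None,
) -> list[HairpinCandidate]:
    """Discover candidate novel miRNA hairpins from read stacks.

    Seeds are 20-24 nt read stacks of at least ``min_reads`` summed copies
    lying outside every annotated feature class except genes.  Around each
    seed, 160 nt windows are folded at 9 offsets on the seed's strand; a
    window is accepted when its structure passes the arm criteria of
    :func:`_evaluate_window`, the best-scoring accepted offset winning.
    The star is the partner block with the canonical 2 nt 3' offset; the
    guide arm is the arm carrying the majority of the read counts.
    Candidates sharing an identical mature sequence at different loci are
    grouped into one family.
    """
    criteria = criteria or HairpinCriteria()
    chrom_seqs = {g.name: g.seq for g in genome}
    blocked = _blocked_regions(annotation)
    hits = _hit_tree(placements)
    stacks = _collect_stacks(placements, criteria)

    processed: dict[str, list[int]] = {}
    candidates: list[HairpinCandidate] = []
    occupied: dict[str, IntervalTree] = {}

    for (chrom, five, strand), entry in stacks:
        near = processed.setdefault(chrom, [])
        if any(abs(five - p) < criteria.merge_distance for p in near):
            continue
        near.append(five)
        hit: Interval = entry["hit"]
        tree = blocked.get(chrom)
        if tree is not None and tree.overlap(hit.start, hit.end):
            continue
        cand = _best_candidate(
            chrom_seqs[chrom], chrom, hit, strand, entry, hits, criteria
        )
        if cand is None:
            continue
        occ = occupied.setdefault(chrom, IntervalTree())
        if occ.overlap(cand.locus.start, cand.locus.end):
            continue  # a larger stack already claimed this hairpin
        occ.addi(cand.locus.start, cand.locus.end)
        candidates.append(cand)

    candidates.sort(key=lambda c: (c.locus.chrom, c.locus.start))
    fam_ids: dict[str, str] = {}
    for cand in candidates:
        if cand.mature_seq not in fam_ids:
            fam_ids[cand.mature_seq] = f"novel-fam{len(fam_ids) + 1}"
        cand.family = fam_ids[cand.mature_seq]
    return candidates


def _best_candidate(
    chrom_seq: str,
    chrom: str,
    hit: Interval,
    strand: str,
    entry: dict,
    hit_trees: dict[str, IntervalTree],
    criteria: HairpinCriteria,
) -> HairpinCandidate | None:
    L = criteria.window
    stack_len = hit.end - hit.start
    best = None
    for t in range(criteria.n_offsets):
        shift = round(t * (L - stack_len) / (criteria.n_offsets - 1))
        ws = hit.start - (shift if strand != "-" else (L - stack_len - shift))
        ws = max(0, min(ws, len(chrom_seq) - L))
        window_seq = chrom_seq[ws : ws + L]
        if strand == "-":
            oriented = revcomp(window_seq)
            m1 = ws + L - hit.start
            m0 = ws + L - hit.end
        else:
            oriented = window_seq
            m0, m1 = hit.start - ws, hit.end - ws
        if m0 < 0 or m1 > L:
            continue
        result = _evaluate_window(oriented, m0, m1, criteria)
        if result is None:
            continue
        structure, score, pmin, pmax = result
        if best is None or score < best[0]:
            best = (score, ws, oriented, structure, m0, m1, pmin, pmax)
    if best is None:
        return None
    score, ws, oriented, structure, m0, m1, pmin, pmax = best
    L = criteria.window
    star0 = min(pmin + 2, L - 1)
    star1 = min(pmax + 3, L)
    star_seq = oriented[star0:star1]
    mature_arm = "5p" if m0 < pmin else "3p"
    # arm read totals from all placements inside the precursor window
    boundary_ori = (min(m1, pmax + 1) + max(m0, pmin)) / 2  # middle of the loop
    if strand == "-":
        boundary = ws + L - boundary_ori
    else:
        boundary = ws + boundary_ori
    reads_left = reads_right = 0
    tree = hit_trees.get(chrom)
    if tree is not None:
        for ov in tree.overlap(ws, ws + L):
            mid = (ov.begin + ov.end) / 2
            if mid < boundary:
                reads_left += ov.data[1]
            else:
                reads_right += ov.data[1]
    reads_5p, reads_3p = (
        (reads_left, reads_right) if strand != "-" else (reads_right, reads_left)
    )
    guide_arm = "5p" if reads_5p >= reads_3p else "3p"
    return HairpinCandidate(
        locus=Interval(chrom, ws, ws + L, strand),
        precursor_seq=oriented,
        structure=structure,
        fold_score=score,
        mature_arm=mature_arm,
        mature_seq=entry["best"],
        star_seq=star_seq,
        reads_5p=reads_5p,
        reads_3p=reads_3p,
        guide_arm=guide_arm,
        stack_count=entry["count"],
    )


def candidates_to_frame(candidates: Sequence[HairpinCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "family": c.family,
                "chrom": c.locus.chrom,
                "start": c.locus.start,
                "end": c.locus.end,
                "strand": c.locus.strand,
                "mfe": c.fold_score,
                "mature_arm": c.mature_arm,
                "mature_seq": c.mature_seq,
                "star_seq": c.star_seq,
                "reads_5p": c.reads_5p,
                "reads_3p": c.reads_3p,
                "guide_arm": c.guide_arm,
                "stack_count": c.stack_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "chrom", "start", "end", "strand", "mfe", "mature_arm",
            "mature_seq", "star_seq", "reads_5p", "reads_3p", "guide_arm",
            "stack_count",
        ],
    )


def write_structures(candidates: Sequence[HairpinCandidate], path) -> None:
    """Vienna-style layout: header, precursor sequence, dot-bracket line."""
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, 1):
            fh.write(
                f">candidate{i} {c.family} {c.locus.chrom}:{c.locus.start}-"
                f"{c.locus.end}({c.locus.strand}) mfe={c.fold_score:.1f}\n"
            )
            fh.write(c.precursor_seq + "\n")
            fh.write(c.structure + "\n")
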