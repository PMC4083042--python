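"""Bisulfite clone analysis: bisulfite-aware global alignment of clone
sequences to their reference locus, per-cytosine context classification
(CG / CHG / CHH, H in {A, C, T}), per-context percent methylation per
genotype, and genotype differencing.

Only the top (bisulfite-converted) strand of each amplicon is analyzed;
a clone arriving in reverse orientation is detected by aligning its
reverse complement and keeping the better-identity orientation.  At each
reference cytosine a clone C is read as methylated and a clone T as
unmethylated (the bisulfite conversion product); anything else, including
gaps, leaves the site uncovered in that clone.  Incomplete conversion is
reported as a QC estimate but not corrected for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .io_formats import revcomp

__all__ = [
    "CloneAlignment",
    "CytosineSite",
    "MethylationSummary",
    "align_clone",
    "call_sites",
    "summarize_locus",
    "diff_genotypes",
    "classify_context",
    "lollipop_report",
    "CONTEXTS",
    "GAP_COST",
    "MISMATCH_COST",
]

CONTEXTS = ("CG", "CHG", "CHH")
MISMATCH_COST = 1.0
GAP_COST = 2.0

_ALPHABET = "ACGTN"


def _make_aligner() -> Align.PairwiseAligner:
    """Global aligner under the bisulfite-aware substitution rule:
    reference C aligned to clone T costs 0 (conversion), matches cost 0,
    other mismatches cost 1, gaps cost 2 (scores are negated costs)."""
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = 0.0 if a == b else -MISMATCH_COST
    matrix["C", "T"] = 0.0  # reference C read as T after conversion
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -GAP_COST
    aligner.extend_gap_score = -GAP_COST
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class CloneAlignment:
    """Per-position pairing of a clone to its locus reference.

    ``ref_to_clone[i]`` is the clone base aligned to reference position i,
    or None at a gap.  ``identity`` excludes reference-C positions read as
    T (conversion events are not mismatches).
    """

    clone_id: str
    ref_to_clone: list
    cost: float
    identity: float
    reversed_orientation: bool
    accepted: bool


def align_clone(
    clone_seq: str,
    locus_ref: str,
    clone_id: str = "clone",
    min_identity: float = 0.9,
) -> CloneAlignment:
    """Bisulfite-aware global alignment of one clone to its reference.

    Both orientations of the clone are tried; the better-identity one is
    kept.  Clones shorter than half or longer than 110% of the reference,
    or below ``min_identity`` (conversion-aware), are rejected.
    """
    clone_seq = clone_seq.upper().replace("U", "T")
    locus_ref = locus_ref.upper().replace("U", "T")
    if not (0.5 * len(locus_ref) <= len(clone_seq) <= 1.1 * len(locus_ref)):
        return CloneAlignment(clone_id, [None] * len(locus_ref), np.inf, 0.0, False, False)
    best = None
    for reversed_orientation, seq in ((False, clone_seq), (True, revcomp(clone_seq))):
        alignment = _ALIGNER.align(locus_ref, seq)[0]
        mapping: list = [None] * len(locus_ref)
        for (r0, r1), (q0, q1) in zip(*alignment.aligned):
            for k in range(r1 - r0):
                mapping[r0 + k] = seq[q0 + k]
        n_cmp = n_match = 0
        for i, base in enumerate(mapping):
            if base is None:
                continue
            if locus_ref[i] == "C" and base == "T":
                continue  # conversion, excluded from identity
            n_cmp += 1
            n_match += base == locus_ref[i]
        identity = n_match / n_cmp if n_cmp else 0.0
        cand = CloneAlignment(
            clone_id, mapping, -float(alignment.score), identity, reversed_orientation, True
        )
        if best is None or cand.identity > best.identity:
            best = cand
    best.accepted = best.identity >= min_identity
    return best


def classify_context(ref: str, i: int) -> str | None:
    """Context of the cytosine at ``ref[i]`` from the top strand.

    CG if the next base is G; else CHG if the base after that is G; else
    CHH.  Returns None when the needed downstream bases run off the end
    (undefined context) or contain N.
    """
    if ref[i] != "C":
        raise ValueError(f"position {i} is not a cytosine")
    if i + 1 >= len(ref) or ref[i + 1] == "N":
        return None
    if ref[i + 1] == "G":
        return "CG"
    if i + 2 >= len(ref) or ref[i + 2] == "N":
        return None
    return "CHG" if ref[i + 2] == "G" else "CHH"


@dataclass
class CytosineSite:
    locus_id: str
    position: int
    context: str
    states: dict = field(default_factory=dict)  # clone_id -> state


def call_sites(
    alignments: Sequence[CloneAlignment], locus_ref: str, locus_id: str = "locus"
) -> list[CytosineSite]:
    """Per-cytosine methylation states across accepted clones.

    Sites whose context is undefined (within 2 bp of the locus end) are
    excluded.  State per clone: C -> methylated, T -> unmethylated,
    gap/other -> uncovered.
    """
    locus_ref = locus_ref.upper().replace("U", "T")
    sites = []
    for i, base in enumerate(locus_ref):
        if base != "C":
            continue
        context = classify_context(locus_ref, i)
        if context is None:
            continue
        site = CytosineSite(locus_id, i, context)
        for aln in alignments:
            if not aln.accepted:
                continue
            clone_base = aln.ref_to_clone[i]
            if clone_base == "C":
                state = "methylated"
            elif clone_base == "T":
                state = "unmethylated"
            else:
                state = "uncovered"
            site.states[aln.clone_id] = state
        sites.append(site)
    return sites


@dataclass
class MethylationSummary:
    locus_id: str
    genotype: str
    context_stats: dict  # context -> dict(n_methylated, n_total, percent, ci_low, ci_high)
    conversion_estimate: float | None = None

    def percent(self, context: str) -> float | None:
        st = self.context_stats.get(context)
        return None if st is None else st["percent"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for context in CONTEXTS:
            st = self.context_stats.get(context)
            rows.append(
                {
                    "locus_id": self.locus_id,
                    "genotype": self.genotype,
                    "context": context,
                    "n_methylated": st["n_methylated"] if st else 0,
                    "n_total": st["n_total"] if st else 0,
                    "percent": st["percent"] if st else float("nan"),
                    "ci_low": st["ci_low"] if st else float("nan"),
                    "ci_high": st["ci_high"] if st else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def summarize_locus(
    sites: Sequence[CytosineSite],
    genotype: str,
    control_positions: Sequence[int] = (),
) -> MethylationSummary:
    """Pool site states across clones into per-context percentages with
    Wilson 95% intervals.  ``control_positions`` designate known-unmethylated
    cytosines used to estimate the bisulfite conversion rate (QC only)."""
    if not sites:
        raise ValueError("no cytosine sites to summarize")
    locus_id = sites[0].locus_id
    stats_by_context: dict[str, dict] = {}
    for context in CONTEXTS:
        n_meth = n_total = 0
        for site in sites:
            if site.context != context:
                continue
            for state in site.states.values():
                if state == "methylated":
                    n_meth += 1
                    n_total += 1
                elif state == "unmethylated":
                    n_total += 1
        if n_total == 0:
            continue
        low, high = proportion_confint(n_meth, n_total, alpha=0.05, method="wilson")
        stats_by_context[context] = {
            "n_methylated": n_meth,
            "n_total": n_total,
            "percent": 100.0 * n_meth / n_total,
            "ci_low": 100.0 * low,
            "ci_high": 100.0 * high,
        }
    conversion = None
    if control_positions:
        control = set(control_positions)
        n_conv = n_ctrl = 0
        for site in sites:
            if site.position not in control:
                continue
            for state in site.states.values():
                if state == "unmethylated":
                    n_conv += 1
                    n_ctrl += 1
                elif state == "methylated":
                    n_ctrl += 1
        conversion = n_conv / n_ctrl if n_ctrl else None
    return MethylationSummary(locus_id, genotype, stats_by_context, conversion)


def diff_genotypes(
    summary_mut: MethylationSummary, summary_wt: MethylationSummary
) -> pd.DataFrame:
    """Per-context percentage-point differences (mutant minus wild type)
    with a two-proportion z-test on the pooled site calls.

    The deltas are absolute percentage points; contexts missing in either
    genotype yield missing deltas.
    """
    if summary_mut.locus_id != summary_wt.locus_id:
        raise ValueError("summaries are for different loci")
    rows = []
    for context in CONTEXTS:
        st_m = summary_mut.context_stats.get(context)
        st_w = summary_wt.context_stats.get(context)
        if st_m is None or st_w is None:
            rows.append(
                {
                    "locus_id": summary_mut.locus_id,
                    "context": context,
                    "percent_mut": st_m["percent"] if st_m else float("nan"),
                    "percent_wt": st_w["percent"] if st_w else float("nan"),
                    "delta_points": float("nan"),
                    "p_value": float("nan"),
                }
            )
            continue
        counts = np.array([st_m["n_methylated"], st_w["n_methylated"]])
        totals = np.array([st_m["n_total"], st_w["n_total"]])
        if counts.sum() in (0, totals.sum()):
            p = 1.0  # identical degenerate proportions
        else:
            _, p = proportions_ztest(counts, totals)
        rows.append(
            {
                "locus_id": summary_mut.locus_id,
                "context": context,
                "percent_mut": st_m["percent"],
                "percent_wt": st_w["percent"],
                "delta_points": st_m["percent"] - st_w["percent"],
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


_SYMBOLS = {
    "CG": ("●", "○"),     # filled / empty circle
    "CHG": ("▲", "△"),    # filled / empty triangle
    "CHH": ("■", "□"),    # filled / empty square
}


def lollipop_report(sites: Sequence[CytosineSite], path) -> None:
    """Text report: one row per clone, one symbol per cytosine site
    (filled = methylated, empty = unmethylated, '-' = uncovered),
    symbol shape encoding the context."""
    clone_ids = sorted({cid for site in sites for cid in site.states})
    ordered = sorted(sites, key=lambda s: s.position)
    with open(path, "w") as fh:
        if ordered:
            fh.write(f"# locus {ordered[0].locus_id}\n")
        fh.write("# CG ●/○  CHG ▲/△  CHH ■/□  uncovered -\n")
        fh.write("# positions: " + ",".join(str(s.position) for s in ordered) + "\n")
        for cid in clone_ids:
            row = []
            for site in ordered:
                state = site.states.get(cid, "uncovered")
                if state == "uncovered":
                    row.append("-")
                else:
                    filled, empty = _SYMBOLS[site.context]
                    row.append(filled if state == "methylated" else empty)
            fh.write(f"{cid}\t{''.join(row)}\n")
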