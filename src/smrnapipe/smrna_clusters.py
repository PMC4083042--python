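"""Windowed small-RNA cluster quantification and differential calling.

The genome is tiled into non-overlapping 100 bp windows (the last window of
a chromosome may be shorter).  Small-RNA hits in a size range (default
18-26 nt) are counted per window — a hit is assigned to the single window
containing its 5'-most genomic coordinate, both strands pooled, and a
multi-mapping read contributes its full copy number at every hit.  Window
counts are normalized to RPM (reads per million clean reads).  For each
window the per-genotype median RPM across libraries is taken (X for the
mutant, Y for wild type) and the fold value is

    fold_value = log2((X + c) / (Y + c))

with a pseudocount c (default 0.5 RPM) guarding empty windows.  A window is
a differential cluster when |fold_value| >= log2(fold_cutoff), i.e. at
least a 4-fold difference with the default cutoff, boundary inclusive.
Windows with X = Y = 0 are never called.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence
from .read_mapping import ReadPlacement

__all__ = [
    "count_windows",
    "normalize_rpm",
    "call_differential",
    "subset_by_size",
    "chromosome_track",
    "clusters_to_bed",
]


def _window_grid(genome: Sequence[GenomeSequence], width: int) -> pd.DataFrame:
    chroms, starts, ends = [], [], []
    for g in genome:
        edges = list(range(0, g.length, width)) + [g.length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(g.name)
            starts.append(s)
            ends.append(e)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def count_windows(
    placements: Sequence[ReadPlacement],
    genome: Sequence[GenomeSequence],
    size_range: tuple[int, int] = (18, 26),
    window: int = 100,
) -> pd.DataFrame:
    """Per-window raw read counts for one library.

    Returns a DataFrame with columns ``chrom, start, end, raw_count``,
    windows tiling every chromosome without gaps.
    """
    lo, hi = size_range
    if not (15 <= lo <= hi <= 35):
        raise ValueError(f"size range {size_range} outside the 15-35 nt bounds")
    grid = _window_grid(genome, window)
    counts: dict[str, np.ndarray] = {}
    n_windows: dict[str, int] = {}
    for g in genome:
        n_windows[g.name] = math.ceil(g.length / window)
        counts[g.name] = np.zeros(n_windows[g.name], dtype=np.int64)
    for placement in placements:
        if not (lo <= placement.read.length <= hi):
            continue
        c = placement.read.count
        for hit in placement.hits:
            five_prime = hit.start if hit.strand != "-" else hit.end - 1
            counts[hit.chrom][five_prime // window] += c
    grid["raw_count"] = np.concatenate(
        [counts[g.name] for g in genome]
    ) if len(grid) else np.array([], dtype=np.int64)
    return grid


def normalize_rpm(profiles: pd.DataFrame, library_total: int) -> pd.DataFrame:
    """Attach ``rpm = raw_count * 1e6 / library_total`` (clean-read total)."""
    if library_total <= 0:
        raise ValueError("library total must be positive for RPM normalization")
    out = profiles.copy()
    out["rpm"] = out["raw_count"] * 1e6 / library_total
    return out


def _median_rpm(profiles: Sequence[pd.DataFrame]) -> np.ndarray:
    return np.median(np.column_stack([p["rpm"].to_numpy() for p in profiles]), axis=1)


def call_differential(
    profiles_mut: Sequence[pd.DataFrame],
    profiles_wt: Sequence[pd.DataFrame],
    fold_cutoff: float = 4.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Median-based per-window differential calling.

    ``profiles_mut`` / ``profiles_wt`` are per-library window profiles from
    :func:`normalize_rpm` on an identical window grid (the median of a
    single library is that library's value).  Returns a DataFrame with
    columns ``chrom, start, end, X, Y, fold_value, direction, passes``.
    """
    if not profiles_mut or not profiles_wt:
        raise ValueError("at least one library per genotype is required")
    grid_cols = ["chrom", "start", "end"]
    grid = profiles_mut[0][grid_cols]
    for p in list(profiles_mut) + list(profiles_wt):
        if not p[grid_cols].equals(grid):
            raise ValueError("window grids differ between libraries")
    X = _median_rpm(profiles_mut)
    Y = _median_rpm(profiles_wt)
    c = pseudocount
    with np.errstate(divide="ignore"):
        fold = np.log2(X + c) - np.log2(Y + c)
    out = grid.copy()
    out["X"] = X
    out["Y"] = Y
    out["fold_value"] = fold
    out["direction"] = np.where(fold < 0, "down", "up")
    out["passes"] = (np.abs(fold) >= math.log2(fold_cutoff)) & ~((X == 0) & (Y == 0))
    return out


def subset_by_size(
    placements: Sequence[ReadPlacement], size_range: tuple[int, int] = (20, 24)
) -> list[ReadPlacement]:
    """Placements whose read length lies in the closed ``size_range``.

    The default 20-24 nt range is the parsimonious siRNA size class; re-running
    window counting and differential calling on the subset gives the
    siRNA-restricted cluster analysis.
    """
    lo, hi = size_range
    return [p for p in placements if lo <= p.read.length <= hi]


def chromosome_track(clusters: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-chromosome ordered ``(position, fold_value)`` series for plotting.

    Non-passing windows are included; positions are window starts and are
    strictly increasing within each chromosome.
    """
    tracks = {}
    for chrom, sub in clusters.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        tracks[chrom] = pd.DataFrame(
            {"position": sub["start"].to_numpy(), "fold_value": sub["fold_value"].to_numpy()}
        )
    return tracks


def clusters_to_bed(clusters: pd.DataFrame, path) -> None:
    """Export clusters as BED6+ (name=window id, score=|fold_value|)."""
    with open(path, "w") as fh:
        for i, row in enumerate(
            clusters.sort_values(["chrom", "start"]).itertuples(), 1
        ):
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        str(row.start),
                        str(row.end),
                        f"window{i}",
                        f"{abs(row.fold_value):.4g}",
                        ".",
                        f"{row.X:.6g}",
                        f"{row.Y:.6g}",
                        f"{row.fold_value:.6g}",
                        str(bool(row.passes)),
                    ]
                )
                + "\n"
            )
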