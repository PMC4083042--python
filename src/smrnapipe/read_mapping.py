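"""Exact-match placement of collapsed small-RNA reads on a reference genome,
plus per-library size-distribution and annotation-category profiles.

Mapping is exact (0 mismatches) on both strands, with all hits of
multi-mapping reads reported.  A read that equals its own reverse
complement would produce the same site twice (once per strand); such hits
are canonicalized to the + strand and reported once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import (
    AnnotationRecord,
    CollapsedRead,
    GenomeSequence,
    Interval,
    SmallRNALibrary,
    revcomp,
)

__all__ = [
    "GenomeIndex",
    "ReadPlacement",
    "SizeProfile",
    "CategoryProfile",
    "build_index",
    "map_reads",
    "profile_sizes",
    "profile_categories",
    "placements_to_bed",
    "CATEGORY_PRIORITY",
]

#: a read's category is the highest-priority feature class among its hits
CATEGORY_PRIORITY = (
    "known_miRNA_locus",
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "repeat",
    "TE",
    "gene",
    "other",
    "unannotated",
)


@dataclass
class ReadPlacement:
    read: CollapsedRead
    hits: list[Interval] = field(default_factory=list)

    @property
    def n_hits(self) -> int:
        return len(self.hits)


class GenomeIndex:
    """Seed-and-verify exact lookup over a genome's forward strand.

    Forward k-mers (default k=12) are hashed to their genomic positions.
    A query is located by looking up its first k-mer and verifying the
    full string; minus-strand hits come from querying the reverse
    complement, so only one strand is ever stored.
    """

    def __init__(self, genome: Sequence[GenomeSequence], k: int = 12):
        self.k = k
        self.chroms = {g.name: g.seq for g in genome}
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for g in genome:
            seq = g.seq
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                self._kmers.setdefault(kmer, []).append((g.name, pos))

    def _exact_hits(self, query: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, pos in self._kmers.get(query[: self.k], ()):
            if self.chroms[chrom][pos : pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits

    def lookup(self, query: str) -> list[Interval]:
        """All exact hits of ``query`` on either strand, genomic order."""
        if len(query) < self.k:
            raise ValueError(
                f"query shorter than seed length k={self.k}: {query!r}"
            )
        n = len(query)
        hits = [Interval(c, p, p + n, "+") for c, p in self._exact_hits(query)]
        rc = revcomp(query)
        if rc != query:  # palindromes: minus hits duplicate plus hits
            hits += [Interval(c, p, p + n, "-") for c, p in self._exact_hits(rc)]
        return sorted(hits)


def build_index(genome: Sequence[GenomeSequence], k: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, k=k)


def map_reads(
    library: Iterable[CollapsedRead], index: GenomeIndex
) -> list[ReadPlacement]:
    """Place every collapsed read; reads with no hit keep an empty hit list."""
    return [ReadPlacement(read, index.lookup(read.seq)) for read in library]


@dataclass
class SizeProfile:
    """Per-length (18-26 nt) read-count totals and fractions for a library.

    Lengths outside 18-26 nt are tallied in ``other_count`` and excluded
    from the fractions.
    """

    counts: dict[int, int]
    other_count: int
    min_len: int = 18
    max_len: int = 26

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.other_count

    @property
    def fractions(self) -> dict[int, float]:
        in_range = sum(self.counts.values())
        if in_range == 0:
            return {n: 0.0 for n in self.counts}
        return {n: c / in_range for n, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions
        return pd.DataFrame(
            {
                "length": list(self.counts) + ["other"],
                "count": list(self.counts.values()) + [self.other_count],
                "fraction": [frac[n] for n in self.counts] + [float("nan")],
            }
        )


def profile_sizes(
    library: SmallRNALibrary | Iterable[CollapsedRead],
    min_len: int = 18,
    max_len: int = 26,
) -> SizeProfile:
    counts = {n: 0 for n in range(min_len, max_len + 1)}
    other = 0
    for read in library:
        if min_len <= read.length <= max_len:
            counts[read.length] += read.count
        else:
            other += read.count
    return SizeProfile(counts, other, min_len, max_len)


@dataclass
class CategoryProfile:
    """Per-annotation-category read-count totals and fractions."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / total for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [frac[c] for c in self.counts],
            }
        )


def _annotation_trees(
    annotation: Sequence[AnnotationRecord],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in annotation:
        iv = rec.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, rec.feature_class
        )
    return trees


def profile_categories(
    placements: Sequence[ReadPlacement],
    annotation: Sequence[AnnotationRecord],
) -> CategoryProfile:
    """Assign each read the highest-priority feature class overlapped by any
    of its hits (:data:`CATEGORY_PRIORITY`); unmapped reads and reads hitting
    no feature are ``unannotated``.  Counts are weighted by copy number.
    """
    trees = _annotation_trees(annotation)
    rank = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
    counts = {c: 0 for c in CATEGORY_PRIORITY}
    for placement in placements:
        best = "unannotated"
        for hit in placement.hits:
            tree = trees.get(hit.chrom)
            if tree is None:
                continue
            for ov in tree.overlap(hit.start, hit.end):
                if rank[ov.data] < rank[best]:
                    best = ov.data
        counts[best] += placement.read.count
    return CategoryProfile(counts)


def placements_to_bed(placements: Sequence[ReadPlacement], path) -> None:
    """Export placements as BED6, one line per hit, score = read copy count."""
    rows = []
    for i, placement in enumerate(placements, 1):
        for hit in placement.hits:
            rows.append(
                (hit.chrom, hit.start, hit.end, f"read{i}", placement.read.count, hit.strand)
            )
    rows.sort()
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")
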