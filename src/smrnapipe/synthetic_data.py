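"""Generate a complete toy two-genotype study with recorded ground truth.

One call to :func:`simulate_study` (or the individual simulators) produces
a genome with annotation, one collapsed small-RNA library per genotype, a
replicate expression matrix, a mature-miRNA catalogue with a target table,
and bisulfite clone sets per target locus — everything the pipeline
consumes — together with ground-truth tables recording exactly what was
planted where.

Study design emulated
---------------------
Two genotypes (an RNA-dependent-RNA-polymerase loss-of-function mutant,
``mut``, and its sibling wild type, ``wt``), one deeply sequenced
small-RNA library per genotype (scaled down from ~10^7 to a desk-scale
default of 2x10^5 clean reads), three expression replicates per genotype,
and ~10 bisulfite target loci drawn from two transposable-element
families and from genes, with planted per-context (CG/CHG/CHH)
methylation levels.  Background small-RNA read lengths are bimodal at 21
and 24 nt, the canonical plant size classes.  Planted differential
clusters occupy single 100 bp windows; planted miRNAs (known catalogue
entries and unannotated novel hairpins, one mature shared by three loci)
are emitted at configured mutant:wild-type ratios.  All randomness is
driven by the config seed; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationRecord,
    CollapsedRead,
    GenomeSequence,
    Interval,
    SmallRNALibrary,
    revcomp,
)
from .mirna_analysis import MiRNACatalogEntry

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedCluster",
    "PlantedMiRNA",
    "PlantedNovelMiRNA",
    "PlantedDEG",
    "PlantedMethLocus",
    "simulate_genome",
    "simulate_smrna_libraries",
    "simulate_expression",
    "simulate_bisulfite_clones",
    "simulate_study",
    "GENOTYPES",
]

GENOTYPES = ("mut", "wt")

_BASES = b"ACGT"
_DECODE = bytes.maketrans(bytes([0, 1, 2, 3]), _BASES)


# ---------------------------------------------------------------------------
# Planted-feature specs
# ---------------------------------------------------------------------------

@dataclass
class PlantedCluster:
    """A differential small-RNA cluster confined to one 100 bp window.

    ``bias_fold`` multiplies the mutant expectation: the mutant library
    receives Poisson(read_count * bias_fold) reads, the wild type
    Poisson(read_count).
    """

    interval: Interval | None = None
    bias_fold: float = 8.0
    read_count: int = 400
    length_mode: int = 24

    def __post_init__(self) -> None:
        if self.bias_fold <= 0:
            raise ValueError("bias fold must be positive")


@dataclass
class PlantedMiRNA:
    """A known catalogue miRNA with a mutant:wild-type abundance ratio."""

    name: str
    ratio: float = 1.0
    base_count: int = 200
    star_mismatches: int = 1
    mature_seq: str | None = None
    locus: Interval | None = None

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("abundance ratio must be positive")


@dataclass
class PlantedNovelMiRNA:
    """An unannotated hairpin expressed mostly in the mutant; the same
    mature sequence may be planted at several independent loci."""

    name: str
    n_loci: int = 3
    mut_count: int = 300
    wt_count: int = 10
    star_fraction: float = 0.2
    star_mismatches: int = 2
    mature_seq: str | None = None
    loci: list = field(default_factory=list)


@dataclass
class PlantedDEG:
    gene_id: str | None = None
    effect: float = 1.5  # log2 shift in the mutant replicates
    chrom_hint: str | None = None


@dataclass
class PlantedMethLocus:
    """A bisulfite target locus with per-context methylation probabilities
    per genotype, e.g. ``probs={"mut": {"CG": .6, ...}, "wt": {...}}``."""

    locus_id: str
    probs: dict
    source: str = "TE_A"  # TE_A | TE_B | gene: which feature type hosts it
    interval: Interval | None = None

    def __post_init__(self) -> None:
        for genotype in GENOTYPES:
            for context in ("CG", "CHG", "CHH"):
                p = self.probs[genotype][context]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"invalid probability {p} for {self.locus_id}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 1
    n_chroms: int = 4               # stands in for the 12 rice chromosomes
    chrom_length: int = 200_000
    n_library_reads: int = 200_000  # clean reads per genotype library
    n_replicates_expr: int = 3
    n_genes_per_chrom: int = 60
    n_te_per_family: int = 5        # copies per chromosome, two families
    n_known_mirna_per_chrom: int = 8
    window: int = 100
    expr_sigma: float = 0.25        # per-replicate log2 intensity noise
    expr_baseline: tuple[float, float] = (8.0, 1.5)  # mean, sd of baselines
    n_bisulfite_clones: int = 30
    conversion_rate: float = 0.995
    meth_locus_length: int = 300
    background_length_probs: dict = field(
        default_factory=lambda: {
            18: 0.03, 19: 0.04, 20: 0.08, 21: 0.25, 22: 0.08,
            23: 0.10, 24: 0.30, 25: 0.07, 26: 0.05,
        }
    )
    planted_cluster_spec: list | None = None
    planted_mirna_spec: list | None = None
    planted_novel_spec: list | None = None
    planted_deg_spec: list | None = None
    planted_meth_spec: list | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion rate must be a probability")
        if self.n_replicates_expr < 2:
            raise ValueError("at least 2 expression replicates per genotype")
        total = sum(self.background_length_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("background length probabilities must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GenomeLayout:
    """Deterministic feature anchors, scaled to the chromosome length.

    Genes occupy the first 60% of each chromosome on a regular grid with
    intergenic gaps (where default clusters are planted); structural RNAs,
    the two TE families, known miRNA loci and novel hairpins follow in
    fixed blocks.  All simulators derive coordinates from this single
    object so planted features never collide.
    """

    chrom_length: int
    n_genes: int
    n_te: int
    n_known_mirna: int

    def __post_init__(self) -> None:
        L = self.chrom_length
        self.gene_offset = 200
        self.gene_pitch = max(1, (int(0.60 * L) - self.gene_offset) // max(self.n_genes, 1))
        self.gene_length = min(1500, max(200, self.gene_pitch - 300))
        self.structural_base = int(0.62 * L)
        self.te_a_base = int(0.70 * L)
        self.te_b_base = int(0.78 * L)
        self.te_step = 600
        self.te_length = 400
        self.mirna_base = int(0.86 * L)
        self.mirna_step = 400
        self.novel_base = int(0.96 * L)
        self.novel_step = 300
        if self.te_b_base - (self.te_a_base + self.n_te * self.te_step) < 0:
            raise ValueError("TE families overlap: reduce n_te_per_family")
        if self.mirna_base + self.n_known_mirna * self.mirna_step > self.novel_base:
            raise ValueError("miRNA block overlaps novel block: reduce counts")

    def gene_interval(self, chrom: str, g: int) -> Interval:
        start = self.gene_offset + g * self.gene_pitch
        return Interval(chrom, start, start + self.gene_length, "+" if g % 2 == 0 else "-")

    def cluster_window(self, chrom: str, g: int, width: int) -> Interval:
        # snapped onto the analysis window grid so a planted cluster is one window
        raw = self.gene_offset + g * self.gene_pitch + self.gene_length + 100
        start = (raw // width) * width
        return Interval(chrom, start, start + width)

    def te_start(self, family: str, i: int) -> int:
        base = self.te_a_base if family == "TE_A" else self.te_b_base
        return base + i * self.te_step


def _layout(config: SimulationConfig) -> GenomeLayout:
    return GenomeLayout(
        config.chrom_length,
        config.n_genes_per_chrom,
        config.n_te_per_family,
        config.n_known_mirna_per_chrom,
    )


def _default_cluster_spec(config: SimulationConfig) -> list[PlantedCluster]:
    """20 planted clusters (at the defaults): intergenic-gap windows on
    every chromosome plus, on the first and last chromosome, one window
    adjacent to a differentially methylated TE locus (for the cross-layer
    association)."""
    layout = _layout(config)
    clusters = []
    first, last = "chr1", f"chr{config.n_chroms}"
    n_slots_full = 5 if config.n_genes_per_chrom >= 10 else 2
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_slots = n_slots_full - (1 if chrom in (first, last) and n_slots_full > 1 else 0)
        slots = [
            round((i + 1) * config.n_genes_per_chrom / (n_slots_full + 1))
            for i in range(n_slots)
        ]
        for i, g in enumerate(slots):
            bias = 8.0 if i % 2 == 0 else 0.125
            clusters.append(PlantedCluster(layout.cluster_window(chrom, g, config.window), bias))
    # association demo: up-cluster near the CHH-gaining TE_B locus (chr1)
    # and down-cluster near the CHH-losing TE_A locus (last chromosome),
    # both in unique background sequence within 1 kb of the locus
    up_start = (layout.te_b_base - 300) // config.window * config.window
    clusters.append(PlantedCluster(Interval(first, up_start, up_start + config.window), 8.0))
    host_i = min(3, config.n_te_per_family - 1)
    down_start = (
        (layout.te_start("TE_A", host_i) + layout.te_length + 50)
        // config.window * config.window
    )
    clusters.append(
        PlantedCluster(Interval(last, down_start, down_start + config.window), 0.125)
    )
    return clusters


def _default_mirna_spec(config: SimulationConfig) -> list[PlantedMiRNA]:
    n = config.n_chroms * config.n_known_mirna_per_chrom
    spec = []
    for i in range(n):
        spec.append(
            PlantedMiRNA(
                name=f"sim-miR{100 + i}",
                ratio=1.0,
                base_count=100 + 10 * (i % 20),
                star_mismatches=i % 3,
            )
        )
    # planted expression changes echoing the study design: a strong up,
    # a strong down, and one family with members moving in opposite ways
    if n >= 4:
        spec[0] = replace(spec[0], name="sim-miR901", ratio=9.0, base_count=200)
        spec[1] = replace(spec[1], name="sim-miR167j", ratio=1 / 6.1, base_count=250)
        spec[2] = replace(spec[2], name="sim-miR395p", ratio=1 / 5.6, base_count=220)
        spec[3] = replace(spec[3], name="sim-miR395s", ratio=4.2, base_count=180)
    return spec


def _default_novel_spec(config: SimulationConfig) -> list[PlantedNovelMiRNA]:
    return [PlantedNovelMiRNA(name="novel-1", n_loci=3)]


def _default_deg_spec(config: SimulationConfig) -> list[PlantedDEG]:
    # ~5% of genes differential, up:down ~ 2:1, concentrated on chr1 to
    # echo the non-random chromosomal distribution of the study
    effects_up = (1.0, 1.2, 1.5, 1.8, 2.0, 2.2, 2.5, 1.5)
    effects_down = (-1.0, -1.5, -2.0, -2.5)
    other = [f"chr{min(2 + k, config.n_chroms)}" for k in range(2)]
    spec = []
    for i, eff in enumerate(effects_up):
        chrom = "chr1" if i < 6 else other[i % 2]
        spec.append(PlantedDEG(effect=eff, chrom_hint=chrom))
    for i, eff in enumerate(effects_down):
        chrom = "chr1" if i < 2 else other[i % 2]
        spec.append(PlantedDEG(effect=eff, chrom_hint=chrom))
    return spec


def _default_meth_spec(config: SimulationConfig) -> list[PlantedMethLocus]:
    flat = {"CG": 0.85, "CHG": 0.55, "CHH": 0.12}

    def probs(mut=None, wt=None):
        return {"mut": {**flat, **(mut or {})}, "wt": {**flat, **(wt or {})}}

    spec = [
        # DNA-transposon locus: CG down 20 pts, CHG up ~30, CHH up ~50
        # (hosted by the first TE_B copy, next to the planted up-cluster)
        PlantedMethLocus(
            "TEb_5p",
            probs(mut={"CG": 0.60, "CHG": 0.60, "CHH": 0.70},
                  wt={"CG": 0.80, "CHG": 0.30, "CHH": 0.20}),
            "TE_B",
        ),
        # retrotransposon-family LTR with a CG/CHG decrease in the mutant
        PlantedMethLocus("TEa_ltr", probs(mut={"CG": 0.55, "CHG": 0.25}), "TE_A"),
        PlantedMethLocus("TEa_body1", probs(), "TE_A"),
        PlantedMethLocus("TEa_body2", probs(), "TE_A"),
        # locus with reduced CHH and reduced nearby small RNAs
        # (hosted on the last chromosome, next to the planted down-cluster)
        PlantedMethLocus(
            "TEa_flank", probs(mut={"CHH": 0.10}, wt={"CHH": 0.50}), "TE_A"
        ),
        PlantedMethLocus("TEb_body1", probs(), "TE_B"),
        PlantedMethLocus("TEb_body2", probs(), "TE_B"),
        # genic locus gaining CG methylation in the mutant
        PlantedMethLocus("geneA", probs(mut={"CG": 0.80}, wt={"CG": 0.30}), "gene"),
        PlantedMethLocus("geneB", probs(), "gene"),
        PlantedMethLocus("geneC", probs(), "gene"),
    ]
    return spec


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    mirnas: pd.DataFrame = field(default_factory=pd.DataFrame)
    novel: pd.DataFrame = field(default_factory=pd.DataFrame)
    degs: pd.DataFrame = field(default_factory=pd.DataFrame)
    methylation: pd.DataFrame = field(default_factory=pd.DataFrame)
    library_totals: dict = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth()
        for name in ("clusters", "mirnas", "novel", "degs", "methylation"):
            a, b = getattr(self, name), getattr(other, name)
            setattr(out, name, b if a.empty else (a if b.empty else pd.concat([a, b])))
        out.library_totals = {**self.library_totals, **other.library_totals}
        return out


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.integers(0, 4, size=n, dtype=np.uint8).tobytes().translate(_DECODE).decode()


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    if n_mut == 0:
        return seq
    out = list(seq)
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _hairpin(rng: np.random.Generator, mature: str, loop_len: int, star_mismatches: int) -> str:
    """mature + loop + (reverse complement of mature with planted mismatches)."""
    loop = _random_seq(rng, loop_len)
    star = _mutate(rng, revcomp(mature), star_mismatches)
    return mature + loop + star


def _resolve_config(config: SimulationConfig) -> None:
    if config.planted_cluster_spec is None:
        config.planted_cluster_spec = _default_cluster_spec(config)
    if config.planted_mirna_spec is None:
        config.planted_mirna_spec = _default_mirna_spec(config)
    if config.planted_novel_spec is None:
        config.planted_novel_spec = _default_novel_spec(config)
    if config.planted_deg_spec is None:
        config.planted_deg_spec = _default_deg_spec(config)
    if config.planted_meth_spec is None:
        config.planted_meth_spec = _default_meth_spec(config)


_GO_CATEGORIES = (
    "metabolic process", "stress response", "transcription", "transport",
    "signal transduction", "development", "photosynthesis", "protein binding",
    "DNA binding", "unknown",
)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GenomeSequence], list[AnnotationRecord]]:
    """Simulate the reference genome and its annotation.

    The background is i.i.d. uniform ACGT.  Each chromosome carries a grid
    of GO-labelled genes, structural-RNA loci, two transposable-element
    families (copies within a family share one planted sequence), known
    miRNA loci with designed embedded hairpins, and — unannotated —
    the novel hairpins and methylation target regions resolved into the
    config's planted specs.  Deterministic for a given config.
    """
    _resolve_config(config)
    layout = _layout(config)
    rng = config.rng(0)
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chroms)]
    chroms = {
        name: bytearray(_random_seq(rng, config.chrom_length), "ascii")
        for name in chrom_names
    }
    annotation: list[AnnotationRecord] = []

    def plant(chrom: str, start: int, seq: str) -> None:
        if start < 0 or start + len(seq) > config.chrom_length:
            raise ValueError(f"planted feature exceeds {chrom} bounds")
        chroms[chrom][start : start + len(seq)] = seq.encode()

    # genes on a regular grid with GO labels
    gene_index = 0
    for chrom in chrom_names:
        for g in range(config.n_genes_per_chrom):
            go = _GO_CATEGORIES[gene_index % len(_GO_CATEGORIES)]
            go2 = _GO_CATEGORIES[(gene_index * 3 + 1) % len(_GO_CATEGORIES)]
            annotation.append(
                AnnotationRecord(
                    f"gene{gene_index + 1:04d}",
                    layout.gene_interval(chrom, g),
                    "gene",
                    {"go_terms": f"{go},{go2}" if gene_index % 4 == 0 else go},
                )
            )
            gene_index += 1

    # structural RNA block per chromosome
    sb = layout.structural_base
    structural = (
        ("rRNA", sb, 800), ("tRNA", sb + 1000, 80), ("tRNA", sb + 1200, 80),
        ("snoRNA", sb + 1500, 150), ("snRNA", sb + 1800, 150),
    )
    for chrom in chrom_names:
        for i, (cls, start, length) in enumerate(structural):
            annotation.append(
                AnnotationRecord(
                    f"{cls}_{chrom}_{i}", Interval(chrom, start, start + length), cls
                )
            )

    # two TE families; copies share the family sequence exactly
    te_len = layout.te_length
    family_seqs = {"TE_A": _random_seq(rng, te_len), "TE_B": _random_seq(rng, te_len)}
    te_copies: dict[str, list[Interval]] = {"TE_A": [], "TE_B": []}
    for chrom in chrom_names:
        for family in ("TE_A", "TE_B"):
            for i in range(config.n_te_per_family):
                start = layout.te_start(family, i)
                plant(chrom, start, family_seqs[family])
                iv = Interval(chrom, start, start + te_len, "+")
                te_copies[family].append(iv)
                annotation.append(
                    AnnotationRecord(
                        f"{family}_{chrom}_{i}", iv, "TE", {"family": family}
                    )
                )

    # known miRNA loci with embedded hairpins (mature arm 21 nt, loop 12)
    mirna_spec: list[PlantedMiRNA] = config.planted_mirna_spec
    per_chrom = config.n_known_mirna_per_chrom
    for idx, planted in enumerate(mirna_spec):
        chrom = chrom_names[(idx // per_chrom) % len(chrom_names)] if per_chrom else chrom_names[0]
        start = layout.mirna_base + (idx % per_chrom) * layout.mirna_step
        if planted.mature_seq is None:
            planted.mature_seq = _random_seq(rng, 21)
        hairpin = _hairpin(rng, planted.mature_seq, 12, planted.star_mismatches)
        plant(chrom, start, hairpin)
        planted.locus = Interval(chrom, start, start + len(hairpin), "+")
        annotation.append(
            AnnotationRecord(
                planted.name, planted.locus, "known_miRNA_locus",
                {"mature": planted.mature_seq},
            )
        )

    # novel hairpins: unannotated, one mature possibly at several loci
    for planted in config.planted_novel_spec:
        if planted.mature_seq is None:
            planted.mature_seq = _random_seq(rng, 21)
        if not planted.loci:
            for k in range(planted.n_loci):
                chrom = chrom_names[0]
                start = layout.novel_base + k * layout.novel_step
                hairpin = _hairpin(
                    rng, planted.mature_seq, 12, planted.star_mismatches
                )
                plant(chrom, start, hairpin)
                planted.loci.append(Interval(chrom, start, start + len(hairpin), "+"))

    # methylation target loci hosted by TE copies or genes (coordinates only)
    used: dict[str, int] = {"TE_A": 0, "TE_B": 0, "gene": 0}
    gene_records = [r for r in annotation if r.feature_class == "gene"]
    for planted in config.planted_meth_spec:
        if planted.interval is not None:
            continue
        length = config.meth_locus_length
        if planted.source in ("TE_A", "TE_B"):
            copies = te_copies[planted.source]
            host = copies[(used[planted.source] * (config.n_te_per_family + 1)) % len(copies)]
            start = host.start
        else:
            host = gene_records[used["gene"] * 37 % len(gene_records)].interval
            start = host.start + 100
        used[planted.source] += 1
        planted.interval = Interval(host.chrom, start, start + length, "+")

    genome = [GenomeSequence(name, chroms[name].decode()) for name in chrom_names]
    _validate_planted(config, genome)
    return genome, annotation


def _validate_planted(config: SimulationConfig, genome: list[GenomeSequence]) -> None:
    sizes = {g.name: g.length for g in genome}
    for cluster in config.planted_cluster_spec:
        iv = cluster.interval
        if iv is None or iv.end > sizes.get(iv.chrom, 0):
            raise ValueError(f"planted cluster outside genome bounds: {iv}")


# ---------------------------------------------------------------------------
# Small-RNA libraries
# ---------------------------------------------------------------------------

def _draw_background(
    rng: np.random.Generator,
    genome: list[GenomeSequence],
    n_reads: int,
    length_probs: dict,
) -> dict[str, int]:
    lengths = np.array(sorted(length_probs))
    probs = np.array([length_probs[n] for n in lengths])
    chrom_lens = np.array([g.length for g in genome])
    chrom_probs = chrom_lens / chrom_lens.sum()
    counts: dict[str, int] = {}
    chosen_chrom = rng.choice(len(genome), size=n_reads, p=chrom_probs)
    chosen_len = rng.choice(lengths, size=n_reads, p=probs)
    chosen_strand = rng.integers(0, 2, size=n_reads)
    for ci, ln, st in zip(chosen_chrom, chosen_len, chosen_strand):
        seq = genome[ci].seq
        start = rng.integers(0, len(seq) - ln + 1)
        read = seq[start : start + ln]
        if st:
            read = revcomp(read)
        counts[read] = counts.get(read, 0) + 1
    return counts


def simulate_smrna_libraries(
    config: SimulationConfig,
    genome: list[GenomeSequence],
    annotation: Sequence[AnnotationRecord],
) -> tuple[dict[str, SmallRNALibrary], GroundTruth]:
    """One collapsed small-RNA library per genotype plus the ground truth.

    Planted cluster, known-miRNA and novel-miRNA reads are drawn first;
    the remaining budget up to ``n_library_reads`` is background drawn
    uniformly from the genome, so each library totals exactly
    ``n_library_reads`` clean reads.  Every emitted read is an exact
    substring of the genome or of its reverse complement.
    """
    rng = config.rng(1)
    chrom_seq = {g.name: g.seq for g in genome}
    counts: dict[str, dict[str, int]] = {g: {} for g in GENOTYPES}

    def add(genotype: str, seq: str, n: int) -> None:
        if n > 0:
            counts[genotype][seq] = counts[genotype].get(seq, 0) + int(n)

    truth_clusters = []
    for cluster in config.planted_cluster_spec:
        iv = cluster.interval
        seq = chrom_seq[iv.chrom]
        n_mut = int(rng.poisson(cluster.read_count * cluster.bias_fold))
        n_wt = int(rng.poisson(cluster.read_count))
        for genotype, n in (("mut", n_mut), ("wt", n_wt)):
            for _ in range(n):
                ln = int(rng.choice([21, 22, 23, cluster.length_mode],
                                    p=[0.15, 0.15, 0.2, 0.5]))
                start = int(rng.integers(iv.start, iv.end - ln + 1))
                read = seq[start : start + ln]
                if rng.integers(0, 2):
                    read = revcomp(read)
                add(genotype, read, 1)
        truth_clusters.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "bias_fold": cluster.bias_fold, "read_count": cluster.read_count,
                "n_mut": n_mut, "n_wt": n_wt,
                "direction": "up" if cluster.bias_fold > 1 else "down",
            }
        )

    truth_mirnas = []
    for planted in config.planted_mirna_spec:
        n_wt = int(rng.poisson(planted.base_count))
        n_mut = int(rng.poisson(planted.base_count * planted.ratio))
        add("mut", planted.mature_seq, n_mut)
        add("wt", planted.mature_seq, n_wt)
        truth_mirnas.append(
            {
                "name": planted.name, "ratio": planted.ratio,
                "base_count": planted.base_count, "n_mut": n_mut, "n_wt": n_wt,
                "chrom": planted.locus.chrom, "start": planted.locus.start,
                "end": planted.locus.end,
            }
        )

    truth_novel = []
    for planted in config.planted_novel_spec:
        n_mut = int(rng.poisson(planted.mut_count))
        n_wt = int(rng.poisson(planted.wt_count))
        add("mut", planted.mature_seq, n_mut)
        add("wt", planted.mature_seq, n_wt)
        # star reads from the 3' arm of the first locus, 2 nt 3' offset
        locus = planted.loci[0]
        star = chrom_seq[locus.chrom][locus.start + 35 : locus.start + 56]
        n_star_mut = int(rng.poisson(planted.mut_count * planted.star_fraction))
        n_star_wt = int(rng.poisson(planted.wt_count * planted.star_fraction))
        add("mut", star, n_star_mut)
        add("wt", star, n_star_wt)
        for k, locus in enumerate(planted.loci):
            truth_novel.append(
                {
                    "name": planted.name, "locus_index": k,
                    "mature_seq": planted.mature_seq, "chrom": locus.chrom,
                    "start": locus.start, "end": locus.end,
                    "n_mut": n_mut, "n_wt": n_wt, "guide_arm": "5p",
                }
            )

    libraries: dict[str, SmallRNALibrary] = {}
    for genotype in GENOTYPES:
        planted_total = sum(counts[genotype].values())
        n_background = config.n_library_reads - planted_total
        if n_background < 0:
            raise ValueError(
                f"planted reads ({planted_total}) exceed the {genotype} library "
                f"budget ({config.n_library_reads})"
            )
        for seq, n in _draw_background(
            rng, genome, n_background, config.background_length_probs
        ).items():
            add(genotype, seq, n)
        reads = [CollapsedRead(s, c) for s, c in sorted(counts[genotype].items())]
        libraries[genotype] = SmallRNALibrary(
            reads, n_input=config.n_library_reads
        )

    truth = GroundTruth(
        clusters=pd.DataFrame(truth_clusters),
        mirnas=pd.DataFrame(truth_mirnas),
        novel=pd.DataFrame(truth_novel),
        library_totals={g: libraries[g].total_reads for g in GENOTYPES},
    )
    return libraries, truth


def mirna_catalog(config: SimulationConfig) -> list[MiRNACatalogEntry]:
    """The known-miRNA catalogue implied by the resolved config."""
    return [
        MiRNACatalogEntry(p.name, p.mature_seq) for p in config.planted_mirna_spec
    ]


def mirna_target_table(config: SimulationConfig) -> pd.DataFrame:
    """A deterministic miRNA -> predicted-target-gene table.

    Each catalogue miRNA is assigned two gene targets on a fixed stride so
    that planted differential miRNAs hit both planted DEGs and null genes.
    """
    n_genes = config.n_chroms * config.n_genes_per_chrom
    rows = []
    for i, planted in enumerate(config.planted_mirna_spec):
        for k in range(2):
            gene = (i * 7 + k * 3) % n_genes + 1
            rows.append({"mirna_name": planted.name, "target_gene_id": f"gene{gene:04d}"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig, annotation: Sequence[AnnotationRecord]
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Replicate log2 expression matrix with planted differential genes.

    Returns ``(matrix, design, truth)``: the matrix is genes x
    (2 * n_replicates) with columns like ``mut_1``; baselines are
    N(mean, sd) per gene and replicates add N(0, expr_sigma) noise; each
    planted gene's mutant replicates are shifted by its log2 effect.
    """
    rng = config.rng(2)
    genes = [r for r in annotation if r.feature_class == "gene"]
    if not genes:
        raise ValueError("annotation contains no genes")
    gene_ids = [g.feature_id for g in genes]
    gene_chrom = {g.feature_id: g.interval.chrom for g in genes}
    mean, sd = config.expr_baseline
    baselines = rng.normal(mean, sd, size=len(genes))

    effects = pd.Series(0.0, index=gene_ids)
    by_chrom: dict[str, list[str]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g.feature_id)
    cursor: dict[str, int] = {}
    truth_rows = []
    for planted in config.planted_deg_spec:
        gene_id = planted.gene_id
        if gene_id is None:
            chrom = planted.chrom_hint or "chr1"
            pool = by_chrom[chrom]
            idx = cursor.get(chrom, 0)
            # skip genes already planted; stride 5 spreads them along the arm
            while pool[(idx * 5) % len(pool)] in set(effects[effects != 0].index):
                idx += 1
            gene_id = pool[(idx * 5) % len(pool)]
            cursor[chrom] = idx + 1
        effects[gene_id] = planted.effect
        truth_rows.append(
            {
                "gene_id": gene_id, "effect": planted.effect,
                "direction": "up" if planted.effect > 0 else "down",
                "chrom": gene_chrom[gene_id],
            }
        )

    n_rep = config.n_replicates_expr
    columns = [f"mut_{i + 1}" for i in range(n_rep)] + [f"wt_{i + 1}" for i in range(n_rep)]
    noise = rng.normal(0.0, config.expr_sigma, size=(len(genes), 2 * n_rep))
    values = baselines[:, None] + noise
    values[:, :n_rep] += effects.to_numpy()[:, None]
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=columns)
    design = pd.DataFrame(
        {
            "sample": columns,
            "genotype": ["mut"] * n_rep + ["wt"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        }
    )
    return matrix, design, GroundTruth(degs=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Bisulfite clones
# ---------------------------------------------------------------------------

def simulate_bisulfite_clones(
    config: SimulationConfig, genome: list[GenomeSequence]
) -> tuple[dict, GroundTruth]:
    """Bisulfite clone sequences per (locus, genotype) plus ground truth.

    For every clone, each reference cytosine on the top strand is
    methylated with the context-specific planted probability; methylated
    cytosines read as C, unmethylated ones convert to T with probability
    ``conversion_rate`` (else stay C, emulating incomplete conversion).
    Returns ``({locus_id: {"ref": str, "clones": {genotype: [(id, seq)]}}},
    truth)``.
    """
    from .methylation import classify_context  # local import avoids a cycle

    rng = config.rng(3)
    chrom_seq = {g.name: g.seq for g in genome}
    out: dict[str, dict] = {}
    truth_rows = []
    for planted in config.planted_meth_spec:
        iv = planted.interval
        ref = chrom_seq[iv.chrom][iv.start : iv.end]
        c_positions = [
            (i, classify_context(ref, i))
            for i in range(len(ref))
            if ref[i] == "C" and classify_context(ref, i) is not None
        ]
        if not c_positions:
            warnings.warn(f"locus {planted.locus_id} contains no cytosines")
        clones: dict[str, list[tuple[str, str]]] = {}
        for genotype in GENOTYPES:
            probs = planted.probs[genotype]
            clone_list = []
            for k in range(config.n_bisulfite_clones):
                seq = list(ref)
                for i, context in c_positions:
                    if rng.random() < probs[context]:
                        seq[i] = "C"  # methylated, protected
                    elif rng.random() < config.conversion_rate:
                        seq[i] = "T"  # converted
                    else:
                        seq[i] = "C"  # incomplete conversion
                clone_list.append((f"{planted.locus_id}_{genotype}_clone{k + 1}", "".join(seq)))
            clones[genotype] = clone_list
            for context in ("CG", "CHG", "CHH"):
                truth_rows.append(
                    {
                        "locus_id": planted.locus_id, "genotype": genotype,
                        "context": context, "planted_probability": probs[context],
                        "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                    }
                )
        out[planted.locus_id] = {"ref": ref, "interval": iv, "clones": clones}
    return out, GroundTruth(methylation=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: list[GenomeSequence]
    annotation: list[AnnotationRecord]
    libraries: dict
    catalog: list
    targets: pd.DataFrame
    expression: pd.DataFrame
    design: pd.DataFrame
    bisulfite: dict
    truth: GroundTruth


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run all four simulators and collect their outputs and ground truth."""
    config = config or SimulationConfig()
    genome, annotation = simulate_genome(config)
    libraries, truth_smrna = simulate_smrna_libraries(config, genome, annotation)
    expression, design, truth_expr = simulate_expression(config, annotation)
    bisulfite, truth_meth = simulate_bisulfite_clones(config, genome)
    truth = truth_smrna.merge(truth_expr).merge(truth_meth)
    return SimulatedStudy(
        config=config,
        genome=genome,
        annotation=annotation,
        libraries=libraries,
        catalog=mirna_catalog(config),
        targets=mirna_target_table(config),
        expression=expression,
        design=design,
        bisulfite=bisulfite,
        truth=truth,
    )
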