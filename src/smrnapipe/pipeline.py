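"""End-to-end orchestration: simulate (or load) a study, run every
analysis stage, associate the layers, and write all tables, plots, a log,
and the resolved configuration into one run directory.

A run is reproducible from its config: identical config + inputs + seed
give byte-identical tables.  Stages communicate through plain-text files
in the run directory, so the CLI subcommands can also re-run any single
stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_diff, methylation, mirna_analysis, read_mapping, smrna_clusters
from .io_formats import (
    GenomeSequence,
    Interval,
    read_annotation,
    read_fasta,
    read_smrna_library,
    revcomp,
    write_annotation,
    write_fasta,
    write_smrna_library,
    write_table,
)
from .read_mapping import ReadPlacement
from .io_formats import CollapsedRead
from .synthetic_data import GENOTYPES, SimulationConfig, simulate_study

__all__ = [
    "RunConfig",
    "run_pipeline",
    "associate_layers",
    "classify_mirna_targets",
    "PipelineError",
]

log = logging.getLogger("smrnapipe")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending record."""


# ---------------------------------------------------------------------------
# Cross-layer association
# ---------------------------------------------------------------------------

def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def associate_layers(
    clusters: pd.DataFrame,
    meth_diffs: pd.DataFrame,
    degs: pd.DataFrame,
    annotation,
    meth_loci: dict[str, Interval],
    max_gap: int = 1000,
) -> pd.DataFrame:
    """Associate differential small-RNA clusters with methylation loci and
    differentially expressed genes.

    A passing cluster associates with a locus/gene when the intervals
    overlap or lie within ``max_gap`` bp.  Among several candidates the
    nearest cluster is reported (overlap counts as distance zero), ties
    broken by the larger |fold value|.  The concordance
    flag records whether the small-RNA change and the CHH methylation
    change share a sign (the RNA-directed DNA methylation expectation).
    One record is emitted per methylation locus and per differentially
    expressed gene; records may have missing layers.
    """
    passing = clusters[clusters["passes"].astype(bool)]

    def best_cluster(iv: Interval):
        sub = passing[
            (passing["chrom"] == iv.chrom)
            & (passing["start"] < iv.end + max_gap)
            & (passing["end"] > iv.start - max_gap)
        ]
        if sub.empty:
            return None
        # nearest passing cluster wins (overlap = distance 0); ties go to
        # the larger |fold value|
        distance = np.maximum(
            0, np.maximum(iv.start - sub["end"], sub["start"] - iv.end)
        )
        order = (distance, -sub["fold_value"].abs())
        best = np.lexsort(order[::-1])[0]
        return float(sub["fold_value"].iloc[best])

    gene_ivs = {
        r.feature_id: r.interval for r in annotation if r.feature_class == "gene"
    }
    deg_dir = degs.set_index("gene_id")["direction"]

    rows = []
    meth_by_locus = (
        {k: g for k, g in meth_diffs.groupby("locus_id")} if len(meth_diffs) else {}
    )
    for locus_id, iv in sorted(meth_loci.items()):
        sub = meth_by_locus.get(locus_id)
        deltas = (
            {r["context"]: r["delta_points"] for _, r in sub.iterrows()}
            if sub is not None
            else {}
        )
        smrna = best_cluster(iv)
        host_gene = next(
            (g for g, giv in gene_ivs.items() if giv.overlaps(iv)), None
        )
        expr = deg_dir.get(host_gene, "missing") if host_gene else "missing"
        chh = deltas.get("CHH")
        concordant = (
            _sign(smrna) == _sign(chh)
            if smrna is not None and chh is not None and not np.isnan(chh)
            else None
        )
        rows.append(
            {
                "record_id": locus_id,
                "layer": "methylation_locus",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "smrna_delta": smrna if smrna is not None else np.nan,
                "meth_delta_CG": deltas.get("CG", np.nan),
                "meth_delta_CHG": deltas.get("CHG", np.nan),
                "meth_delta_CHH": deltas.get("CHH", np.nan),
                "expr_direction": expr,
                "concordance_flag": concordant,
            }
        )
    for gene_id, direction in deg_dir.items():
        if direction == "unchanged":
            continue
        iv = gene_ivs.get(gene_id)
        if iv is None:
            continue
        smrna = best_cluster(iv)
        rows.append(
            {
                "record_id": gene_id,
                "layer": "deg",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "smrna_delta": smrna if smrna is not None else np.nan,
                "meth_delta_CG": np.nan,
                "meth_delta_CHG": np.nan,
                "meth_delta_CHH": np.nan,
                "expr_direction": direction,
                "concordance_flag": None,
            }
        )
    return pd.DataFrame(rows)


_RELATION = {
    ("down", "up"): "I",
    ("up", "down"): "II",
    ("up", "up"): "III",
    ("down", "down"): "IV",
}


def classify_mirna_targets(
    quants: pd.DataFrame, degs: pd.DataFrame, target_table: pd.DataFrame
) -> pd.DataFrame:
    """Classify each (miRNA, predicted target) pair into relation types.

    I: miRNA down & target up; II: miRNA up & target down; III: both up;
    IV: both down; ``none`` whenever either side is unchanged or the
    target is absent from the expression results.
    """
    mirna_dir = quants.set_index("name")["pattern"]
    deg_dir = degs.set_index("gene_id")["direction"]
    rows = []
    for _, pair in target_table.iterrows():
        m_dir = mirna_dir.get(pair["mirna_name"], "missing")
        t_dir = deg_dir.get(pair["target_gene_id"], "missing")
        relation = _RELATION.get((m_dir, t_dir), "none")
        rows.append(
            {
                "mirna_name": pair["mirna_name"],
                "target_gene_id": pair["target_gene_id"],
                "mirna_direction": m_dir,
                "target_direction": t_dir,
                "relation_type": relation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters; serialized with the run outputs."""

    seed: int = 1
    outdir: str = "smrnapipe_run"
    # simulation scale
    n_chroms: int = 4
    chrom_length: int = 200_000
    n_library_reads: int = 200_000
    n_replicates_expr: int = 3
    n_bisulfite_clones: int = 30
    conversion_rate: float = 0.995
    # cluster analysis
    window: int = 100
    size_min: int = 18
    size_max: int = 26
    sirna_min: int = 20
    sirna_max: int = 24
    fold_cutoff: float = 4.0
    pseudocount: float = 0.5
    # miRNA analysis
    mirna_ratio_cutoff: float = 2.0
    hairpin_min_reads: int = 5
    hairpin_window: int = 160
    hairpin_max_fold_score: float = -15.0
    # expression
    alpha: float = 0.05
    min_lfc: float = 1.0
    deg_method: str = "moderated"
    # association
    max_gap: int = 1000
    # mapping
    index_k: int = 12
    make_plots: bool = True

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in sorted(fields(self), key=lambda f: f.name):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise PipelineError(f"config line {lineno} is not key=value: {line!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                values[key] = value
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for key, value in values.items():
            if key not in known:
                raise PipelineError(f"unknown config key {key!r}")
            ftype = known[key].type
            if ftype == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            n_chroms=self.n_chroms,
            chrom_length=self.chrom_length,
            n_library_reads=self.n_library_reads,
            n_replicates_expr=self.n_replicates_expr,
            n_bisulfite_clones=self.n_bisulfite_clones,
            conversion_rate=self.conversion_rate,
            window=self.window,
        )

    def hairpin_criteria(self) -> mirna_analysis.HairpinCriteria:
        return mirna_analysis.HairpinCriteria(
            min_reads=self.hairpin_min_reads,
            window=self.hairpin_window,
            max_fold_score=self.hairpin_max_fold_score,
            merge_distance=self.hairpin_window,
        )


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

class PipelineRun:
    """Stage runner over a run directory; see :func:`run_pipeline`."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.inputs = self.outdir / "inputs"

    # -- stage: simulate -------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config
        self.inputs.mkdir(parents=True, exist_ok=True)
        study = simulate_study(cfg.simulation_config())
        write_fasta(((g.name, g.seq) for g in study.genome), self.inputs / "genome.fa")
        write_annotation(study.annotation, self.inputs / "annotation.gff3")
        for genotype in GENOTYPES:
            write_smrna_library(
                study.libraries[genotype], self.inputs / f"smrna_{genotype}.fa"
            )
            log.info(
                "simulate: %s library %d clean reads (%d unique)",
                genotype,
                study.libraries[genotype].total_reads,
                len(study.libraries[genotype]),
            )
        write_fasta(
            ((e.name, e.mature_seq) for e in study.catalog),
            self.inputs / "mirna_catalog.fa",
        )
        study.targets.to_csv(self.inputs / "mirna_targets.tsv", sep="\t", index=False)
        study.expression.to_csv(self.inputs / "expression.tsv", sep="\t", float_format="%.6g")
        study.design.to_csv(self.inputs / "design.tsv", sep="\t", index=False)
        bs_dir = self.inputs / "bisulfite"
        bs_dir.mkdir(exist_ok=True)
        manifest = []
        for locus_id, entry in study.bisulfite.items():
            iv = entry["interval"]
            write_fasta([(locus_id, entry["ref"])], bs_dir / f"{locus_id}_ref.fa")
            for genotype in GENOTYPES:
                write_fasta(entry["clones"][genotype], bs_dir / f"{locus_id}_{genotype}.fa")
            manifest.append(
                {
                    "locus_id": locus_id, "chrom": iv.chrom, "start": iv.start,
                    "end": iv.end,
                    "ref_file": f"{locus_id}_ref.fa",
                    "clones_mut": f"{locus_id}_mut.fa",
                    "clones_wt": f"{locus_id}_wt.fa",
                }
            )
        pd.DataFrame(manifest).to_csv(bs_dir / "manifest.tsv", sep="\t", index=False)
        truth_dir = self.inputs / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name in ("clusters", "mirnas", "novel", "degs", "methylation"):
            df = getattr(study.truth, name)
            if not df.empty:
                write_table(df, truth_dir / f"{name}.tsv")

    # -- loading helpers -------------------------------------------------
    def load_genome(self) -> list[GenomeSequence]:
        return [GenomeSequence(n, s) for n, s in read_fasta(self.inputs / "genome.fa")]

    def load_annotation(self, genome=None):
        sizes = {g.name: g.length for g in genome} if genome else None
        return read_annotation(self.inputs / "annotation.gff3", "gff3", sizes)

    def load_libraries(self) -> dict:
        return {
            g: read_smrna_library(self.inputs / f"smrna_{g}.fa", "fasta")
            for g in GENOTYPES
        }

    def load_placements(self, genotype: str, genome) -> list[ReadPlacement]:
        chrom_seq = {g.name: g.seq for g in genome}
        path = self.outdir / "map" / f"placements_{genotype}.bed"
        by_read: dict[str, ReadPlacement] = {}
        with open(path) as fh:
            for line in fh:
                chrom, start, end, name, score, strand = line.split("\t")
                start, end = int(start), int(end)
                strand = strand.strip()
                hit = Interval(chrom, start, end, strand)
                if name not in by_read:
                    seq = chrom_seq[chrom][start:end]
                    if strand == "-":
                        seq = revcomp(seq)
                    by_read[name] = ReadPlacement(CollapsedRead(seq, int(score)), [])
                by_read[name].hits.append(hit)
        return list(by_read.values())

    # -- stage: map ------------------------------------------------------
    def map_stage(self) -> None:
        cfg = self.config
        genome = self.load_genome()
        annotation = self.load_annotation(genome)
        libraries = self.load_libraries()
        index = read_mapping.build_index(genome, k=cfg.index_k)
        map_dir = self.outdir / "map"
        map_dir.mkdir(parents=True, exist_ok=True)
        for genotype in GENOTYPES:
            placements = read_mapping.map_reads(libraries[genotype], index)
            mapped = sum(1 for p in placements if p.n_hits)
            log.info(
                "map: %s %d/%d unique reads mapped", genotype, mapped, len(placements)
            )
            read_mapping.placements_to_bed(
                placements, map_dir / f"placements_{genotype}.bed"
            )
            write_table(
                read_mapping.profile_sizes(libraries[genotype]).to_frame(),
                map_dir / f"size_profile_{genotype}.tsv",
            )
            write_table(
                read_mapping.profile_categories(placements, annotation).to_frame(),
                map_dir / f"category_profile_{genotype}.tsv",
            )

    # -- stage: clusters -------------------------------------------------
    def clusters_stage(self) -> None:
        cfg = self.config
        genome = self.load_genome()
        libraries = self.load_libraries()
        out = self.outdir / "clusters"
        out.mkdir(parents=True, exist_ok=True)
        for label, size_range in (
            ("18_26", (cfg.size_min, cfg.size_max)),
            ("20_24", (cfg.sirna_min, cfg.sirna_max)),
        ):
            profiles = {}
            for genotype in GENOTYPES:
                placements = self.load_placements(genotype, genome)
                counted = smrna_clusters.count_windows(
                    placements, genome, size_range, cfg.window
                )
                profiles[genotype] = smrna_clusters.normalize_rpm(
                    counted, libraries[genotype].total_reads
                )
            clusters = smrna_clusters.call_differential(
                [profiles["mut"]], [profiles["wt"]], cfg.fold_cutoff, cfg.pseudocount
            )
            write_table(clusters, out / f"clusters_{label}.tsv")
            log.info(
                "clusters[%s]: %d/%d windows pass the %.0f-fold cut-off",
                label, int(clusters["passes"].sum()), len(clusters), cfg.fold_cutoff,
            )
            if label == "18_26":
                smrna_clusters.clusters_to_bed(clusters, out / "clusters.bed")
                track_rows = []
                for chrom, track in smrna_clusters.chromosome_track(clusters).items():
                    track = track.assign(chrom=chrom)
                    track_rows.append(track)
                pd.concat(track_rows).to_csv(
                    out / "track.tsv", sep="\t", index=False, float_format="%.6g"
                )

    # -- stage: mirna ----------------------------------------------------
    def mirna_stage(self) -> None:
        cfg = self.config
        genome = self.load_genome()
        annotation = self.load_annotation(genome)
        libraries = self.load_libraries()
        catalog = mirna_analysis.read_catalog(self.inputs / "mirna_catalog.fa")
        out = self.outdir / "mirna"
        out.mkdir(parents=True, exist_ok=True)
        quants = mirna_analysis.quantify_known(
            libraries["mut"], libraries["wt"], catalog,
            alpha=cfg.alpha, ratio_cutoff=cfg.mirna_ratio_cutoff,
        )
        write_table(quants, out / "quant.tsv")
        pattern_counts = quants["pattern"].value_counts()
        log.info(
            "mirna: %d up, %d down, %d unchanged of %d catalogue entries",
            pattern_counts.get("up", 0), pattern_counts.get("down", 0),
            pattern_counts.get("unchanged", 0), len(quants),
        )
        write_table(mirna_analysis.family_divergence(quants), out / "families.tsv")
        placements = self.load_placements("mut", genome) + self.load_placements(
            "wt", genome
        )
        candidates = mirna_analysis.discover_novel(
            placements, annotation, genome, cfg.hairpin_criteria()
        )
        log.info("mirna: %d novel hairpin candidates", len(candidates))
        write_table(mirna_analysis.candidates_to_frame(candidates), out / "novel_candidates.tsv")
        mirna_analysis.write_structures(candidates, out / "novel_structures.txt")

    # -- stage: expression -----------------------------------------------
    def expression_stage(self) -> None:
        cfg = self.config
        annotation = self.load_annotation()
        matrix = pd.read_csv(self.inputs / "expression.tsv", sep="\t", index_col=0)
        design = pd.read_csv(self.inputs / "design.tsv", sep="\t")
        gene_chrom = {
            r.feature_id: r.interval.chrom
            for r in annotation
            if r.feature_class == "gene"
        }
        out = self.outdir / "expression"
        out.mkdir(parents=True, exist_ok=True)
        degs = expression_diff.call_degs(
            matrix, design, alpha=cfg.alpha, min_lfc=cfg.min_lfc,
            method=cfg.deg_method, gene_chrom=gene_chrom,
        )
        write_table(degs, out / "degs.tsv")
        n_up = int((degs["direction"] == "up").sum())
        n_down = int((degs["direction"] == "down").sum())
        log.info("expression: %d up, %d down of %d genes", n_up, n_down, len(degs))
        if n_up + n_down:
            test = expression_diff.chrom_distribution_test(
                degs, pd.Series(gene_chrom)
            )
            rows = [
                {
                    "chrom": chrom, "observed": test.observed[chrom],
                    "expected": test.expected[chrom],
                }
                for chrom in test.observed
            ]
            report = pd.DataFrame(rows)
            report["statistic"] = test.statistic
            report["df"] = test.df
            report["p_value"] = test.p_value
            write_table(report, out / "chrom_chisq.tsv")
        go_rows = []
        for rec in annotation:
            if rec.feature_class != "gene":
                continue
            for term in rec.attributes.get("go_terms", "").split(","):
                if term:
                    go_rows.append({"gene_id": rec.feature_id, "category": term})
        if go_rows:
            write_table(
                expression_diff.go_proportions(degs, pd.DataFrame(go_rows)),
                out / "go_proportions.tsv",
            )

    # -- stage: methylation ----------------------------------------------
    def methylation_stage(self) -> None:
        bs_dir = self.inputs / "bisulfite"
        manifest = pd.read_csv(bs_dir / "manifest.tsv", sep="\t")
        out = self.outdir / "methylation"
        out.mkdir(parents=True, exist_ok=True)
        summaries, diffs, site_rows = [], [], []
        for _, row in manifest.iterrows():
            locus_id = row["locus_id"]
            ref = read_fasta(bs_dir / row["ref_file"])[0][1]
            per_genotype = {}
            for genotype in GENOTYPES:
                clones = read_fasta(bs_dir / row[f"clones_{genotype}"])
                alignments = [
                    methylation.align_clone(seq, ref, clone_id=name)
                    for name, seq in clones
                ]
                rejected = sum(1 for a in alignments if not a.accepted)
                if rejected:
                    log.info(
                        "methylation: %s %s: %d clones rejected",
                        locus_id, genotype, rejected,
                    )
                sites = methylation.call_sites(alignments, ref, locus_id)
                per_genotype[genotype] = methylation.summarize_locus(sites, genotype)
                summaries.append(per_genotype[genotype].to_frame())
                for site in sites:
                    for clone_id, state in site.states.items():
                        site_rows.append(
                            {
                                "locus_id": locus_id, "genotype": genotype,
                                "position": site.position, "context": site.context,
                                "clone_id": clone_id, "state": state,
                            }
                        )
                if genotype == "mut":
                    methylation.lollipop_report(sites, out / f"lollipop_{locus_id}_mut.txt")
            diffs.append(
                methylation.diff_genotypes(per_genotype["mut"], per_genotype["wt"])
            )
        write_table(pd.concat(summaries, ignore_index=True), out / "summary.tsv")
        write_table(pd.concat(diffs, ignore_index=True), out / "diffs.tsv")
        write_table(pd.DataFrame(site_rows), out / "sites.tsv")

    # -- stage: associate ------------------------------------------------
    def associate_stage(self) -> None:
        cfg = self.config
        genome = self.load_genome()
        annotation = self.load_annotation(genome)
        clusters = pd.read_csv(self.outdir / "clusters" / "clusters_18_26.tsv", sep="\t")
        meth_diffs = pd.read_csv(self.outdir / "methylation" / "diffs.tsv", sep="\t")
        degs = pd.read_csv(self.outdir / "expression" / "degs.tsv", sep="\t")
        quants = pd.read_csv(self.outdir / "mirna" / "quant.tsv", sep="\t")
        targets = pd.read_csv(self.inputs / "mirna_targets.tsv", sep="\t")
        manifest = pd.read_csv(self.inputs / "bisulfite" / "manifest.tsv", sep="\t")
        meth_loci = {
            r["locus_id"]: Interval(r["chrom"], r["start"], r["end"])
            for _, r in manifest.iterrows()
        }
        out = self.outdir / "associate"
        out.mkdir(parents=True, exist_ok=True)
        associations = associate_layers(
            clusters, meth_diffs, degs, annotation, meth_loci, cfg.max_gap
        )
        write_table(associations, out / "associations.tsv")
        relations = classify_mirna_targets(quants, degs, targets)
        write_table(relations, out / "mirna_target_relations.tsv")
        log.info(
            "associate: %d association records, %d miRNA-target pairs",
            len(associations), len(relations),
        )

    # -- stage: plots ----------------------------------------------------
    def plots_stage(self) -> None:
        from . import plotting

        out = self.outdir / "plots"
        out.mkdir(parents=True, exist_ok=True)
        sizes = {
            g: pd.read_csv(self.outdir / "map" / f"size_profile_{g}.tsv", sep="\t")
            for g in GENOTYPES
        }
        plotting.plot_size_profiles(sizes, out / "size_distribution.png")
        track = pd.read_csv(self.outdir / "clusters" / "track.tsv", sep="\t")
        plotting.plot_chromosome_tracks(track, out / "cluster_tracks.png")
        diffs = pd.read_csv(self.outdir / "methylation" / "diffs.tsv", sep="\t")
        summary = pd.read_csv(self.outdir / "methylation" / "summary.tsv", sep="\t")
        plotting.plot_methylation_panel(summary, diffs, out / "methylation_panel.png")

    STAGES = (
        "simulate", "map", "clusters", "mirna", "expression", "methylation",
        "associate", "plots",
    )

    def run(self, stages=None) -> Path:
        stages = list(stages or self.STAGES)
        if not self.config.make_plots and "plots" in stages:
            stages.remove("plots")
        self.outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(self.outdir / "pipeline.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        try:
            self.config.to_file(self.outdir / "run_config.txt")
            for stage in stages:
                method = {
                    "simulate": self.simulate,
                    "map": self.map_stage,
                    "clusters": self.clusters_stage,
                    "mirna": self.mirna_stage,
                    "expression": self.expression_stage,
                    "methylation": self.methylation_stage,
                    "associate": self.associate_stage,
                    "plots": self.plots_stage,
                }[stage]
                try:
                    method()
                except PipelineError:
                    raise
                except Exception as exc:  # noqa: BLE001 - annotate with stage
                    raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        finally:
            log.removeHandler(handler)
            handler.close()
        return self.outdir


def run_pipeline(config: RunConfig, stages=None) -> Path:
    """Run the full analysis (or selected stages) into ``config.outdir``."""
    return PipelineRun(config).run(stages)
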