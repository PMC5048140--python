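"""End-to-end pipeline driver.

`RunConfig` captures every input path, threshold and seed; `run_pipeline`
executes preprocess -> popgen -> indices -> inference (-> similarity when a
second species is configured) and writes profile TSVs, the permutation-null
report and optional plots. All counts of filtered genes and every seed are
logged, so a run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import preprocess
from .expression import ExpressionMatrix
from .indices import rel
from .io import read_gene_table, read_hit_table, read_lineage_map
from .model import StageIndexModel
from .phylostrata import LineageMap, assign_phylostrata
from .popgen import segregating_sites, theta_table
from .similarity import OrthologMap, best_matching_stage, reciprocal_best_hits, stage_similarity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seed for one pipeline run."""

    counts: str
    genes: str
    outdir: str
    stage_order: list[str] | None = None
    # age assignment
    hits: str | None = None
    lineage: str | None = None
    focal_species: str = "focal"
    evalue_cutoff: float = 1e-3
    # popgen
    vcf: str | None = None
    bed: str | None = None
    # preprocessing
    tmm: bool = True
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    correlation_filter: bool = False
    r_threshold: float = 0.99
    max_length_bp: int = 500
    min_peak_expression: float = 10_000.0
    # indices & inference
    indices: list[str] = field(default_factory=lambda: ["TAI"])
    exclude_ranks: list[int] = field(default_factory=list)
    n_boot: int = 1000
    n_perm: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    # similarity
    counts_b: str | None = None
    hits_ab: str | None = None
    hits_ba: str | None = None
    orthologs: str | None = None  # precomputed one-to-one pairs (gene_a, gene_b)
    rbh_evalue_cutoff: float = 1e-5
    plots: bool = False

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must lie in (0, 1]")
        if self.evalue_cutoff <= 0 or self.rbh_evalue_cutoff <= 0:
            raise ValueError("e-value cutoffs must be positive")
        for kind in self.indices:
            if kind not in ("TAI", "TPI"):
                raise ValueError(f"unknown index {kind!r}")
        if "TPI" in self.indices and not (self.vcf and self.bed):
            raise ValueError("TPI requires vcf and bed inputs")
        if "TAI" in self.indices and not (self.hits and self.lineage):
            raise ValueError("TAI requires hits and lineage inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns the dict of output paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    counts = ExpressionMatrix.from_tsv(config.counts)
    if config.stage_order:
        missing = set(config.stage_order) - set(counts.stage_ids)
        if missing:
            raise ValueError(f"stage_order references unknown stages: {sorted(missing)}")
        counts = ExpressionMatrix(counts.data[config.stage_order], counts.kind)
    genes = read_gene_table(config.genes)
    logger.info("loaded %d genes x %d stages", counts.n_genes, counts.n_stages)

    # ---------------- preprocessing -------------------------------------
    expr = preprocess.length_weight(counts, genes)
    if config.tmm:
        expr = preprocess.tmm_normalize(expr, config.logratio_trim, config.abs_trim)
    if config.correlation_filter:
        expr, report = preprocess.filter_correlated_duplicates(
            expr, genes, config.r_threshold, config.max_length_bp, config.min_peak_expression)
        logger.info("correlation filter removed %d genes", len(report.removed))
        report.to_tsv(outdir / "correlation_filter_removed.tsv")
        outputs["correlation_filter"] = outdir / "correlation_filter_removed.tsv"

    # ---------------- covariates ----------------------------------------
    if config.hits and config.lineage:
        lineage = LineageMap.from_frame(read_lineage_map(config.lineage), config.focal_species)
        ranks = assign_phylostrata(read_hit_table(config.hits), lineage,
                                   counts.gene_ids, config.evalue_cutoff)
        genes = genes.merge(ranks.rename("phylostratum"), left_on="gene_id", right_index=True,
                            how="left", suffixes=("_input", ""))
        ranks.to_csv(outdir / "phylostrata.tsv", sep="\t", header=["rank"])
        outputs["phylostrata"] = outdir / "phylostrata.tsv"
    if config.vcf and config.bed:
        counts_tbl = segregating_sites(config.vcf, config.bed)
        genes = theta_table(counts_tbl, genes)
        genes.to_csv(outdir / "theta.tsv", sep="\t", index=False)
        outputs["theta"] = outdir / "theta.tsv"

    # ---------------- indices + inference -------------------------------
    for kind in config.indices:
        model = StageIndexModel(expr, genes, index=kind,
                                exclude_ranks=config.exclude_ranks if kind == "TAI" else None)
        results = model.fit(n_boot=config.n_boot, n_perm=config.n_perm,
                            level=config.ci_level, seed=config.seed)
        profile_path = outdir / f"{kind.lower()}_profile.tsv"
        results.profile.to_tsv(profile_path)
        results.null.to_text(outdir / f"{kind.lower()}_null.txt")
        outputs[f"{kind.lower()}_profile"] = profile_path
        outputs[f"{kind.lower()}_null"] = outdir / f"{kind.lower()}_null.txt"
        logger.info("%s: combined p = %.3g, lowest at %s",
                    kind, results.p_combined, results.argmin_stage())
        if config.plots:
            import matplotlib.pyplot as plt
            ax = results.plot()
            ax.figure.savefig(outdir / f"{kind.lower()}_profile.svg")
            plt.close(ax.figure)

    if "TAI" in config.indices:
        rel_grid = rel(expr, genes)
        rel_grid.to_tsv(outdir / "rel.tsv")
        outputs["rel"] = outdir / "rel.tsv"

    # ---------------- similarity ----------------------------------------
    if config.counts_b and (config.orthologs or (config.hits_ab and config.hits_ba)):
        if config.orthologs:
            orthologs = OrthologMap.from_tsv(config.orthologs)
        else:
            orthologs = reciprocal_best_hits(read_hit_table(config.hits_ab),
                                             read_hit_table(config.hits_ba),
                                             config.rbh_evalue_cutoff)
        counts_b = ExpressionMatrix.from_tsv(config.counts_b)
        # raw counts on both sides: Spearman only sees ranks, and the two
        # species must be in the same units (no CDS lengths for species B)
        grid = stage_similarity(counts, counts_b, orthologs)
        grid.to_tsv(outdir / "similarity.tsv")
        best_matching_stage(grid).to_csv(outdir / "best_matching_stage.tsv", sep="\t")
        outputs["similarity"] = outdir / "similarity.tsv"
        outputs["best_matching_stage"] = outdir / "best_matching_stage.tsv"

    config.to_yaml(outdir / "run_config.yaml")
    outputs["config"] = outdir / "run_config.yaml"
    return outputs
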