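"""Expression-weighted transcriptome indices.

Each developmental stage s is summarised by a weighted mean of a per-gene
evolutionary covariate, weighted by that stage's expression:

* TAI_s = sum_i ps_i e_is / sum_i e_is — the transcriptome age index, with
  ps_i the phylostratum rank of gene i (low = old). A low TAI means the
  stage's transcriptome is dominated by evolutionarily old genes.
* TPI_s = 1000 * sum_i theta_i e_is / sum_i e_is — the transcriptome
  polymorphism index, with theta_i the per-site Watterson diversity of gene
  i; the factor 1000 reports theta per kilobase. A low TPI means the stage
  expresses genes that are conserved within the population.
* REL(ps, s) — per-phylostratum mean partial concentration, min-max scaled
  to [0, 1] across stages, showing when each age class peaks.

Both TAI and TPI depend only on the composition of the transcriptome at a
stage: rescaling a stage's whole expression column leaves them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

INDEX_KINDS = ("TAI", "TPI")
#: gene-table column holding the covariate of each index
COVARIATE_COLUMN = {"TAI": "phylostratum", "TPI": "theta"}
#: reporting scale (theta is reported per kilobase)
INDEX_SCALE = {"TAI": 1.0, "TPI": 1e3}


@dataclass
class StageIndexProfile:
    """Per-stage index values with optional uncertainty annotations."""

    stage_ids: list[str]
    values: np.ndarray
    index_kind: str
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    p_per_stage: np.ndarray | None = None
    p_combined: float | None = None

    def __post_init__(self):
        if len(self.values) != len(self.stage_ids):
            raise ValueError("one value per stage required")
        if self.ci_low is not None and self.ci_high is not None:
            if not (
                (self.ci_low <= self.values + 1e-12).all()
                and (self.values <= self.ci_high + 1e-12).all()
            ):
                raise ValueError("confidence bounds must bracket the point estimate")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.stage_ids, name="stage"),
                         name=self.index_kind)

    def as_frame(self) -> pd.DataFrame:
        frame = self.as_series().to_frame()
        if self.ci_low is not None:
            frame["ci_low"] = self.ci_low
            frame["ci_high"] = self.ci_high
        if self.p_per_stage is not None:
            frame["p_value"] = self.p_per_stage
        return frame

    def argmin_stage(self) -> str:
        return self.stage_ids[int(np.argmin(self.values))]

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t")


@dataclass
class RelMatrix:
    """Phylostratum x stage grid of relative expression levels in [0, 1].

    ``fbar`` holds the underlying mean partial concentrations; rows of
    ``rel`` with no dynamics (constant fbar) are all-NaN and listed in
    ``undefined_rows``.
    """

    rel: pd.DataFrame
    fbar: pd.DataFrame
    undefined_rows: list[int] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.rel.to_csv(path, sep="\t", index_label="phylostratum")


# ----------------------------------------------------------------------

def _covariate_vector(expr: ExpressionMatrix, genes: pd.DataFrame, column: str) -> np.ndarray:
    table = genes.set_index("gene_id")
    missing = [g for g in expr.gene_ids if g not in table.index]
    if missing:
        raise KeyError(f"genes missing from gene table: {missing[:5]}")
    cov = table.loc[expr.gene_ids, column]
    if cov.isna().any():
        bad = cov.index[cov.isna()].tolist()
        raise ValueError(f"gene table column {column!r} missing for genes: {bad[:5]}")
    cov = cov.to_numpy(dtype=float)
    if column == "theta" and (cov < 0).any():
        raise ValueError("negative theta values")
    return cov


def drop_silent_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero expression at every stage (they carry no
    weight in any index and break per-phylostratum means)."""
    silent = (expr.values.sum(axis=1) == 0)
    if silent.any():
        logger.info("dropping %d genes with zero expression at every stage", int(silent.sum()))
        keep = [g for g, s in zip(expr.gene_ids, silent) if not s]
        return expr.subset_genes(keep)
    return expr


def weighted_stage_index(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Column-wise expression-weighted mean of the covariate.

    ``values`` is genes x stages, ``covariate`` length genes; stages with a
    zero expression total are the caller's responsibility.
    """
    totals = values.sum(axis=0)
    return (covariate @ values) / totals


def _check_stage_totals(expr: ExpressionMatrix) -> None:
    totals = expr.values.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(expr.stage_ids, totals) if t <= 0]
        raise ValueError(f"stage(s) with zero total expression: {bad}")


def tai(expr: ExpressionMatrix, genes: pd.DataFrame) -> StageIndexProfile:
    """Transcriptome age index per stage (expression-weighted mean rank)."""
    expr = drop_silent_genes(expr)
    _check_stage_totals(expr)
    ranks = _covariate_vector(expr, genes, "phylostratum")
    return StageIndexProfile(expr.stage_ids, weighted_stage_index(expr.values, ranks), "TAI")


def tai_excluding(expr: ExpressionMatrix, genes: pd.DataFrame, excluded_ranks) -> StageIndexProfile:
    """TAI restricted to genes whose phylostratum is not in ``excluded_ranks``
    (e.g. dropping the species-specific stratum to ask whether young genes
    drive the pattern)."""
    excluded = set(excluded_ranks)
    table = genes.set_index("gene_id")["phylostratum"]
    keep = [g for g in expr.gene_ids if int(table.loc[g]) not in excluded]
    if not keep:
        raise ValueError("exclusion removes every gene")
    sub = expr.subset_genes(keep)
    if (sub.values.sum(axis=0) <= 0).any():
        raise ValueError("exclusion empties at least one stage")
    return tai(sub, genes)


def tpi(expr: ExpressionMatrix, genes: pd.DataFrame, kilo_scale: bool = True) -> StageIndexProfile:
    """Transcriptome polymorphism index per stage (expression-weighted mean
    per-site theta, x1000 for a per-kilobase scale)."""
    expr = drop_silent_genes(expr)
    _check_stage_totals(expr)
    theta = _covariate_vector(expr, genes, "theta")
    scale = 1e3 if kilo_scale else 1.0
    return StageIndexProfile(expr.stage_ids, scale * weighted_stage_index(expr.values, theta), "TPI")


def partial_concentrations(expr: ExpressionMatrix) -> pd.DataFrame:
    """f_is = e_is / sum_j e_js — each gene's share of the stage transcriptome."""
    _check_stage_totals(expr)
    return expr.data / expr.data.sum(axis=0)


def rel(expr: ExpressionMatrix, genes: pd.DataFrame) -> RelMatrix:
    """Relative expression level per phylostratum and stage.

    The mean partial concentration of each phylostratum's genes is min-max
    normalized across stages: every non-constant row attains 0 at its
    minimum stage and 1 at its maximum stage. A constant row has no dynamics
    to normalize; it is emitted as NaN with a warning.
    """
    if expr.n_stages < 2:
        raise ValueError("REL needs at least 2 stages")
    expr = drop_silent_genes(expr)
    ranks = _covariate_vector(expr, genes, "phylostratum").astype(int)
    conc = partial_concentrations(expr)
    fbar = conc.groupby(ranks).mean()
    fbar.index.name = "phylostratum"

    span = fbar.max(axis=1) - fbar.min(axis=1)
    undefined = fbar.index[span == 0].tolist()
    if undefined:
        logger.warning("REL undefined (constant mean concentration) for phylostrata %s", undefined)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_grid = fbar.sub(fbar.min(axis=1), axis=0).div(span.replace(0, np.nan), axis=0)
    return RelMatrix(rel=rel_grid, fbar=fbar, undefined_rows=undefined)


def minmax_per_gene(expr: ExpressionMatrix, gene_subset) -> pd.DataFrame:
    """Min-max normalize each gene's profile to [0, 1] across stages.

    The stage of maximal expression maps to 1 and the minimum to 0 (the
    normalization behind expression-timing panels). Constant genes have no
    range and come back as NaN rows.
    """
    if expr.n_stages < 2:
        raise ValueError("min-max normalization needs at least 2 stages")
    missing = set(gene_subset) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"unknown genes: {sorted(missing)[:5]}")
    sub = expr.data.loc[list(gene_subset)]
    lo = sub.min(axis=1)
    span = sub.max(axis=1) - lo
    flagged = span.index[span == 0].tolist()
    if flagged:
        logger.warning("constant expression profile for genes %s; emitting NaN", flagged[:5])
    return sub.sub(lo, axis=0).div(span.replace(0, np.nan), axis=0)
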