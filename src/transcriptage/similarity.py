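"""Cross-species developmental-stage similarity.

One-to-one orthologs are called by reciprocal best hit (RBH): gene a of
species A pairs with gene b of species B iff b is a's best qualifying hit
and a is b's. Transcriptome similarity between stage s_a and stage s_b is
then Spearman's rho over the ortholog pairs' expression, computed on
average-tied ranks (exact under ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """One-to-one gene pairs between two species with provenance scores."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b, evalue_ab, bitscore_ab, evalue_ba, bitscore_ba

    def __post_init__(self):
        if self.pairs["gene_a"].duplicated().any() or self.pairs["gene_b"].duplicated().any():
            raise ValueError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str}))


@dataclass
class SimilarityGrid:
    """Stages-of-A x stages-of-B matrix of Spearman rho."""

    rho: pd.DataFrame
    n_orthologs: int

    def to_tsv(self, path) -> None:
        self.rho.to_csv(path, sep="\t", index_label="stage_a")


def _best_hits(hits: pd.DataFrame, evalue_cutoff: float) -> pd.Series:
    """Best subject per query: lowest e-value, then highest bitscore, then
    lexicographically smallest subject id."""
    qualifying = hits.loc[hits["evalue"] <= evalue_cutoff]
    if qualifying.empty:
        return pd.Series(dtype=str)
    ordered = qualifying.sort_values(
        ["query_gene", "evalue", "bitscore", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ordered.drop_duplicates("query_gene", keep="first")
    return best.set_index("query_gene")["subject_id"]


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_cutoff: float = 1e-5,
) -> OrthologMap:
    """Call one-to-one orthologs by reciprocal best hit at the given cutoff."""
    if hits_ab.empty or hits_ba.empty:
        raise ValueError("both hit tables must be non-empty")
    best_ab = _best_hits(hits_ab, evalue_cutoff)
    best_ba = _best_hits(hits_ba, evalue_cutoff)

    score_ab = hits_ab.set_index(["query_gene", "subject_id"])[["evalue", "bitscore"]]
    score_ba = hits_ba.set_index(["query_gene", "subject_id"])[["evalue", "bitscore"]]

    rows = []
    for gene_a, gene_b in best_ab.items():
        if best_ba.get(gene_b) == gene_a:
            ab = score_ab.loc[(gene_a, gene_b)]
            ba = score_ba.loc[(gene_b, gene_a)]
            if isinstance(ab, pd.DataFrame):
                ab = ab.sort_values(["evalue", "bitscore"], ascending=[True, False]).iloc[0]
            if isinstance(ba, pd.DataFrame):
                ba = ba.sort_values(["evalue", "bitscore"], ascending=[True, False]).iloc[0]
            rows.append((gene_a, gene_b, ab["evalue"], ab["bitscore"], ba["evalue"], ba["bitscore"]))
    pairs = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "evalue_ab", "bitscore_ab", "evalue_ba", "bitscore_ba"]
    )
    return OrthologMap(pairs)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation via Pearson on average-tied ranks."""
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def stage_similarity(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orthologs: OrthologMap,
) -> SimilarityGrid:
    """All-stages-by-all-stages Spearman similarity over ortholog pairs.

    Ortholog pairs with zero expression at every stage in either species
    are dropped (all-tie rank vectors distort the correlation). A constant
    stage column yields NaN cells with a warning.
    """
    pairs = orthologs.pairs
    usable = pairs.loc[
        pairs["gene_a"].isin(expr_a.gene_ids) & pairs["gene_b"].isin(expr_b.gene_ids)
    ]
    a = expr_a.data.loc[usable["gene_a"]].to_numpy()
    b = expr_b.data.loc[usable["gene_b"]].to_numpy()
    expressed = (a.sum(axis=1) > 0) & (b.sum(axis=1) > 0)
    n_dropped = int((~expressed).sum())
    if n_dropped:
        logger.info("dropping %d ortholog pairs silent in one species", n_dropped)
    a, b = a[expressed], b[expressed]
    if a.shape[0] < 3:
        raise ValueError("need at least 3 expressed ortholog pairs")

    grid = np.empty((expr_a.n_stages, expr_b.n_stages))
    for i in range(expr_a.n_stages):
        for j in range(expr_b.n_stages):
            grid[i, j] = spearman_rho(a[:, i], b[:, j])
    if np.isnan(grid).any():
        logger.warning("constant stage column(s) produced NaN similarity cells")
    rho = pd.DataFrame(grid, index=pd.Index(expr_a.stage_ids, name="stage_a"),
                       columns=pd.Index(expr_b.stage_ids, name="stage_b"))
    return SimilarityGrid(rho=rho, n_orthologs=int(a.shape[0]))


def best_matching_stage(grid: SimilarityGrid) -> pd.Series:
    """For each stage of species A, the species-B stage of maximal rho.

    Ties resolve to the earliest developmental stage (and are logged);
    all-NaN rows come back as NaN.
    """
    rho = grid.rho
    out = {}
    for stage_a, row in rho.iterrows():
        if row.isna().all():
            logger.warning("all-NaN similarity row for stage %s", stage_a)
            out[stage_a] = np.nan
            continue
        best = row.max()
        winners = row.index[row == best]
        if len(winners) > 1:
            logger.info("similarity tie at stage %s between %s; keeping earliest", stage_a, list(winners))
        out[stage_a] = winners[0]
    return pd.Series(out, name="best_stage_b").rename_axis("stage_a")
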