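"""Preprocessing of raw count matrices into index-ready expression values.

The weighted expression ``e_is`` that all indices consume is produced here:
counts are divided by CDS length (so the value tracks transcript molecule
numbers rather than sequenced bases), scaled between libraries by TMM
(trimmed mean of M-values) to correct RNA composition effects, and cleaned
by two redundancy filters — one collapsing clusters of near-identical
expression profiles (r > 0.99 retrotransposon-like elements), one collapsing
clusters of near-identical sequences (>=97% protein / >=95% DNA identity,
gap-free protein alignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix
from .io import validate_gene_table

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# length weighting and RPKM
# ----------------------------------------------------------------------

def _lengths_for(expr: ExpressionMatrix, genes: pd.DataFrame) -> np.ndarray:
    validate_gene_table(genes)
    lengths = genes.set_index("gene_id")["cds_length"]
    missing = [g for g in expr.gene_ids if g not in lengths.index]
    if missing:
        raise KeyError(f"no CDS length for genes: {missing[:5]}")
    return lengths.loc[expr.gene_ids].to_numpy(dtype=float)


def length_weight(counts: ExpressionMatrix, genes: pd.DataFrame) -> ExpressionMatrix:
    """Divide each gene's reads by its CDS length (value per base)."""
    lengths = _lengths_for(counts, genes)
    return counts.with_values(counts.values / lengths[:, None], "length_weighted")


def rpkm(counts: ExpressionMatrix, genes: pd.DataFrame) -> ExpressionMatrix:
    """Reads per kilobase of CDS per million library reads."""
    lengths = _lengths_for(counts, genes)
    libs = counts.values.sum(axis=0)
    if (libs <= 0).any():
        bad = [s for s, v in zip(counts.stage_ids, libs) if v <= 0]
        raise ValueError(f"zero library size in stages: {bad}")
    values = counts.values * 1e9 / (lengths[:, None] * libs[None, :])
    return counts.with_values(values, "rpkm")


# ----------------------------------------------------------------------
# TMM normalization
# ----------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float,
    abs_trim: float,
    weighted: bool = True,
) -> float:
    """Scaling factor of one library against the reference.

    Doubly trimmed, precision-weighted mean of per-gene log-ratios
    (M-values): genes with zero in either library are excluded, the most
    extreme M and A (average log abundance) fractions are trimmed, and the
    surviving M-values are averaged with inverse delta-method binomial
    variances as weights.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[finite], abs_e[finite], var[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0

    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        weights = 1.0 / var[keep]
        f = np.sum(log_r[keep] * weights) / np.sum(weights)
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_reference_stage(expr: ExpressionMatrix) -> str:
    """Stage whose upper-quartile expression (of library-scaled values) is
    closest to the mean upper quartile across stages."""
    values = expr.values
    libs = values.sum(axis=0)
    uq = np.array([np.quantile(values[:, j] / libs[j], 0.75) for j in range(values.shape[1])])
    return expr.stage_ids[int(np.argmin(np.abs(uq - uq.mean())))]


def tmm_factors(
    expr: ExpressionMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    reference: str | None = None,
    weighted: bool = True,
) -> pd.Series:
    """Per-stage TMM scaling factors, with the reference stage fixed at 1.

    The effective library size of stage ``s`` is ``library_size_s * factor_s``;
    dividing counts by it removes both sequencing-depth and RNA-composition
    differences between stages.

    ``weighted`` applies inverse delta-method binomial variances to the
    trimmed M-values (the published algorithm's default). Precision weights
    depend on the absolute counts, so weighted factors are only
    approximately invariant to rescaling a column; ``weighted=False`` is
    exactly scale-invariant.
    """
    if expr.n_stages < 2:
        raise ValueError("TMM needs at least 2 stages")
    values = expr.values
    libs = values.sum(axis=0)
    if (libs <= 0).any():
        bad = [s for s, v in zip(expr.stage_ids, libs) if v <= 0]
        raise ValueError(f"stage(s) with all-zero counts: {bad}")
    if reference is None:
        reference = tmm_reference_stage(expr)
    elif reference not in expr.stage_ids:
        raise KeyError(f"reference stage {reference!r} not in matrix")
    ref_col = values[:, expr.stage_ids.index(reference)]
    factors = [
        _tmm_pair(values[:, j], ref_col, logratio_trim, abs_trim, weighted)
        for j in range(values.shape[1])
    ]
    return pd.Series(factors, index=pd.Index(expr.stage_ids, name="stage"), name="tmm_factor")


def tmm_normalize(
    expr: ExpressionMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    reference: str | None = None,
) -> ExpressionMatrix:
    """Scale each stage by its effective library size (library x TMM factor).

    The grand geometric mean of effective sizes is multiplied back in so the
    output stays on a count-like scale; indices are invariant to that choice.
    """
    factors = tmm_factors(expr, logratio_trim, abs_trim, reference)
    effective = expr.values.sum(axis=0) * factors.to_numpy()
    scale = np.exp(np.mean(np.log(effective)))
    return expr.with_values(expr.values / effective[None, :] * scale, "tmm_scaled")


# ----------------------------------------------------------------------
# redundancy filters
# ----------------------------------------------------------------------

@dataclass
class FilterReport:
    """Outcome of a redundancy filter: which genes were collapsed and why."""

    removed: pd.DataFrame  # columns: gene_id, component, kept_representative

    @property
    def removed_genes(self) -> list[str]:
        return list(self.removed["gene_id"])

    def to_tsv(self, path) -> None:
        self.removed.to_csv(path, sep="\t", index=False)


def _pick_representative(members: list[str], lengths: pd.Series) -> str:
    # longest CDS wins; ties broken by lexicographically smallest id
    return sorted(members, key=lambda g: (-lengths.get(g, 0), g))[0]


def _collapse_components(
    graph: nx.Graph, lengths: pd.Series
) -> tuple[set[str], pd.DataFrame]:
    removed_rows = []
    removed = set()
    for comp_idx, component in enumerate(sorted(nx.connected_components(graph), key=min)):
        members = sorted(component)
        if len(members) < 2:
            continue
        keep = _pick_representative(members, lengths)
        for gene in members:
            if gene != keep:
                removed.add(gene)
                removed_rows.append((gene, comp_idx, keep))
    report = pd.DataFrame(removed_rows, columns=["gene_id", "component", "kept_representative"])
    return removed, report


def filter_correlated_duplicates(
    expr: ExpressionMatrix,
    genes: pd.DataFrame,
    r_threshold: float = 0.99,
    max_length_bp: int = 500,
    min_peak_expression: float = 10_000.0,
    ) -> tuple[ExpressionMatrix, FilterReport]:
    """Collapse clusters of short, highly expressed genes with near-identical
    expression curves (Pearson r above ``r_threshold`` across stages).

    Only short genes (``cds_length <= max_length_bp``) whose peak expression
    reaches ``min_peak_expression`` are candidates; one representative per
    connected component is retained.
    """
    if expr.n_stages < 3:
        raise ValueError("correlation filter needs at least 3 stages")
    lengths = validate_gene_table(genes).set_index("gene_id")["cds_length"]

    frame = expr.data
    peak = frame.max(axis=1)
    in_table = frame.index.isin(lengths.index)
    cand_mask = in_table & (lengths.reindex(frame.index) <= max_length_bp).fillna(False).to_numpy()
    cand_mask &= (peak >= min_peak_expression).to_numpy()
    candidates = frame.index[cand_mask]

    variances = frame.loc[candidates].var(axis=1)
    constant = variances.index[variances == 0]
    if len(constant):
        logger.info("excluding %d constant-expression genes from correlation candidacy", len(constant))
        candidates = candidates.difference(constant)

    graph = nx.Graph()
    graph.add_nodes_from(candidates)
    if len(candidates) >= 2:
        sub = frame.loc[candidates].to_numpy()
        corr = np.corrcoef(sub)
        ii, jj = np.triu_indices(len(candidates), k=1)
        hot = corr[ii, jj] > r_threshold
        graph.add_edges_from(zip(candidates[ii[hot]], candidates[jj[hot]]))

    removed, report = _collapse_components(graph, lengths)
    kept = [g for g in expr.gene_ids if g not in removed]
    return expr.subset_genes(kept), FilterReport(report)


def filter_sequence_redundant(
    alignments: pd.DataFrame,
    genes: pd.DataFrame,
    prot_identity_min: float = 97.0,
    dna_identity_min: float = 95.0,
) -> tuple[set[str], FilterReport]:
    """Collapse clusters of sequence-redundant genes from an all-vs-all
    self-alignment table.

    A pair clusters iff protein identity >= ``prot_identity_min`` AND DNA
    identity >= ``dna_identity_min`` AND the aligned protein region has no
    gaps. Components are collapsed to one representative (longest CDS).
    """
    lengths = validate_gene_table(genes).set_index("gene_id")["cds_length"]
    known = set(lengths.index)
    pair_genes = set(alignments["query_gene"]) | set(alignments["subject_id"])
    unknown = pair_genes - known
    if unknown:
        raise KeyError(f"alignment rows reference unknown genes: {sorted(unknown)[:5]}")

    edges = alignments.loc[
        (alignments["query_gene"] != alignments["subject_id"])
        & (alignments["pct_identity_protein"] >= prot_identity_min)
        & (alignments["pct_identity_dna"] >= dna_identity_min)
        & (alignments["aligned_gaps_protein"] == 0)
    ]
    graph = nx.Graph()
    graph.add_nodes_from(known)
    graph.add_edges_from(zip(edges["query_gene"], edges["subject_id"]))
    removed, report = _collapse_components(graph, lengths)
    return known - removed, FilterReport(report)
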