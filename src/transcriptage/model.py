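"""Model/Results interface over the indices and their uncertainty.

`StageIndexModel` bundles an expression matrix and a gene table into a
fittable object; `fit()` computes the index profile, the bootstrap
confidence band, and the permutation/gamma significance test, and returns a
`StageIndexResults` with a `summary()` table — the shape familiar from
statistical modelling packages.

    >>> model = StageIndexModel(expr, genes, index="TAI")
    >>> res = model.fit(n_boot=1000, n_perm=1000, seed=7)
    >>> res.summary()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .indices import (
    COVARIATE_COLUMN,
    INDEX_KINDS,
    StageIndexProfile,
    drop_silent_genes,
    tai,
    tai_excluding,
    tpi,
)
from .inference import NullModel, bootstrap_ci, permutation_null


class StageIndexModel:
    """An expression-weighted stage index (TAI or TPI) ready to fit.

    Parameters
    ----------
    expr : ExpressionMatrix
        Preprocessed (typically length-weighted, TMM-scaled) expression.
    genes : DataFrame
        Gene table holding the covariate the index weights
        (``phylostratum`` for TAI, ``theta`` for TPI).
    index : str
        "TAI" or "TPI".
    exclude_ranks : set of int, optional
        Phylostrata to drop before computing a TAI (e.g. the
        species-specific stratum).
    """

    def __init__(self, expr: ExpressionMatrix, genes: pd.DataFrame, index: str = "TAI",
                 exclude_ranks=None, kilo_scale: bool = True):
        if index not in INDEX_KINDS:
            raise ValueError(f"index must be one of {INDEX_KINDS}")
        if exclude_ranks and index != "TAI":
            raise ValueError("rank exclusion only applies to TAI")
        column = COVARIATE_COLUMN[index]
        if column not in genes.columns:
            raise ValueError(f"gene table lacks the {column!r} column required for {index}")
        expr = drop_silent_genes(expr)
        if exclude_ranks:
            table = genes.set_index("gene_id")["phylostratum"]
            keep = [g for g in expr.gene_ids if int(table.loc[g]) not in set(exclude_ranks)]
            if not keep:
                raise ValueError("rank exclusion removes every gene")
            expr = expr.subset_genes(keep)
        self.expr = expr
        self.genes = genes
        self.index = index
        self.exclude_ranks = set(exclude_ranks) if exclude_ranks else set()
        self.kilo_scale = kilo_scale

    @classmethod
    def from_dataframe(cls, expr_frame: pd.DataFrame, genes: pd.DataFrame, **kwargs) -> "StageIndexModel":
        """Build from a plain genes x stages DataFrame of expression values."""
        return cls(ExpressionMatrix(expr_frame, kind="tmm_scaled"), genes, **kwargs)

    # ------------------------------------------------------------------
    def profile(self) -> StageIndexProfile:
        """Point estimate only (no uncertainty)."""
        if self.index == "TAI":
            return tai(self.expr, self.genes)
        return tpi(self.expr, self.genes, kilo_scale=self.kilo_scale)

    def fit(
        self,
        n_boot: int = 1000,
        n_perm: int = 1000,
        level: float = 0.95,
        seed: int | None = None,
        two_sided: bool = True,
        combine_method: str = "empirical",
    ) -> "StageIndexResults":
        """Compute the profile with bootstrap CIs and permutation p-values.

        A single seed drives both resampling schemes (two independent
        streams are spawned from it), so a fitted result is reproducible.
        """
        profile = self.profile()
        root = np.random.default_rng(seed)
        boot_rng, perm_rng = root.spawn(2)
        low, high = bootstrap_ci(
            self.expr, self.genes, self.index, n_boot=n_boot, level=level, seed=boot_rng,
        )
        null = permutation_null(
            self.expr, self.genes, self.index, n_perm=n_perm, seed=perm_rng,
            two_sided=two_sided, combine_method=combine_method,
        )
        profile = StageIndexProfile(
            stage_ids=profile.stage_ids,
            values=profile.values,
            index_kind=profile.index_kind,
            ci_low=low,
            ci_high=high,
            p_per_stage=null.p_per_stage,
            p_combined=null.p_combined,
        )
        return StageIndexResults(self, profile, null, level=level, seed=seed)


class StageIndexResults:
    """Fitted stage index profile with its uncertainty and diagnostics."""

    def __init__(self, model: StageIndexModel, profile: StageIndexProfile,
                 null: NullModel, level: float, seed: int | None):
        self.model = model
        self.profile = profile
        self.null = null
        self.level = level
        self.seed = seed

    # convenient accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.profile.values

    @property
    def stage_ids(self) -> list[str]:
        return self.profile.stage_ids

    @property
    def p_combined(self) -> float:
        return self.profile.p_combined

    def argmin_stage(self) -> str:
        """Stage with the lowest index — the candidate phylotypic stage for
        TAI (oldest transcriptome) and TPI (least polymorphic)."""
        return self.profile.argmin_stage()

    def summary(self) -> pd.DataFrame:
        """Per-stage table: estimate, CI bounds, permutation p-value."""
        frame = self.profile.as_frame()
        frame.attrs["index"] = self.model.index
        frame.attrs["combined_p"] = self.p_combined
        frame.attrs["level"] = self.level
        frame.attrs["seed"] = self.seed
        return frame

    def summary_text(self) -> str:
        frame = self.summary()
        lines = [
            f"{self.model.index} profile over {len(self.stage_ids)} stages "
            f"({self.model.expr.n_genes} genes)",
            frame.to_string(float_format=lambda v: f"{v:.4g}"),
            f"combined pattern p-value ({self.null.combine_method}): {self.p_combined:.3g}",
            f"lowest index at stage: {self.argmin_stage()}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Line plot of the profile with its confidence band."""
        from .plotting import plot_profile

        return plot_profile(self.profile, ax=ax)
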