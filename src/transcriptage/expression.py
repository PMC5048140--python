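"""Expression matrix container.

A thin wrapper around a pandas DataFrame (genes x ordered developmental
stages) that tracks what kind of values it holds (raw counts, length-weighted,
TMM-scaled, RPKM) and enforces the invariants every downstream index relies
on: non-negative entries and a stable stage order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Recognised value kinds, in the order transformations typically apply.
KINDS = ("raw_counts", "length_weighted", "tmm_scaled", "rpkm")


class ExpressionMatrix:
    """Genes x stages expression values with a declared value kind.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by stage id in developmental order.
    kind : str
        One of :data:`KINDS`.
    """

    def __init__(self, data: pd.DataFrame, kind: str = "raw_counts"):
        if kind not in KINDS:
            raise ValueError(f"unknown expression kind {kind!r}; expected one of {KINDS}")
        if data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate stage ids in expression matrix")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative values")
        self.data = data.astype(float)
        self.kind = kind

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def stage_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_stages(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def library_sizes(self) -> pd.Series:
        """Per-stage column totals."""
        return self.data.sum(axis=0)

    # ------------------------------------------------------------------
    def subset_genes(self, gene_ids, kind: str | None = None) -> "ExpressionMatrix":
        missing = set(gene_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], kind or self.kind)

    def with_values(self, values: np.ndarray, kind: str) -> "ExpressionMatrix":
        """Same genes/stages, new values and kind."""
        frame = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(frame, kind)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ExpressionMatrix {self.n_genes} genes x {self.n_stages} stages, "
            f"kind={self.kind!r}>"
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, kind: str = "raw_counts") -> "ExpressionMatrix":
        """Read a tab-delimited matrix: first column gene id, header = stage ids.

        Stage order is taken from the file's column order.
        """
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(frame, kind)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")
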