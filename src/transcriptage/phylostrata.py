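"""Phylostratigraphic age assignment.

Each focal-species gene receives a phylostratum rank: the oldest lineage
node (rank 1 = e.g. cellular organisms) at which a homolog is detectable in
a taxonomically partitioned species database. Genes with no qualifying hit
outside the focal species are "new genes" and receive the youngest
(focal-species-specific) rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Classic phylostratigraphy similarity cutoff; configurable everywhere it is used.
DEFAULT_EVALUE_CUTOFF = 1e-3


@dataclass(frozen=True)
class LineageMap:
    """Species -> phylostratum rank, with the focal species at the deepest rank.

    Ranks must form a contiguous ``1..n_strata`` range and the focal species
    must map to ``n_strata`` (the species-specific node).
    """

    ranks: dict[str, int]
    focal_species: str
    n_strata: int = field(init=False)

    def __post_init__(self):
        if not self.ranks:
            raise ValueError("empty lineage map")
        observed = set(self.ranks.values())
        n_strata = max(observed)
        if observed != set(range(1, n_strata + 1)):
            missing = sorted(set(range(1, n_strata + 1)) - observed)
            raise ValueError(f"phylostratum ranks not contiguous; missing ranks {missing}")
        if self.focal_species not in self.ranks:
            raise ValueError(f"focal species {self.focal_species!r} absent from lineage map")
        if self.ranks[self.focal_species] != n_strata:
            raise ValueError(
                f"focal species must map to the youngest rank {n_strata}, "
                f"got {self.ranks[self.focal_species]}"
            )
        object.__setattr__(self, "n_strata", n_strata)

    def rank_of(self, species: str) -> int | None:
        return self.ranks.get(species)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, focal_species: str) -> "LineageMap":
        return cls(dict(zip(frame["species_id"], frame["rank"].astype(int))), focal_species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.ranks.items(), key=lambda kv: (kv[1], kv[0])),
            columns=["species_id", "rank"],
        )


def assign_phylostrata(
    hits: pd.DataFrame,
    lineage: LineageMap,
    gene_ids,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    strict: bool = False,
) -> pd.Series:
    """Assign every gene in ``gene_ids`` a phylostratum rank.

    A gene's rank is the minimum rank among subject species with a hit at
    ``evalue <= evalue_cutoff``. Self-hits (subject species == focal) are
    ignored; genes with no qualifying non-focal hit get ``n_strata``.

    Parameters
    ----------
    hits : DataFrame
        Columns ``query_gene``, ``subject_species``, ``evalue`` (extra
        columns ignored).
    lineage : LineageMap
    gene_ids : iterable of str
        The companion gene list; genes absent from ``hits`` are still
        assigned (they get ``n_strata``).
    evalue_cutoff : float
        Must be positive.
    strict : bool
        If True, a hit row whose species is absent from the lineage map is
        an error; otherwise such rows are skipped with a warning.

    Returns
    -------
    pandas.Series
        Rank per gene id, name ``phylostratum``.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue cutoff must be positive")
    gene_ids = list(gene_ids)

    known = hits["subject_species"].map(lineage.ranks.get)
    unknown_mask = known.isna()
    if unknown_mask.any():
        unknown = sorted(hits.loc[unknown_mask, "subject_species"].unique())
        if strict:
            raise KeyError(f"hit rows reference species absent from lineage map: {unknown[:5]}")
        logger.warning(
            "skipping %d hit rows from %d unknown species (e.g. %s)",
            int(unknown_mask.sum()), len(unknown), unknown[:3],
        )

    usable = hits.loc[
        ~unknown_mask
        & (hits["subject_species"] != lineage.focal_species)
        & (hits["evalue"] <= evalue_cutoff)
    ]
    min_rank = (
        usable["subject_species"].map(lineage.ranks).groupby(usable["query_gene"]).min()
    )

    ranks = pd.Series(lineage.n_strata, index=pd.Index(gene_ids, name="gene_id"), name="phylostratum")
    shared = min_rank.index.intersection(ranks.index)
    ranks.loc[shared] = min_rank.loc[shared].astype(int)
    return ranks.astype(int)
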