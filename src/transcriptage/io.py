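"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are tab-delimited. Gene tables carry per-gene metadata (CDS
length, phylostratum rank once assigned, per-site theta once computed);
hit tables are BLAST "outfmt 6"-style rows augmented with a subject-species
column; lineage maps assign each database species a phylostratum rank.
"""

from __future__ import annotations

import pandas as pd

GENE_TABLE_COLUMNS = ["gene_id", "cds_length"]
HIT_TABLE_COLUMNS = [
    "query_gene",
    "subject_id",
    "subject_species",
    "evalue",
    "bitscore",
    "pct_identity_protein",
    "pct_identity_dna",
    "aligned_gaps_protein",
]
#: Minimal hit format: just enough for age assignment.
HIT_TABLE_MINIMAL = ["query_gene", "subject_species", "evalue"]


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Check gene-table invariants: unique ids, positive CDS lengths."""
    if "gene_id" not in genes.columns or "cds_length" not in genes.columns:
        raise ValueError("gene table needs 'gene_id' and 'cds_length' columns")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in gene table: {dups[:5]}")
    if (genes["cds_length"] <= 0).any():
        bad = genes.loc[genes["cds_length"] <= 0, "gene_id"].tolist()
        raise ValueError(f"non-positive CDS length for genes: {bad[:5]}")
    if "theta" in genes.columns and (genes["theta"].dropna() < 0).any():
        raise ValueError("negative theta in gene table")
    return genes


def read_gene_table(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return validate_gene_table(genes)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> pd.DataFrame:
    """Read a hit table; accepts the full 8-column or minimal 3-column layout."""
    hits = pd.read_csv(path, sep="\t", dtype={"query_gene": str, "subject_id": str, "subject_species": str})
    if not set(HIT_TABLE_MINIMAL) <= set(hits.columns):
        raise ValueError(f"hit table must at least contain columns {HIT_TABLE_MINIMAL}")
    if (hits["evalue"] < 0).any() or hits["evalue"].isna().any():
        raise ValueError("hit table e-values must be finite and non-negative")
    return hits


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_lineage_map(path) -> pd.DataFrame:
    """Two-column TSV: species_id, phylostratum rank."""
    lineage = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    if not {"species_id", "rank"} <= set(lineage.columns):
        raise ValueError("lineage map needs 'species_id' and 'rank' columns")
    return lineage


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) mapping genes to genomic intervals.

    Columns: chrom, start, end, name. Extra BED columns are ignored.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    if (bed["end"] <= bed["start"]).any():
        bad = bed.loc[bed["end"] <= bed["start"], "name"].tolist()
        raise ValueError(f"BED intervals with end <= start: {bad[:5]}")
    return bed
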