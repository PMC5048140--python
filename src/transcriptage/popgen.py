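"""Per-gene nucleotide diversity from resequencing genotypes.

Watterson's theta per site, theta = S / (H_{n-1} * L), estimated for each
gene from the count of segregating sites S among n sequences (two per
diploid individual) over the annotated gene length L. Genotypes come from a
VCF; gene spans from a BED (0-based half-open) gene-coordinate table.

The whole-gene n (2 x individuals in the panel) is used for the harmonic
number even at sites with missing calls, matching the convention of
gene-wise diversity software that infers complete diploid sequences per
individual; a site still counts as segregating when at least two distinct
alleles appear among the called genotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .io import read_bed


def harmonic_number(n: int) -> float:
    """H_n = sum_{i=1..n} 1/i."""
    if n < 1:
        raise ValueError("harmonic number needs n >= 1")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def watterson_theta(n_segregating: int, n_sequences: int, length_bp: int) -> float:
    """Watterson's estimator of the per-site population mutation rate.

    Parameters
    ----------
    n_segregating : int
        Number of segregating (polymorphic) sites S in the gene.
    n_sequences : int
        Number of sampled sequences n (2 x diploid individuals); must be >= 2.
    length_bp : int
        Gene length L in base pairs; must be positive.
    """
    if length_bp <= 0:
        raise ValueError("gene length must be positive")
    if n_sequences < 2:
        raise ValueError("Watterson's theta needs at least 2 sequences")
    if n_segregating < 0:
        raise ValueError("negative segregating-site count")
    return n_segregating / (harmonic_number(n_sequences - 1) * length_bp)


def _site_is_segregating(record) -> bool:
    """At least two distinct alleles among called genotype alleles."""
    alleles = set()
    for sample in record.samples.values():
        for allele_index in sample["GT"]:
            if allele_index is not None:
                alleles.add(allele_index)
                if len(alleles) > 1:
                    return True
    return False


def segregating_sites(vcf_path, bed) -> pd.DataFrame:
    """Count segregating sites per gene.

    Parameters
    ----------
    vcf_path : str or Path
        VCF (plain or bgzipped) with per-individual diploid genotypes.
    bed : str, Path or DataFrame
        Gene spans, BED-style 0-based half-open (chrom, start, end, name).

    Returns
    -------
    DataFrame with columns gene_id, L, n_individuals, n_sequences, S.
    Multiple records at the same position count once.
    """
    if not isinstance(bed, pd.DataFrame):
        bed = read_bed(bed)
    if bed["name"].duplicated().any():
        dups = bed.loc[bed["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate gene entries in coordinate table: {dups[:5]}")

    with pysam.VariantFile(str(vcf_path)) as vcf:
        n_individuals = len(vcf.header.samples)
        seg_positions: dict[str, set[int]] = {}
        for record in vcf:
            if _site_is_segregating(record):
                seg_positions.setdefault(record.chrom, set()).add(record.pos)  # 1-based

    rows = []
    for gene in bed.itertuples(index=False):
        positions = seg_positions.get(gene.chrom, ())
        # half-open [start, end) in 0-based == (start, end] in 1-based
        s_count = sum(1 for pos in positions if gene.start < pos <= gene.end)
        rows.append((gene.name, int(gene.end - gene.start), n_individuals, 2 * n_individuals, s_count))
    return pd.DataFrame(rows, columns=["gene_id", "L", "n_individuals", "n_sequences", "S"])


def theta_table(snp_counts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach per-site theta to a gene table.

    Genes absent from the SNP input get theta = 0 and the flag
    ``no_snp_data``. Output columns: the gene table plus ``n_sequences``,
    ``S``, ``L``, ``theta``, ``theta_flag``.
    """
    if snp_counts["gene_id"].duplicated().any():
        dups = snp_counts.loc[snp_counts["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene entries in SNP counts: {dups[:5]}")
    merged = genes.merge(snp_counts, on="gene_id", how="left")
    covered = merged["S"].notna()
    theta = np.zeros(len(merged))
    if covered.any():
        sub = merged.loc[covered]
        theta[covered.to_numpy()] = [
            watterson_theta(int(s), int(n), int(length))
            for s, n, length in zip(sub["S"], sub["n_sequences"], sub["L"])
        ]
    merged["theta"] = theta
    merged["theta_flag"] = np.where(covered, "ok", "no_snp_data")
    return merged
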