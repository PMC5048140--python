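"""Synthetic dataset generator with known ground truth.

Emulates the structure of a stage-resolved phylotranscriptomic study of a
marine invertebrate: ~10-11 phylostrata, an ordered series of developmental
stages, negative-binomial RNA-seq counts with an age-dependent
developmental signal, a resequencing panel of diploid individuals giving
per-gene segregating sites with known theta, a homology hit table from
which age assignment recovers the generating phylostrata exactly, and a
second "species" whose stage expression is a rank-perturbed copy of the
first, maximally correlated at the designated phylotypic stage.

The hourglass effect delta multiplies the expression of old-strata genes at
the phylotypic stage (young-strata genes are boosted at the terminal stage
instead, mirroring the two opposing phylostratum groups seen in real
ontogenies); delta = 1 is the null with no age-stage association.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .phylostrata import LineageMap
from .popgen import harmonic_number

FOCAL_SPECIES = "focal"


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the study design the pipeline
    targets (11 phylostrata, 11 ordered stages, 10 resequenced diploids).

    ``hourglass_effect`` (delta) is the old-gene expression multiplier at
    the phylotypic stage; delta = 1 generates the null. ``age_theta_slope``
    is the increment of log theta per phylostratum rank (young genes are
    more polymorphic when positive).
    """

    n_genes: int = 2000
    n_strata: int = 11
    n_stages: int = 11
    stage_of_phylotype: int = 5          # 0-based stage index
    hourglass_effect: float = 1.0        # delta >= 1
    age_distribution: tuple | None = None  # probs per stratum; default skewed old
    length_log_mean: float = float(np.log(1200.0))  # bp
    length_log_sd: float = 0.45
    expr_log_mean: float = float(np.log(50.0))      # baseline per-gene level
    expr_log_sd: float = 1.0
    noise: str = "nb"                    # "nb" (dispersion below) or "poisson"
    nb_dispersion: float = 0.1
    depth: float = 30.0                  # mean per-kilobase sequencing depth scale
    n_individuals: int = 10
    theta_log_mean: float = float(np.log(0.004))
    theta_log_sd: float = 0.5
    age_theta_slope: float = 0.0
    ortholog_fraction: float = 0.6
    swap_fraction: float = 0.4           # max fraction of ortholog rank swaps (at stage distance max)
    old_rank_max: int | None = None      # default n_strata // 3
    young_rank_min: int | None = None    # default n_strata - 1
    # component toggles: large expression-only studies (e.g. calibration
    # sweeps) can skip the SNP / hit-table / second-species machinery
    include_snps: bool = True
    include_hits: bool = True
    include_species_b: bool = True
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.stage_of_phylotype < self.n_stages):
            raise ValueError("stage_of_phylotype out of range")
        if self.hourglass_effect < 1:
            raise ValueError("hourglass effect delta must be >= 1")
        if self.age_distribution is not None:
            probs = np.asarray(self.age_distribution, dtype=float)
            if len(probs) != self.n_strata or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
                raise ValueError("age_distribution must be n_strata probabilities summing to 1")
        if self.noise not in ("nb", "poisson"):
            raise ValueError("noise must be 'nb' or 'poisson'")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")

    @property
    def old_cutoff(self) -> int:
        return self.old_rank_max if self.old_rank_max is not None else max(1, self.n_strata // 3)

    @property
    def young_cutoff(self) -> int:
        return self.young_rank_min if self.young_rank_min is not None else self.n_strata - 1


@dataclass
class SnpSite:
    chrom: str
    pos: int                      # 1-based
    genotypes: list[tuple[int, int]]


@dataclass
class SimBundle:
    """Everything one simulated study produces, with ground truth attached."""

    config: SimConfig
    genes: pd.DataFrame           # gene_id, cds_length, phylostratum, theta_true
    counts: ExpressionMatrix      # raw counts, species A
    counts_b: ExpressionMatrix    # species B (ortholog genes only)
    ortholog_truth: pd.DataFrame  # gene_a, gene_b
    hits: pd.DataFrame            # homology hits recovering the true ages
    lineage: LineageMap
    snp_sites: list[SnpSite]
    bed: pd.DataFrame
    sample_names: list[str]
    manifest: dict | None = None

    def write(self, outdir) -> dict:
        """Write every input format the pipeline reads; returns file paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "counts_b": outdir / "counts_species_b.tsv",
            "genes": outdir / "genes.tsv",
            "hits": outdir / "hits.tsv",
            "lineage": outdir / "lineage.tsv",
            "vcf": outdir / "snps.vcf",
            "bed": outdir / "genes.bed",
            "orthologs": outdir / "ortholog_truth.tsv",
            "manifest": outdir / "manifest.json",
        }
        self.counts.to_tsv(paths["counts"])
        self.counts_b.to_tsv(paths["counts_b"])
        self.genes.to_csv(paths["genes"], sep="\t", index=False)
        self.hits.to_csv(paths["hits"], sep="\t", index=False)
        self.lineage.to_frame().to_csv(paths["lineage"], sep="\t", index=False)
        self.bed.to_csv(paths["bed"], sep="\t", index=False, header=False)
        write_vcf(paths["vcf"], self.snp_sites, self.sample_names,
                  contigs=sorted(self.bed["chrom"].unique()))
        self.ortholog_truth.to_csv(paths["orthologs"], sep="\t", index=False)
        manifest = {"config": asdict(self.config)}
        if self.manifest:
            manifest["expected"] = self.manifest
        with open(paths["manifest"], "w") as handle:
            json.dump(manifest, handle, indent=2, default=str)
        return paths


def write_vcf(path, sites: list[SnpSite], sample_names: list[str], contigs=()) -> None:
    """Write a minimal genotype-only VCF 4.2 text file."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in contigs:
            handle.write(f"##contig=<ID={contig}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(sample_names) + "\n")
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            gts = "\t".join(f"{a}/{b}" for a, b in site.genotypes)
            handle.write(f"{site.chrom}\t{site.pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ----------------------------------------------------------------------

def _default_age_distribution(n_strata: int) -> np.ndarray:
    # skewed towards old strata with a bump of species-specific genes,
    # loosely matching real phylostratum size profiles
    weights = np.exp(-0.25 * np.arange(n_strata))
    weights[-1] += 0.35 * weights.sum()
    return weights / weights.sum()


def _stage_modulation(cfg: SimConfig, ranks: np.ndarray) -> np.ndarray:
    """Per-gene x per-stage expression multiplier carrying the hourglass
    signal: a Gaussian bump of width ~n_stages/8 at the phylotypic stage for
    old strata, at the terminal stage for the youngest strata."""
    stages = np.arange(cfg.n_stages)
    width = max(1.0, cfg.n_stages / 8.0)
    bump_phylo = np.exp(-0.5 * ((stages - cfg.stage_of_phylotype) / width) ** 2)
    bump_late = np.exp(-0.5 * ((stages - (cfg.n_stages - 1)) / width) ** 2)
    mod = np.ones((len(ranks), cfg.n_stages))
    delta = cfg.hourglass_effect
    old = ranks <= cfg.old_cutoff
    young = ranks >= cfg.young_cutoff
    mod[old] = 1.0 + (delta - 1.0) * bump_phylo
    mod[young] = 1.0 + (delta - 1.0) * bump_late
    return mod


def _draw_counts(cfg: SimConfig, mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise == "poisson":
        return rng.poisson(mean).astype(float)
    # negative binomial: var = mu + phi mu^2
    phi = cfg.nb_dispersion
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_dataset(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimBundle:
    """Generate one complete study with known ground truth.

    All randomness comes from ``rng`` (or ``cfg.seed`` if none is given).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    probs = (np.asarray(cfg.age_distribution, dtype=float)
             if cfg.age_distribution is not None
             else _default_age_distribution(cfg.n_strata))
    ranks = rng.choice(np.arange(1, cfg.n_strata + 1), size=cfg.n_genes, p=probs)
    lengths = np.maximum(150, np.round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd,
                                                     cfg.n_genes))).astype(int)
    log_theta = (cfg.theta_log_mean
                 + cfg.age_theta_slope * (ranks - ranks.mean())
                 + rng.normal(0.0, cfg.theta_log_sd, cfg.n_genes))
    theta_true = np.exp(log_theta)

    # expression: per-gene baseline concentration x stage modulation, counts
    # proportional to CDS length (reads land anywhere in the transcript)
    baseline = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, cfg.n_genes)
    modulation = _stage_modulation(cfg, ranks)
    depth = cfg.depth * rng.lognormal(0.0, 0.2, cfg.n_stages)  # stage-to-stage depth wobble
    mean_counts = baseline[:, None] * modulation * (lengths[:, None] / 1000.0) * depth[None, :]
    counts = _draw_counts(cfg, mean_counts, rng)

    stage_ids = [f"S{i + 1:02d}" for i in range(cfg.n_stages)]
    counts_a = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=stage_ids),
        kind="raw_counts",
    )

    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "cds_length": lengths,
        "phylostratum": ranks,
        "theta_true": theta_true,
    })

    if cfg.include_hits:
        lineage, hits = _make_hits(cfg, genes, rng)
    else:
        lineage, hits = _empty_hits(cfg)
    snp_sites, bed = _make_snps(cfg, genes, rng)
    if cfg.include_species_b:
        counts_b, ortholog_truth = _make_species_b(cfg, counts_a, rng)
    else:
        counts_b = ExpressionMatrix(pd.DataFrame(index=pd.Index([], name="gene_id"),
                                                 columns=stage_ids, dtype=float))
        ortholog_truth = pd.DataFrame(columns=["gene_a", "gene_b"])

    return SimBundle(
        config=cfg,
        genes=genes,
        counts=counts_a,
        counts_b=counts_b,
        ortholog_truth=ortholog_truth,
        hits=hits,
        lineage=lineage,
        snp_sites=snp_sites,
        bed=bed,
        sample_names=[f"ind{i + 1}" for i in range(cfg.n_individuals)],
    )


def _empty_hits(cfg: SimConfig):
    species = {r: f"sp_r{r:02d}" for r in range(1, cfg.n_strata)}
    ranks_map = {sp: r for r, sp in species.items()}
    ranks_map[FOCAL_SPECIES] = cfg.n_strata
    lineage = LineageMap(ranks_map, focal_species=FOCAL_SPECIES)
    hits = pd.DataFrame(columns=[
        "query_gene", "subject_id", "subject_species", "evalue", "bitscore",
        "pct_identity_protein", "pct_identity_dna", "aligned_gaps_protein",
    ])
    return lineage, hits


def _make_hits(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator):
    """Hit table constructed so age assignment recovers the true ranks:
    each gene hits one species at exactly its stratum (strong e-value), a
    few younger strata, and its own species; species-specific genes hit
    nothing outside the focal species."""
    species = {r: f"sp_r{r:02d}" for r in range(1, cfg.n_strata)}
    ranks_map = {sp: r for r, sp in species.items()}
    ranks_map[FOCAL_SPECIES] = cfg.n_strata
    lineage = LineageMap(ranks_map, focal_species=FOCAL_SPECIES)

    rows = []
    for gene_id, rank in zip(genes["gene_id"], genes["phylostratum"]):
        rows.append((gene_id, f"{FOCAL_SPECIES}:{gene_id}", FOCAL_SPECIES, 0.0, 500.0, 100.0, 100.0, 0))
        if rank < cfg.n_strata:
            rows.append((gene_id, f"{species[rank]}:{gene_id}", species[rank],
                         float(10.0 ** -rng.uniform(20, 100)), float(rng.uniform(80, 400)),
                         float(rng.uniform(40, 95)), float(rng.uniform(40, 95)), 0))
            for extra in range(rank + 1, cfg.n_strata):
                if rng.random() < 0.5:
                    rows.append((gene_id, f"{species[extra]}:{gene_id}", species[extra],
                                 float(10.0 ** -rng.uniform(6, 80)), float(rng.uniform(60, 300)),
                                 float(rng.uniform(40, 95)), float(rng.uniform(40, 95)), 0))
    hits = pd.DataFrame(rows, columns=[
        "query_gene", "subject_id", "subject_species", "evalue", "bitscore",
        "pct_identity_protein", "pct_identity_dna", "aligned_gaps_protein",
    ])
    return lineage, hits


def _make_snps(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator):
    """Segregating sites per gene with E[S] = theta_true * H_{2n-1} * L;
    genes laid end to end on one contig with 100 bp spacers."""
    n_seq = 2 * cfg.n_individuals
    h = harmonic_number(n_seq - 1)
    sites: list[SnpSite] = []
    bed_rows = []
    cursor = 0
    for gene_id, length, theta in zip(genes["gene_id"], genes["cds_length"], genes["theta_true"]):
        start, end = cursor, cursor + int(length)
        bed_rows.append(("chr1", start, end, gene_id))
        n_sites = 0
        if cfg.include_snps:
            n_sites = min(int(rng.poisson(theta * h * length)), int(length))
        if n_sites:
            offsets = rng.choice(int(length), size=n_sites, replace=False)
            for offset in np.sort(offsets):
                k = int(rng.integers(1, n_seq))  # derived allele count, always polymorphic
                alleles = np.zeros(n_seq, dtype=int)
                alleles[rng.choice(n_seq, size=k, replace=False)] = 1
                genotypes = [(int(alleles[2 * i]), int(alleles[2 * i + 1]))
                             for i in range(cfg.n_individuals)]
                sites.append(SnpSite("chr1", start + int(offset) + 1, genotypes))
        cursor = end + 100
    bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"])
    return sites, bed


def _make_species_b(cfg: SimConfig, counts_a: ExpressionMatrix, rng: np.random.Generator):
    """Species-B expression for a subset of orthologous genes: each stage
    column is the species-A column with a number of random value swaps that
    grows with the stage's distance from the phylotypic stage, so the
    cross-species rank correlation peaks there by construction."""
    n_orth = max(3, int(round(cfg.ortholog_fraction * counts_a.n_genes)))
    orth_idx = np.sort(rng.choice(counts_a.n_genes, size=n_orth, replace=False))
    genes_a = [counts_a.gene_ids[i] for i in orth_idx]
    genes_b = [f"b_{g}" for g in genes_a]

    values = counts_a.values[orth_idx].copy()
    max_dist = max(cfg.stage_of_phylotype, cfg.n_stages - 1 - cfg.stage_of_phylotype, 1)
    for s in range(cfg.n_stages):
        dist = abs(s - cfg.stage_of_phylotype) / max_dist
        n_swaps = int(round(cfg.swap_fraction * n_orth * dist))
        col = values[:, s]
        for _ in range(n_swaps):
            i, j = rng.integers(0, n_orth, size=2)
            col[i], col[j] = col[j], col[i]
    counts_b = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes_b, name="gene_id"),
                     columns=counts_a.stage_ids),
        kind="raw_counts",
    )
    truth = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    return counts_b, truth


# ----------------------------------------------------------------------
# hand-checkable fixture
# ----------------------------------------------------------------------

def fixture_small() -> SimBundle:
    """Deterministic 6-gene, 5-stage, 3-individual fixture.

    Every value in the attached manifest was derived by hand from the
    closed forms: stage indices from the length-weighted counts, theta from
    the segregating-site counts in the VCF (n = 6 sequences, H_5 = 137/60).
    """
    cfg = SimConfig(n_genes=6, n_strata=11, n_stages=5, stage_of_phylotype=2,
                    n_individuals=3, seed=0)
    stage_ids = ["S1", "S2", "S3", "S4", "S5"]
    gene_ids = ["g1", "g2", "g3", "g4", "g5", "g6"]
    lengths = [1000, 500, 2000, 1000, 800, 400]
    ranks = [1, 2, 3, 5, 5, 11]
    counts = np.array([
        [100, 200, 300, 400, 500],
        [50, 50, 50, 50, 50],
        [200, 0, 200, 400, 200],
        [100, 100, 100, 100, 100],
        [80, 160, 80, 80, 240],
        [40, 40, 400, 40, 40],
    ], dtype=float)
    counts_a = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=stage_ids),
        kind="raw_counts",
    )

    # segregating sites per gene: g1:5 g2:2 g3:0 g4:3 g5:4 g6:6
    h5 = harmonic_number(5)  # 137/60
    s_counts = {"g1": 5, "g2": 2, "g3": 0, "g4": 3, "g5": 4, "g6": 6}
    theta_true = np.array([s_counts[g] / (h5 * L) for g, L in zip(gene_ids, lengths)])
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "cds_length": lengths,
        "phylostratum": ranks,
        "theta_true": theta_true,
    })

    bed_rows, sites = [], []
    cursor = 0
    site_offsets = {"g1": [9, 19, 29, 39, 49], "g2": [9, 19], "g3": [],
                    "g4": [9, 19, 29], "g5": [9, 19, 29, 39], "g6": [9, 19, 29, 39, 49, 59]}
    for gene_id, length in zip(gene_ids, lengths):
        start, end = cursor, cursor + length
        bed_rows.append(("chr1", start, end, gene_id))
        for offset in site_offsets[gene_id]:
            # heterozygous first individual: always segregating among 6 alleles
            sites.append(SnpSite("chr1", start + offset + 1, [(0, 1), (0, 0), (0, 0)]))
        cursor = end + 100
    # a monomorphic record inside g3: must NOT count as segregating
    sites.append(SnpSite("chr1", 1600, [(0, 0), (0, 0), (0, 0)]))
    bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"])

    species = {r: f"sp_r{r:02d}" for r in range(1, 11)}
    ranks_map = {sp: r for r, sp in species.items()}
    ranks_map[FOCAL_SPECIES] = 11
    lineage = LineageMap(ranks_map, focal_species=FOCAL_SPECIES)
    hit_rows = []
    for gene_id, rank in zip(gene_ids, ranks):
        hit_rows.append((gene_id, f"{FOCAL_SPECIES}:{gene_id}", FOCAL_SPECIES,
                         0.0, 500.0, 100.0, 100.0, 0))
        if rank < 11:
            hit_rows.append((gene_id, f"{species[rank]}:{gene_id}", species[rank],
                             1e-40, 200.0, 60.0, 70.0, 0))
    hits = pd.DataFrame(hit_rows, columns=[
        "query_gene", "subject_id", "subject_species", "evalue", "bitscore",
        "pct_identity_protein", "pct_identity_dna", "aligned_gaps_protein",
    ])

    # species B: identical counts under renamed ids (rho = 1 on the diagonal)
    counts_b = ExpressionMatrix(
        pd.DataFrame(counts.copy(), index=pd.Index([f"b_{g}" for g in gene_ids], name="gene_id"),
                     columns=stage_ids),
        kind="raw_counts",
    )
    truth = pd.DataFrame({"gene_a": gene_ids, "gene_b": [f"b_{g}" for g in gene_ids]})

    bundle = SimBundle(
        config=cfg, genes=genes, counts=counts_a, counts_b=counts_b,
        ortholog_truth=truth, hits=hits, lineage=lineage, snp_sites=sites,
        bed=bed, sample_names=["ind1", "ind2", "ind3"],
    )
    bundle.manifest = fixture_manifest()
    return bundle


def fixture_manifest() -> dict:
    """Hand-derived expected values for :func:`fixture_small`.

    TAI_s = sum ps_i e_is / sum e_is on length-weighted counts; e.g. at S1
    every gene has e = 0.1, so TAI = (1+2+3+5+5+11)/6 = 4.5. Theta for g1:
    S=5, n=6, L=1000 -> 5 / (H_5 * 1000) with H_5 = 137/60.
    """
    h5 = 137.0 / 60.0
    theta = {
        "g1": 5 / (h5 * 1000),
        "g2": 2 / (h5 * 500),
        "g3": 0.0,
        "g4": 3 / (h5 * 1000),
        "g5": 4 / (h5 * 800),
        "g6": 6 / (h5 * 400),
    }
    sum_theta = sum(theta.values())
    # weighted expression columns (counts / length), per stage:
    # S1: all 0.1; S2: (.2,.1,0,.1,.2,.1); S3: (.3,.1,.1,.1,.1,1.0);
    # S4: (.4,.1,.2,.1,.1,.1); S5: (.5,.1,.1,.1,.3,.1)
    tai = {
        "S1": 2.7 / 0.6,
        "S2": 3.0 / 0.7,
        "S3": 12.8 / 1.7,
        "S4": 3.3 / 1.0,
        "S5": 4.1 / 1.2,
    }
    th = theta
    tpi = {
        "S1": 1000 * 0.1 * sum_theta / 0.6,
        "S2": 1000 * (0.2 * th["g1"] + 0.1 * th["g2"] + 0.1 * th["g4"] + 0.2 * th["g5"] + 0.1 * th["g6"]) / 0.7,
        "S3": 1000 * (0.3 * th["g1"] + 0.1 * th["g2"] + 0.1 * th["g3"] + 0.1 * th["g4"] + 0.1 * th["g5"] + 1.0 * th["g6"]) / 1.7,
        "S4": 1000 * (0.4 * th["g1"] + 0.1 * th["g2"] + 0.2 * th["g3"] + 0.1 * th["g4"] + 0.1 * th["g5"] + 0.1 * th["g6"]) / 1.0,
        "S5": 1000 * (0.5 * th["g1"] + 0.1 * th["g2"] + 0.1 * th["g3"] + 0.1 * th["g4"] + 0.3 * th["g5"] + 0.1 * th["g6"]) / 1.2,
    }
    return {"theta": theta, "tai": tai, "tpi": tpi,
            "segregating_sites": {"g1": 5, "g2": 2, "g3": 0, "g4": 3, "g5": 4, "g6": 6},
            "phylostrata": {"g1": 1, "g2": 2, "g3": 3, "g4": 5, "g5": 5, "g6": 11}}
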