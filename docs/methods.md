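# Methods

This note documents the statistical procedures implemented in
`transcriptage`, their assumptions, the parameters that matter, and the
design choices made where the literature leaves the design open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Gene ages (phylostratigraphy)

A gene's phylostratum is the minimum lineage-node rank among database
species with a homology hit at `evalue <= cutoff`; self-hits (subject
species = focal species) are ignored, and genes with no qualifying non-focal
hit receive the maximum rank ("new genes", the species-specific node).
Ranks must form a contiguous `1..n_strata` range with the focal species at
`n_strata` — 11 strata for a bivalve/gastropod-style lineage, 10 for an
annelid-style one.

*Default e-value cutoff:* `1e-3`, the classic phylostratigraphy choice; the
ortholog-calling step uses the stricter `1e-5` conventional for reciprocal
best hits. Both are configurable. Hit rows naming species absent from the
lineage map are skipped with a warning by default (`strict=True` raises):
real hit tables routinely contain taxa outside the curated lineage.

The assignment is monotone in the cutoff (loosening it can only make genes
older), idempotent, and bounded by `[1, n_strata]`; these are asserted as
properties.

## Expression preprocessing

The weighted expression `e_is` used by every index is obtained by dividing
raw counts by CDS length (RNA-seq reads land anywhere in a transcript, so
per-base values track molecule numbers) and then TMM-scaling between
stages. Length-weighting before TMM is the default order; a switch allows
TMM on raw counts.

**TMM.** Our implementation follows the published trimmed-mean-of-M-values
algorithm: genes zero in either library are excluded; M (log2 ratio of
library-scaled proportions) and A (average log2 abundance) are doubly
trimmed (30% / 5% by default); the surviving M-values are averaged with
inverse delta-method binomial variances as weights; the factor is `2^mean`.
The reference stage is the one whose upper-quartile expression of
library-scaled values is closest to the mean upper quartile, and its factor
is fixed at 1 (rather than normalising the factor vector to geometric mean
1 — only ratios matter downstream). The test suite pins the implementation
to edgeR's `calcNormFactors` on a 200-gene composition-shift fixture at
1e-6. Note the precision weights see absolute counts, so factors are only
approximately invariant to rescaling a column; `weighted=False` gives the
exactly scale-invariant unweighted trimmed mean.

**Redundancy filters.** Two graph-based filters, each collapsing connected
components to a single representative (longest CDS, ties to the
lexicographically smallest id):

- *correlation filter* — candidates are short (`cds_length <= 500 bp`) and
  extremely expressed (peak `>= 10,000`) genes; edges connect candidate
  pairs with Pearson r > 0.99 across stages. The length/peak defaults are
  calibrated to the retrotransposon-like elements such filters target
  (reported at 186–465 bp and up to ~120,000 RPKM) and are configurable;
  constant-expression genes are excluded from candidacy (r undefined).
- *sequence filter* — edges connect pairs with ≥97% protein identity, ≥95%
  DNA identity and zero gaps in the aligned protein region, from an
  all-vs-all self-alignment table.

## Watterson's θ per gene

θ̂ = S / (H_{n−1} · L) with S the number of segregating sites in the gene,
n = 2 × (number of diploid individuals in the VCF) and L the annotated gene
length. A site is segregating when at least two distinct alleles appear
among called genotype alleles; multi-allelic records count once; duplicated
positions are collapsed. The whole-gene n is used even at sites with
missing calls — the convention of gene-wise diversity software operating on
inferred diploid sequences — rather than a per-site n reduction; L is the
annotated length rather than the callable length. Both choices are
documented here because they matter when coverage is uneven; with complete
synthetic genotypes they coincide. Genes without SNP coverage get θ = 0 and
an explicit `no_snp_data` flag.

The estimator's unbiasedness is checked by simulation
(S ~ Poisson(θ·H·L) inverted through the closed form).

## Indices

- `TAI_s = Σ ps_i e_is / Σ e_is`; a convex combination of ranks, invariant
  to any positive rescaling of a stage column.
- `TPI_s = 10³ Σ θ_i e_is / Σ e_is` (per-kilobase scale by default).
- `REL(ps, s)`: mean partial concentration `f̄` of the phylostratum's genes
  (f_is = e_is / Σ_j e_js), min–max normalized across stages; a
  phylostratum with constant f̄ has no dynamics and yields NaN (not 0),
  preserving the distinction between "no dynamics" and "minimum".
- per-gene min–max: (x − min)/(max − min) across stages; constant genes are
  NaN and flagged.

Genes with zero expression at every stage are dropped (logged) before any
index: they carry no weight and would distort per-stratum means. A stage
whose total expression is zero is an error naming the stage.

## Uncertainty

**Bootstrap.** Genes are resampled with replacement; one resample is shared
across all stages of a replicate, preserving the profile's across-stage
coupling (per-stage independent resampling is available). Percentile
intervals at `(1±level)/2`. Degenerate resamples that empty a stage are
redrawn, with a retry cap. Empirical coverage of the 95% band is verified
on synthetic replicates drawn from a fixed 20,000-gene population.

**Permutation null.** Per stage, the covariate vector (ranks or θ) is
shuffled across genes `n_perm` times; each stage's surrogate distribution
is summarised by a gamma fitted by the method of moments (shape = m²/v,
scale = v/m, sample moments) and the observed index scored two-sided,
`p = min(1, 2·min(F, 1−F))` (one-sided optional). Permuting the expression
vector as well would not change the sampling distribution — the stage total
is permutation-invariant — so only the covariate is shuffled; likewise
permuting gene length separately from already-length-normalized expression
would be a no-op. The gamma approximation is accurate at transcriptome
scale; our checks place its agreement with empirical permutation p-values
within a factor of 2 down to p ≈ 10⁻³ from ~500 genes upward, degrading for
very small gene sets (the 4-gene enumeration oracle therefore checks
moments, not tails).

**Combined pattern p-value.** Per-stage p-values are *not* independent:
every stage weights the same genes, and under the null the realized
rank–expression association is largely shared across stages. Closed-form
Fisher combination is therefore anticonservative here — on the default null
generator it rejected at ≈0.20 for α = 0.05. The default combiner instead
draws each surrogate replicate with **one permutation shared across all
stages**, scores surrogate profiles exactly like the observed one
(per-stage gamma p, then the Fisher statistic −2Σ ln p), and reports the
add-one rank of the observed statistic among surrogates. This calibrates
the test by construction (measured type-I ≈ 0.04) at the cost of a
resolution floor of `1/(n_perm+1)`; the closed-form Fisher p (and
Stouffer's Z) are always reported alongside for comparability with the
conventional approach, which can resolve astronomically small values.
Per-stage surrogate marginals are identical under shared vs fresh
permutations.

A constant covariate makes every surrogate equal the observed index; the
convention is p = 1 (and fewer than 3 distinct covariate values logs a
near-degeneracy warning).

## Cross-species similarity

Reciprocal best hits at `evalue <= 1e-5`; "best" = lowest e-value, ties by
highest bitscore, then lexicographically smallest subject id, making the
map deterministic. Spearman ρ is computed as Pearson on average-tied ranks
(exact under ties, unlike the no-ties closed form). Ortholog pairs silent
at every stage in either species are dropped before ranking (all-tie
vectors distort ρ); constant stage columns yield NaN cells with a warning.
Best-matching stages resolve ties to the earliest developmental stage.
Similarity should be computed on comparable units in both species; the
pipeline driver uses raw counts on both sides (rank-based ρ does not see
per-gene scale, and CDS lengths are generally unavailable for the second
species), while the library function accepts whatever units the caller
prepared.

## Synthetic studies

The generator emulates the design of a stage-resolved hourglass study of a
marine invertebrate: 11 phylostrata (age distribution skewed old with a
bump of species-specific genes), 11 ordered stages, 10 resequenced diploid
individuals, log-normal CDS lengths (median ≈ 1.2 kb) and baselines,
negative-binomial counts (dispersion 0.1; Poisson as the limiting flag) —
RNA-seq counts are overdispersed — and a mild stage-to-stage depth wobble.

The hourglass signal multiplies old-strata genes (rank ≤ n_strata/3) by δ
at the phylotypic stage and youngest-strata genes (rank ≥ n_strata−1) by δ
at the terminal stage, through Gaussian bumps of width ≈ n_stages/8,
mirroring the two opposing phylostratum groups seen in real ontogenies;
δ = 1 is the exact null. Per-gene θ is log-normal, optionally trending with
age. SNP sites are drawn with E[S] = θ·H_{2n−1}·L and uniformly placed
derived-allele counts, so `segregating_sites` recovers S exactly and θ̂ is
unbiased by construction. The hit table is built so age assignment recovers
the generating ranks with 100% accuracy. Species-B expression applies
random value swaps per stage, growing with distance from the phylotypic
stage, so the cross-species rank correlation peaks there by construction.

What the generator does **not** emulate: genuinely novel species-B biology
(its expression is a perturbed copy, not an independent evolution), read
mapping artefacts, coverage-dependent SNP calling error, linked selection
or demography in the coalescent sense (S is Poisson, not genealogical),
and isoform structure. Passing tests demonstrate correctness and
calibration of the statistical machinery under these idealized conditions,
not robustness to the upstream error processes of real data.

A hand-checkable 6-gene/5-stage/3-individual fixture (`fixture_small`)
ships with a manifest of pen-and-paper index and θ values used as formula
oracles throughout the tests.

## Problem sizes used in validation

Formula and enumeration oracles run on toy inputs (≤ 6 genes). Calibration
experiments use 300 replicates of a 300-gene/8-stage null and 100
replicates of a 2000-gene hourglass study at n_perm = 200, and 200
bootstrap-coverage replicates of 300 genes sampled from a 20,000-gene
population — sizes chosen so the full suite completes in well under a
minute while keeping Monte-Carlo error small relative to the asserted
bands (e.g. a true 5% rejection rate measured over 300 replicates has
standard error ≈ 1.3%).

## Known limitations

- The empirical combined p cannot go below `1/(n_perm+1)`; use the reported
  Fisher p for a magnitude-style statistic, remembering its independence
  assumption.
- θ uses annotated gene length, not callable length; with incomplete
  coverage it is biased downward.
- The redundancy filters' candidacy thresholds are study-calibrated
  defaults, not universal constants.
- REL rows for single-gene phylostrata are as noisy as that gene.
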