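# transcriptage

Expression-weighted transcriptome age and polymorphism indices across
development, for phylo-transcriptomic studies of the developmental
hourglass.

## The problem

Stage-resolved RNA-seq lets you ask *how evolutionarily old* — and *how
polymorphic within a population* — a transcriptome is at each point of
ontogeny. In several animal and plant lineages the mid-developmental
(phylotypic) period expresses the oldest, most conserved gene set, giving
the profile its hourglass shape. Testing that pattern requires a chain of
analyses that this package implements end to end:

1. **Phylostratigraphy** (`phylostrata`): each gene is assigned a
   phylostratum rank *ps* — the oldest lineage node with a detectable
   homolog in a taxonomically partitioned database (rank 1 = e.g. cellular
   organisms; the maximum rank = species-specific "new genes" with no hit
   outside the focal species).
2. **Expression preprocessing** (`preprocess`): read counts are divided by
   CDS length, TMM-normalized between stages (trimmed mean of M-values,
   correcting RNA composition effects), and cleaned by two redundancy
   filters — one collapsing clusters of short, extremely expressed genes
   with near-identical expression curves (Pearson r > 0.99), one collapsing
   sequence-redundant genes (≥97% protein and ≥95% DNA identity, gap-free
   protein alignment).
3. **Population diversity** (`popgen`): per-gene Watterson's θ per site,
   θ = S / (H₍ₙ₋₁₎ · L), from a multi-individual VCF and a gene-coordinate
   BED.
4. **Indices** (`indices`): per developmental stage *s*, with weighted
   expression *e₍ᵢₛ₎*,

   - TAI(s) = Σᵢ psᵢ·e₍ᵢₛ₎ / Σᵢ e₍ᵢₛ₎ — the transcriptome age index
     (low = old transcriptome);
   - TPI(s) = 10³ · Σᵢ θᵢ·e₍ᵢₛ₎ / Σᵢ e₍ᵢₛ₎ — the transcriptome
     polymorphism index, θ per kilobase (low = conserved within the
     population);
   - REL(ps, s) — each phylostratum's mean partial concentration, min–max
     scaled to [0, 1] across stages;
   - per-gene min–max profiles for expression-timing panels.
5. **Inference** (`inference`): gene-resampling bootstrap confidence bands;
   a per-stage permutation null summarised by a moment-fitted gamma
   distribution; and a combined pattern p-value (dependence-aware by
   default, closed-form Fisher/Stouffer available).
6. **Cross-species similarity** (`similarity`): reciprocal-best-hit
   orthologs and all-stages-by-all-stages Spearman ρ grids.
7. **Synthetic studies** (`synthetic`): a generator producing every input
   the pipeline reads — counts, gene tables, hit tables, lineage maps,
   VCF + BED, a second species — with known ground truth (gene ages, θ,
   the injected hourglass signal), so the whole chain is testable without
   any external download.

## Worked example

Fit a TAI profile on a synthetic hourglass study (2000 genes, 11 stages,
3-fold old-gene boost at stage S06):

```python
from transcriptage import (SimConfig, simulate_dataset, StageIndexModel,
                           length_weight, tmm_normalize)

cfg = SimConfig(n_genes=2000, hourglass_effect=3.0, seed=42)
study = simulate_dataset(cfg)
genes = study.genes.rename(columns={"theta_true": "theta"})
expr = tmm_normalize(length_weight(study.counts, genes))
results = StageIndexModel(expr, genes, index="TAI").fit(
    n_boot=1000, n_perm=1000, seed=42)
print(results.summary_text())
```

```
TAI profile over 11 stages (2000 genes)
        TAI  ci_low  ci_high    p_value
stage
S01   5.579   5.324    5.848     0.4106
S02   5.487   5.233    5.758    0.09985
S03   5.342   5.059    5.614    0.00575
S04   4.767   4.506    5.027  3.099e-15
S05   4.079   3.848    4.321  4.175e-27
S06   3.831   3.619    4.067  1.107e-41
S07   4.182   3.949    4.438  9.555e-31
S08   4.926    4.66    5.221  1.369e-08
S09   6.299   5.992    6.606  1.129e-06
S10   7.232   6.909    7.539 2.225e-308
S11   7.584   7.289    7.861 2.225e-308
combined pattern p-value (empirical): 0.000999
lowest index at stage: S06
```

The profile dips exactly at the injected phylotypic stage S06 (the oldest
transcriptome), each stage carries its 95% bootstrap band and
permutation/gamma p-value, and the combined pattern p is the smallest value
resolvable with 1000 shared-permutation surrogates (the per-stage gamma
p-values show how extreme individual stages are).

The same workflow is available from the shell:

```bash
transcriptage simulate --n-genes 2000 --delta 3 --seed 42 --out study/
transcriptage theta --vcf study/snps.vcf --bed study/genes.bed \
    --genes study/genes.tsv --out theta.tsv
transcriptage test-pattern --counts study/counts.tsv --genes study/genes.tsv \
    --index TAI --seed 42 --out tai_profile.tsv
```

plus `assign-ages`, `normalize`, `tai`, `tpi`, `rel`, `similarity` and a
`run` command driving the full pipeline from a YAML config.

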