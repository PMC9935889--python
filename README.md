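# magbias

Genome-resolved metagenomics reconstructs draft bacterial genomes (MAGs,
metagenome-assembled genomes) that are usually incomplete: a genome
estimated at 70% completeness is missing roughly a third of its genes, and
with them part of every metabolic pathway it encodes. When per-gene
annotations are distilled into **module fullness** — the proportion of a
metabolic module's enzymatic steps enabled by the genes present — that
missing content shows up as a systematic, completeness-dependent deficit
that is easily mistaken for biology.

`magbias` is a library and CLI for microbial ecologists who compare
functional profiles across MAGs. It quantifies the completeness bias,
models it, and corrects for it:

1. **Distillation.** Gene content × module catalog → fullness matrix
   `f_mg = k_mg / S_m`, where `k_mg` is the number of satisfied steps of
   module *m* in genome *g* and `S_m` the module's step count (a step is
   satisfied by any one of its alternative orthologous genes). Modules
   present in fewer than 5% of genomes are dropped.
2. **Per-module GLM.** For each module, a weighted binomial GLM with logit
   link, `k_mg ~ Binomial(S_m, p_mg)`,
   `logit(p_mg) = α + phylum_g + β·c_g + (phylum_g × c_g)`,
   with completeness `c_g` as a proportion — one completeness slope per
   phylum.
3. **Slope meta-analysis.** The per-(module, phylum) slopes `β̂_mp` enter a
   linear mixed model `β̂ ~ phylum + domain + steps + (1 | module)` (REML),
   with 95% percentile confidence intervals from a 999-simulation
   parametric bootstrap and marginal predictions per factor level.
4. **Correction.** For an incomplete genome, each fitted module yields a
   predicted fullness at the observed completeness and at 100%; their
   difference is added to the observed fullness and the result clamped to
   [0, 1].
5. **Validation.** Complete genomes are degraded by random contig dropout
   at 70/80/90% retention (ten replicates each), completeness is
   re-estimated from single-copy core genes, and raw vs corrected profiles
   are compared to the complete genome in a joint PCoA.

A first-class synthetic-data module generates module catalogs, complete
genomes, mechanistic incompleteness (contig dropout) and parametric
fullness data from a known logit-linear truth, so every stage is testable
against generative parameters.

## Worked example

```python
import magbias as mb

catalog = mb.generate_catalog(60, mb.poisson_steps(6.0), seed=1)
cohort  = mb.simulate_cohort(catalog, 200, seed=2)       # contig-dropout MAGs
matrix  = mb.filter_modules(mb.build_matrix(cohort, catalog), 0.05)
fits    = mb.fit_all_modules(matrix)

fit = fits["M00002"]
print(round(fit.slopes["Proteobacteria"], 2))
print(round(mb.fullness_change(fit, "Proteobacteria", 0.70, 1.00), 1))
```

```
2.83
19.3
```

The first number is the fitted logit-scale slope of fullness on
completeness for Proteobacteria in module M00002; the second says that
raising completeness from 70% to 100% raises this module's expected
fullness by 19.3 percentage points — bias that would be misread as a
functional difference between genomes of unequal quality.

The same analysis from the shell:

```bash
magbias simulate --n-genomes 200 --n-modules 60 --seed 1337 --outdir sim
magbias distill  --annotations sim/annotations.tsv --metadata sim/metadata.tsv \
                 --catalog sim/catalog.json --outdir distilled
magbias fit      --fullness-dir distilled --outdir fits
magbias meta     --slopes fits/glm_fits.tsv --n-sim 999 --seed 1337 --outdir meta
magbias correct  --fullness-dir distilled --fits fits/fits.json --outdir corrected
magbias all      --outdir demo   # whole pipeline incl. subsampling validation
```

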