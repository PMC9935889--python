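# Methods

## The problem being modelled

Metabolic capability of a bacterial genome is summarised per module as
*fullness*: the fraction of the module's enzymatic steps for which the
genome carries at least one enabling orthologous gene. A module here is an
ordered list of steps; each step is a non-empty set of alternative gene
identifiers, and a step counts as satisfied when any one alternative is
present (pure OR semantics — within-step enzyme complexes that would
require several genes simultaneously are not modelled; this is a
documented simplification of real module logic). Fullness of module *m*
in genome *g* is `f_mg = k_mg / S_m` with `k_mg` satisfied steps out of
`S_m`.

Because metagenome-assembled genomes lose content roughly at random,
fullness declines with genome completeness even when the underlying
organism's capabilities are identical. The package models, quantifies and
corrects that dependence.

## Per-module binomial GLM

For each module, satisfied-step counts are modelled as
`k_mg ~ Binomial(S_m, p_mg)` with

```
logit(p_mg) = alpha + phylum_g + beta * c_g + (phylum_g x c_g)
```

where `c_g` is estimated completeness **as a proportion** and phylum is
treatment-coded with the alphabetically first level as reference
(Actinobacteriota in the default four-phylum universe). The two-column
(successes, failures) response makes `S_m` the binomial weight, so a
ten-step module carries ten times the information of a one-step module.
Per-phylum slopes are derived as main effect + interaction; they are
invariant to the choice of reference level, which the tests assert.
Fitting is IRLS (statsmodels GLM), relative deviance tolerance 1e-8,
maximum 100 iterations. Fits that fail to converge or separate are
returned flagged `converged=False` with NaN coefficients and are excluded
from all downstream steps rather than patched — no Firth-type correction
is attempted.

Completeness enters as a proportion throughout the package; slopes on a
percent scale would be exactly 100× smaller (a reparameterisation the
tests check). TSV metadata can be read/written on the percent scale with
an explicit flag.

## Slope meta-analysis

The per-(module, phylum) slope estimates form the response of a linear
mixed model

```
slope ~ phylum + domain + n_steps + (1 | module)
```

fitted by REML (statsmodels MixedLM; the default optimizer falls back to
Powell and CG near the variance boundary). Slopes enter unweighted —
their standard errors are ignored by design; a precision-weighted variant
is out of scope. Each module contributes up to four correlated slopes,
which the module-level random intercept absorbs. A fit whose module
variance collapses to (effectively) zero is flagged singular but still
returned.

All 95% confidence intervals — marginal predictions per phylum and domain
level and the steps coefficient alike — come from one mechanism: a
percentile parametric bootstrap (default 999 simulations) that redraws
module intercepts and residuals from the fitted variances, refits, and
takes the 2.5/97.5 percentiles. Using the same bootstrap for the steps
coefficient (rather than a profile-likelihood interval) keeps one code
path for every reported interval; the difference is negligible at the
table sizes involved. Failed refits are dropped and counted; more than 5%
failures aborts the run. Marginal predictions hold the non-focal factor
at its reference level and step count at its mean.

Evidence is read off exactly as the intervals state it: non-overlapping
95% CIs between factor levels count as evidence of a difference, and a
steps-coefficient CI excluding zero as evidence of an association with
module complexity.

## Correction

For a genome of phylum *p* and estimated completeness *c*, each converged
module fit yields `p_obs = invlogit(a_p + b_p c)` and
`p_100 = invlogit(a_p + b_p)`; the corrected fullness is
`clamp(f_obs + p_100 - p_obs, 0, 1)`. The upper clamp implements the
round-to-1 rule; the lower clamp is its symmetric counterpart, needed for
negative-slope modules, and both are flagged in the audit table. Modules
without a usable fit (missing, non-converged, or unaware of the genome's
phylum) pass through unchanged with a skip flag and a logged warning. The
correction is driven by the SCCG-estimated completeness by default,
matching a marker-based workflow; flags switch to the true retained
fraction or the nominal retention tier for clean experiments. At
completeness 1 the correction is the identity. Its defining property —
on data generated from the fitted model itself, corrected fullness has
mean equal to the model's fullness at 100% completeness — is verified by
simulation in the test suite.

## Synthetic data: what it emulates and what it does not

The generator stands in for a real cohort (reference databases, marker-
gene completeness estimation, HMM annotation) with two routes.

*Mechanistic route.* Complete genomes are built from the catalog: each
module is included with probability 0.7 and contributes one gene per
step; 100 single-copy core genes (SCCGs) are always present; all genes
land uniformly at random on the genome's contigs (42 by default for
complete references, 200 for dropout experiments so the retained fraction
concentrates). Incompleteness = dropping whole contigs:
`round(retention x n_contigs)` kept (round half up, floor of one).
Completeness is then re-estimated as the surviving SCCG fraction — noisy
by construction, exactly as marker-based estimators are. Under uniform
placement the expected fullness of a fully present module equals the
retention, giving a closed-form check of the whole mechanical chain.

*Parametric route.* Fullness is drawn directly from the GLM's generative
mirror: `k ~ Binomial(S_m, invlogit(alpha_m + beta_mp c))`, completeness
uniform on [0.70, 1.00], four phyla in equal proportions. Default
generative parameters — `alpha_m ~ N(-1.5, 1)`, base slope `~ N(4, 1)`,
phylum offsets +0.4 (Proteobacteria), +0.1 (Firmicutes), −0.1
(Actinobacteriota), −0.4 (Bacteroidota), and a −0.05 per-step complexity
effect — were chosen to produce the regime observed in large MAG
cohorts: overwhelmingly positive slopes, a fullness gain of roughly
10–20 percentage points (mean ± sd around 13 ± 8) from 70% to 100%
completeness, Proteobacteria with the strongest association and complex
modules with weaker ones. Step counts follow 1 + Poisson(6); the default
catalog size is 195 modules across ten functional-domain labels.

Not emulated: operon/island clustering of functionally related genes
(gene placement is uniform, so contig dropout removes module steps
independently; real MAGs likely lose co-located steps together, making
fullness more bimodal), shared genes between modules, read- and
assembly-level artefacts, and real marker sets. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative assumptions, not that the bias in any particular real cohort
is fully captured.

Contamination is zero by default; a helper duplicates a fraction of the
SCCG set to exercise the contamination filter only.

## Cohort filters and thresholds

Module prevalence: keep modules with fullness > 0 in at least
`floor(0.05 x n_genomes)` genomes ("present" means any step satisfied,
since distillation reports partial modules). On an 11,842-genome cohort
the floor rule gives 592. Genome filters: completeness ≥ 0.70
(inclusive), contamination < 0.10 (strict); both boundary policies are
configurable. The optional per-1%-window balanced subsampling uses
half-open windows [lower, upper) in percent units.

## Ordination and the validation experiment

Profile distances default to Euclidean on fullness vectors (bounded,
dense data; Bray-Curtis available). PCoA is classical MDS — Gower
double-centering of −½D², eigendecomposition, coordinates scaled by the
square root of the eigenvalues (via scikit-bio); axes with negative
eigenvalues are dropped and their absolute mass reported. For Euclidean
input the embedding reproduces the distances to numerical precision and
coincides with PCA scores of the centred profiles up to sign, both of
which are tested.

The validation experiment degrades each complete genome ten times at
retention tiers 0.7/0.8/0.9 (8 genomes × 3 tiers × 10 replicates = 240
subsamples in the default design), corrects the distilled profiles with
GLMs trained on an independent cohort, and embeds complete + raw +
corrected profiles in one joint PCoA. Replicate scatter per (genome,
tier) is summarised by 95% normal-approximation ellipses on the first two
axes (χ²₂ quantile of the sample covariance). Overcorrection is reported
as the signed projection of (corrected − complete) onto the
(raw − complete) direction — negative values mean the correction
overshot past the complete genome.

## Determinism and problem sizes

Every stochastic operation takes a seed (integer or numpy Generator);
pipeline stages derive all randomness from one master seed recorded in a
manifest, so outputs are reproducible bit-for-bit. The documented default
seed is 1337.

`scripts/acceptance.py` runs the analysis at desk scale: a 195-module
catalog, a 2,000-genome parametric cohort for the GLM stage, a 60-module
slope table for the 999-simulation bootstrap, 200 dropout replicates for
the retention check, a 200-genome mechanistic training cohort and the
240-subsample validation design. These sizes keep a full run around a
minute while leaving Monte-Carlo error well inside the tolerances the
tests use.

## Known limitations

- OR-only step semantics; no enzyme-complex (AND) logic.
- Slope meta-analysis ignores the slopes' estimation uncertainty.
- The correction shifts fullness by a phylum-level expectation; it cannot
  recover which specific steps were lost, and it corrects genuinely absent
  modules upward like any module without gene evidence.
- Uniform gene placement makes contig dropout an optimistic model of real
  MAG incompleteness (see above).
- No overdispersion modelling in the GLMs (quasi-binomial/beta-binomial
  out of scope).
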