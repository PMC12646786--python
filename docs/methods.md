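# Methods

This note documents the models implemented in `cytocline`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Transect geometry

All clines are fitted on a scaled transect position. Distances between
sampling coordinates are great-circle (haversine) with a fixed mean Earth
radius of 6371.0 km; no ellipsoid correction is applied, which is
negligible relative to sampling noise at contact-zone scale. Within each
contact zone, distance is measured from an anchor sample — by default the
westernmost (minimum longitude), standing in for "closest to the coast"
in a hybrid zone that runs inland from the Pacific; an explicit anchor id
can be given instead — and min-max normalized to [0, 1]. Normalization is
per zone, never pooled, so zones of different physical lengths are
comparable on the same axis.

## The cline model family

The core model is the hybrid-zone sigmoid

    Psi(x) = (1 + tanh(2 (x - c) / w)) / 2

with center `c` in (0, 1) (transect position of the midpoint) and width
`w` > 0 defined as 1 / maximum slope, so `d p / d x` at the center is
`(pmax - pmin) / w`. Two optional extensions follow stepped-cline
practice:

- **Scaling.** `none` pins the asymptotes at 0 and 1; `fixed` pins them
  at the empirical mean ancestry in the outer deciles of the transect
  (an observed-frequency convention; the outer-decile rule is this
  package's concrete choice); `free` estimates `pmin < pmax` as
  parameters.
- **Tails.** Exponential introgression tails attach continuously at
  `c - dL` and/or `c + dR` with decay rate `4 tau / w` per unit x
  (`left`, `right`, `both`; `mirror` shares one `(delta, tau)` pair
  across both sides). Continuity at the junctions is exact by
  construction and property-tested to 1e-6.

Three likelihoods share this mean function: Bernoulli for binary
chlorotype, binomial with two trials for diploid ancestry counts, and
Gaussian for continuous mean ancestry with sigma^2 profiled analytically.
Probabilities are clamped to [1e-9, 1 - 1e-9] before logs so boundary
data stay finite.

**Fitting.** Bounded L-BFGS-B from a seeded Latin-hypercube of start
points (default 20) plus one moment-based start; the best optimum is
returned and refits with the same seed are bit-identical. Bounds:
c in [0, 1], w in [1e-3, 2], delta in [0, 1], tau in [1e-3, 1]. A start
whose line search aborts at the shared optimum still counts as converged
if another start confirms the value. Degenerate data (all responses
equal) return a boundary-flagged fit rather than an exception. An
exhaustive grid over (c, w) on small instances never beats the optimizer
by more than 1e-6 log-likelihood units (tested).

**Model choice and uncertainty.** AIC over the requested scaling x tails
variants (all 15 available), ties broken toward fewer parameters and then
no tails. Uncertainty is summarised by 2-log-likelihood-unit profile
support intervals found by bisection on the profile likelihood
(re-optimizing nuisance parameters at each trial value); 2 units is
asymptotically ~95% for one degree of freedom. MCMC credible intervals
were deliberately not used: the profile construction is deterministic,
testable, and needs no sampler tuning. The cline is monotone
non-decreasing by convention; a transect whose focal taxon declines with
x should be recoded (flip the ancestry coding or the transect).

## Co-introgression classification and constrained LRTs

Two reference clines are fitted per zone: the chloroplast cline (Bernoulli
on chlorotype) and the "mean non-interacting nuclear" cline (Gaussian on
per-individual ancestry averaged across genes — a summary cline, not a
pooled multi-gene likelihood). Per-gene data are diploid ancestry counts:
each haplotype's gene ancestry is its majority state across the ancestry
matrix positions within the gene span +/- 100 bp, and the diploid count is
the sum over the two haplotypes.

A gene **overlaps** a reference when BOTH its center and width are
concordant with the reference's support intervals. Concordance is
interval-interval: the gene's own support interval must intersect the
reference's. (A point-in-interval rule was considered and rejected: when
gene and reference are estimated from data of comparable information, a
point estimate falls outside the other fit's ~95% interval roughly a
quarter of the time however large n is, which destroys scan sensitivity
without reflecting any real discordance. The point rule remains as a
fallback for fits without computed intervals.) Classification:
co-introgressing = overlaps chloroplast but not nuclear; ambiguous =
overlaps both; independent otherwise; unevaluable when the gene fit did
not converge. The scan's default model set per gene is scaling in
{none, free} with no tails, selected by AIC — tails are rarely
identifiable from per-gene diploid counts at contact-zone sample sizes,
and the restriction keeps a multi-hundred-gene scan tractable; the full
15-variant selection remains available.

Each gene also gets two **constrained LRTs** (against the chloroplast and
the nuclear reference). The constrained model refits the gene's selected
variant with the center *fixed at the reference's center estimate* (a
value inside the reference's 95% support interval), giving a cleanly
nested model with one constrained degree of freedom;
`2 (lnL_free - lnL_constrained)` is referred to chi-square(1). An
alternative reading — bounding the center to the whole reference interval
— is implemented as `mode="interval"` but is structurally conservative
(its null rejection rate is far below nominal, measured ~0.002 at
alpha = 0.05) and is not the default. Null calibration of the default is
verified by simulation: genes generated at the reference's fitted center
reject at 0.02–0.09 over 500 replicates. No multiple-testing correction
is applied to per-gene p-values; raw values are emitted.

## Firth logistic climate associations

Chlorotype (PB = 0, PT = 1) is regressed on one climate variable at a
time, per contact zone, by maximizing the Firth-penalized log-likelihood
`l*(beta) = l(beta) + 1/2 log det I(beta)` with modified-score Newton
iterations (hat-value-adjusted residuals), step-halving on non-increase
(at most 5 halvings), tolerance 1e-8 on the modified score, 100
iterations maximum. The penalty guarantees finite estimates under
complete separation — the failure mode that motivates the method on steep
climatic gradients. In the saturated 2x2 case the penalized maximum
equals the Haldane half-cell-corrected log odds ratio, and the
intercept-only fit gives p = (k + 1/2)/(n + 1); both closed forms anchor
the tests. Slopes are reported per natural unit (per degree C, per %, per
mm) and predictors are not standardized. Univariate models are the
default because variable-wise effects are the reporting unit; a
multivariable design can be passed to `firth_fit` directly. Standard
errors are Wald, from the inverse penalized information.

## Quantitative genetics

Both mixed models are estimated by EM-REML on Henderson's mixed-model
equations, written in-house because the implementation enforces two
properties used as invariants: the restricted likelihood is
non-decreasing across EM iterations (asserted each step, away from the
zero-residual boundary where the floored variance makes the objective
numerically meaningless), and variance components stay non-negative, with
estimates reaching the zero boundary truncated and flagged rather than
hidden. Convergence is relative change < 1e-8 in every component. For
balanced designs the estimates agree with closed-form ANOVA
method-of-moments to 1e-3 (tested). The dense equations limit the
implementation to the small designs it targets (hundreds of genotypes).

- **Heritability.** Per garden and trait: genotype and block as crossed
  random effects, `H2 = V_G / (V_G + V_E + V_eps)`. With clonal
  replicates V_G is the total genotypic variance, so H2 is broad-sense.
- **Cytonuclear model.** Fixed effects: nuclear ancestry N (continuous in
  [0, 1]), chlorotype C (0/1), their product N x C, and garden
  (treatment-coded); random intercept for block nested in garden.
  OTHER/MISSING chlorotypes are excluded with a logged count. Wald
  p-values per coefficient; `R2_marginal = V_fixed / (V_fixed + V_block
  + V_eps)` and `R2_conditional = (V_fixed + V_block) / (...)` with
  V_fixed the variance of the fixed-effect predictor. The extended model
  with chlorotype x environment and three-way interactions is available
  by adding columns to the design, but the simplified model is the
  default. Unbalanced replication is handled natively by REML; nothing is
  imputed.

## Chloroplast divergence

A column of the plastome alignment is a fixed difference iff every
group-A sequence carries one nucleotide, every group-B sequence a
different one, and no sequence in either group has a gap or ambiguity
code there (strict missing-data rule). Indel columns can be listed but
are never counted as substitutions. Coding effects are classified by
locating the codon from single-interval CDS annotations (a CDS whose
length is not a multiple of 3 is an annotation error), reverse-
complementing minus-strand codons, and translating with table 11 (the
plastid/bacterial code). Two fixed differences in one codon are
classified jointly and flagged `multi_site`.

Polarization builds a neighbour-joining tree on Jukes-Cantor distances
(`d = -3/4 ln(1 - 4/3 p)`, pairwise-complete sites, saturation error at
p >= 3/4). The NJ implementation breaks Q-matrix ties by the
lexicographically smallest cluster-label pair and repairs negative branch
lengths by clamping to zero with the deficit moved to the sister branch,
so output is deterministic and label-order invariant; on additive
matrices it reproduces the generating tree exactly (tested on random
trees of 4–8 taxa). The ancestral chlorotype is the one clustering with
the outgroups — operationally, the *other* group forms a clade excluding
all outgroups; identical-state shortcuts apply first, and calls are
"unresolved" when outgroups split between the states or neither grouping
is clean.

## Synthetic data: what it emulates, and what it does not

All generators draw from named substreams of a single seed
(`numpy` `SeedSequence`), so every output is bit-reproducible from
(config, seed).

- **Hybrid zone.** Sample positions uniform on [0, 1] (endpoints pinned
  so the transect anchors are defined); chlorotype Bernoulli in the
  chloroplast cline, or fixed zone-wide under the `capture` option (the
  chloroplast-capture situation); each gene's two haplotype ancestries
  independent Bernoulli draws from the gene's cline — Hardy-Weinberg at
  the local frequency, constant across the SNPs of a gene (gene-scale
  linkage blocks with no intragenic recombination). Co-introgressing
  genes take the chloroplast cline's parameters, the rest the nuclear
  cline's, with optional per-gene center jitter. Real data violate the
  independence assumptions through linkage disequilibrium between genes,
  between haplotypes, and between chlorotype and nuclear background;
  passing recovery tests therefore demonstrates estimator correctness
  under the model, not robustness to LD.
- **Climate.** Each variable is linear in transect position plus Gaussian
  noise; default slopes make the high-trichocarpa end warmer, wetter and
  less continental so association signs match a maritime-vs-boreal
  contrast. Spatial autocorrelation beyond the shared transect trend is
  not simulated.
- **Traits.** `y = mu + b_N N + b_C C + b_NxC N C + b_E E + block + eps`
  with three blocks per garden and one replicate per genotype per block
  (a randomized-complete-block clonal design). The default interaction
  -0.11 matches the scale of a photosystem-II efficiency effect. For the
  heritability generator, random effects are planted with *realized*
  sample variance equal to the recorded truth (draws are standardized):
  with only three blocks the realized variance of raw draws has a
  chi-square_2 spread, and recovery tests are only meaningful against the
  variance actually present in the data.
- **Alignment.** Synonymous differences are planted at third positions of
  fourfold-degenerate codons, nonsynonymous at first positions chosen to
  change the amino acid, noncoding between genes; each planted codon is
  reserved whole so planted sites never share a codon, and within-group
  polymorphism is placed only at unplanted positions with one sequence
  per group left unmutated, so polymorphism can neither create nor
  destroy a fixed difference. Default counts (33 + 9 + 20 = 62 total, 9
  nonsynonymous) mirror the divergence scale of the two study
  chlorotypes.

## Pipeline and problem sizes

`run_all` executes simulate -> transect -> co-introgression scan ->
climate associations -> quantitative genetics -> chloroplast divergence,
records per-stage status and wall time, and fails soft: a stage failure
skips only dependents. The run report's summary block is fully
determined by (inputs, config, seed), which the determinism test asserts
by running the pipeline twice. The test suite and the acceptance script
use n = 300 samples, 100-gene scans, 500-replicate null calibrations and
50-seed recovery batches — sizes chosen so the estimators' sampling
behaviour is measurable while a full run completes in minutes on one CPU;
the shipped steep-zone scenario (234 genes) is for demonstration. The
generator simulates one contact zone per call; multi-zone studies run the
pipeline per zone, and zone-specific scenarios (for example a capture
zone) are separate config files.

## Known limitations

- No MCMC: support intervals are profile-likelihood, and coverage is
  asymptotic.
- The cline is monotone non-decreasing; decreasing clines require
  recoding.
- No linkage disequilibrium, demography or coalescent structure in the
  generator.
- Wald (not profile-penalized) intervals for Firth fits; Wald (not LRT)
  p-values for mixed-model fixed effects.
- The co-introgression scan's default per-gene model set excludes tail
  variants.
- EM-REML is dense and intended for common-garden-scale designs, not
  genome-scale random effects.
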