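# cytocline

Cytonuclear co-introgression analysis for hybrid zones between sister
species, built around the contact zones of *Populus trichocarpa* x
*P. balsamifera* but applicable to any two-taxon hybrid zone with a
maternally inherited organelle genome.

When two species hybridize, the chloroplast genome (inherited only from
the mother) and the nuclear genome (inherited from both parents) can end
up mismatched. Nuclear genes whose proteins work inside the chloroplast
(N-cp genes) are predicted to *co-introgress* — to move across the species
boundary together with the chloroplast. `cytocline` tests that prediction
and measures its phenotypic consequences:

- **Geographic clines.** Ancestry probability along a scaled transect
  x in [0, 1] is modelled as the hybrid-zone sigmoid
  `p(x) = pmin + (pmax - pmin) * (1 + tanh(2 (x - c) / w)) / 2`
  with center `c` and width `w` = 1 / maximum slope, optionally with
  exponential introgression tails; fitting is multi-start maximum
  likelihood (Bernoulli chlorotype, binomial diploid ancestry counts, or
  Gaussian mean ancestry), model choice across the 15 scaling x tail
  variants is by AIC, and uncertainty comes from 2-log-likelihood-unit
  profile support intervals (approximately 95% for 1 df).
- **Co-introgression scan.** Each gene's cline is compared to the
  chloroplast cline and to a mean non-interacting nuclear reference; a
  gene is called co-introgressing when its center and width are
  concordant with the chloroplast but not the nuclear reference, and two
  constrained-model likelihood-ratio tests (1 df, center fixed at the
  reference estimate) quantify the evidence per gene.
- **Climate associations.** Firth bias-reduced logistic regression of
  chlorotype on climate (TD, MAT, MAP, CMD, RH, PAS), per contact zone —
  finite estimates even under complete separation.
- **Chloroplast divergence.** Fixed-difference scanning of a plastome
  alignment, synonymous/nonsynonymous classification (translation
  table 11), and polarization against outgroups with neighbour-joining
  trees on Jukes-Cantor distances.
- **Quantitative genetics.** EM-REML variance components and broad-sense
  heritability `H2 = V_G / (V_G + V_E + V_eps)` from clonal common-garden
  designs, and the cytonuclear trait model
  `y = mu + b_N N + b_C C + b_NxC (N x C) + b_E E + block(garden) + eps`
  with Wald tests and marginal/conditional R².
- **Synthetic data.** A seeded generator that produces every input with
  recorded ground truth, so every estimator above is exercised against
  known answers.

## Worked example

Fit the chloroplast cline of a steep synthetic contact zone
(`examples/02_fit_chloroplast_cline.py`):

```text
selected variant: scaling=none, tails=none (AIC 33.76)
center: 0.4282  support interval (0.4140, 0.4434)  truth 0.43
width:  0.0600  support interval (0.0362, 0.1002)  truth 0.05
```

The chlorotype switches at 43% of the transect over about 5% of its
length; both planted parameters sit inside their support intervals. Then
scan 40 genes, 5 of which were planted on the chloroplast cline
(`examples/03_cointrogression_scan.py`):

```text
5 of 40 genes classified co-introgressing (5 planted)
independent: 35, ambiguous: 0, unevaluable: 0
example gene0000: co_introgressing; LRT vs chloroplast p=0.19, vs nuclear p=1.11e-99
```

The example gene is statistically indistinguishable from the chloroplast
cline (p = 0.19) and overwhelmingly different from the nuclear reference,
the signature of co-introgression. The other scripts in `examples/` cover
simulation, climate association, heritability/trait models, chloroplast
divergence, and the full pipeline; `examples/scenario_steep_zone.yaml` is
a run-all configuration at the scale of the study system (234 genes, 12
planted co-introgressing).

A thin CLI wraps the same functions:

```sh
cytocline run-all --config examples/scenario_steep_zone.yaml
cytocline simulate --seed 1 --output-dir out
cytocline cpdiff --alignment out/cp_alignment.fasta --cds out/cp_cds.gff3 \
    --group-a A0,A1,A2,A3 --group-b B0,B1,B2,B3 --output out/diffs.tsv
```

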