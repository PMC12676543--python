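# Methods

`suidgxe` implements a genome x environment (G x E) risk analysis for
sudden unexpected infant death (SUID): it classifies whole-genome-sequencing
(WGS) findings in SUID cases into genetic-etiology categories, converts them
to quantitative prevalence risk ratios (PRRs), tiers cases by genetic risk,
and re-estimates environmental hazard ratios in a birth cohort after
excluding cases by tier. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Genotype-frequency cutoffs

A genotype that is a highly penetrant cause of SUID must be rare. Two upper
bounds gate classification; the operative primary cutoff is the larger.

**Prevalence model.** If a fraction `G` of SUID (population prevalence `P`)
is genetic, spread over `l` loci with `d` causal genotypes per locus, each
conveying probability `p` of SUID, then a causal genotype frequency obeys

```
f = P * G / (p * l * d)
```

Defaults: `P = 101/100,000` (US SUID prevalence), `G = 0.33`, `p = 0.9`,
`l = 100`, `d = 20`, giving `f = 1.85e-7` (1.9e-7 at two significant
figures). The formula is sometimes typeset as a bare product; only the
quotient form is dimensionally coherent (a frequency, not a rate times
counts) and reproduces the stated value, so the quotient is implemented.

**Reference-cohort zero-count bound.** A penetrant lethal genotype should be
absent from a large adult reference cohort (gnomAD-style, default
`n = 807,162` subjects). The Wilson score upper limit for zero events
reduces to `z^2 / (n + z^2)`. The default critical value is `z = 2.5758`
(99% two-sided), which yields `8.22e-6` and is the value the classification
cutoff of `8.2e-6` corresponds to; the often-quoted 99.9% level
(`z = 3.2905`) would give `1.34e-5` instead. `crit` is configurable;
the bound is counted over subjects (genotype-level), not alleles.

**Secondary cutoff.** P/LP findings with frequency between the primary
cutoff and `f_secondary = 3.6e-5` are admitted as *possible* etiologies
(implied penetrance below ~25%). The secondary cutoff is a configuration
constant: it is not derivable from the two models above.

## Etiology classification

Each retained finding (gene, disorder, variant class P/LP/VUS, mode of
inheritance, genotype population frequency `f_obs`, phenotype-match flag)
is called, with strict inequalities throughout:

| variant class | `f_obs` < primary | primary <= `f_obs` < secondary | else |
|---|---|---|---|
| P/LP | probable | possible | excluded |
| VUS, phenotype match | probable (upgrade) | excluded | excluded |
| VUS, no match | possible | excluded | excluded |

Findings with unsatisfied MOI, or whose disorder is not associated with
infant death, are excluded. The phenotype upgrade is an input boolean — in
practice it encodes clinical judgement about death-certificate phenotype
overlap, which this package does not attempt to automate. When a gene maps
to several disorders, the one with the greatest infant-death likelihood
(`p_death`) is selected, with a lexicographic disorder-id tie-break for
determinism. A case's category is the best call over its findings
(probable > possible > none). P/LP findings excluded solely by frequency
(diagnostic findings over the cutoff) can be listed with
`--report-demoted`.

The sequencing QC checker applies fixed rules (Q30 >= 80%, error rate
<= 3%, yield > 120 Gb, duplicates < 15% strict, aligned > 98%, Ti/Tv in
[2.0, 2.2], Hom/Het in [0.40, 0.61], >90% of disease genes at 10x, sex
match); a sample passes only if every rule passes.

## PRR quantification and tiers

For a disorder with infant-mortality likelihood `p_death`:

* probable etiology: `PRR = p_death / P`;
* possible etiology: the square root of the probable PRR (expressivity
  discount; square root taken before capping — the cap is unreachable
  post-sqrt at default parameters, the order is fixed for determinism);
* multiple disorders in one case (G x G): the product of the individual
  PRRs;
* cap: `round(1/P) = 990`, the PRR representing certain SUID. (Published
  text uses 991; the config accepts an override. The discrepancy is
  documented, not absorbed.)
* `p_death = 0` returns PRR 1 with a warning — no excess risk is
  representable on a ratio scale.

Tier boundaries: weak `< 3.7 <=` strong `<= 99 <` very strong. The strong
floor is inclusive and the very-strong floor exclusive, consistent with the
printed bands ("3.7 – 99", ">99"); observed weak-tier values in the source
analysis never exceeded 3.3, so the placement of the boundary point is
immaterial there. Cases with no retained findings take combined PRR 1 and
tier weak, so the partition covers every case. A sensitivity sweep re-tiers
the fixed combined PRRs under alternative floor pairs.

Tier-dependent conditioning of environmental (E) factors: very strong
genetic risk subsumes all E factors (genetics sufficient for causality);
strong risk retains only designated causal modifiers (e.g. fever or drugs
modifying an ion-channel disorder); weak risk retains all E factors.

Display rounding: PRR >= 100 to the nearest integer, otherwise one decimal.

## Cohort survival analysis

One row per live birth; outcome `suid`, `other_death` or `alive`; time is
age in days (1–365). SUID is the event; non-SUID deaths are censored at the
day of death and survivors at day 365.

* **Univariate screen**: chi-square (or Fisher's exact for sparse 2x2
  tables; Welch's t for continuous factors) of SUID vs alive-at-one-year;
  retain factors with p <= 0.1 and at least 5 exposed cases. The lenient
  alpha reflects the small case stratum.
* **Adjusted models**: one Cox proportional-hazards model per retained
  factor (lifelines, Efron tie handling — many same-day infant deaths are
  plausible), adjusted for maternal race/ethnicity, age band, education,
  BMI, prenatal-care adequacy and payer, plus maternal nicotine use except
  in the nicotine model itself (smoking confounds prenatal and infant
  factors). Categorical factors are coded against the modal reference
  level. A factor with no events in a stratum is non-estimable and reported
  as NA.
* **Imputation**: the source analysis does not state its method; we use
  seeded single imputation by marginal draw (deterministic given the seed,
  `<col>_imputed` flags retained) with a no-imputation mode for the
  with/without check.
* **Stratified re-analysis**: five comparisons against the fixed survivor
  pool — all SUID cases; without very strong genetic risk; without strong
  or very strong; and, as sensitivity analyses, without probable etiology
  and without probable or possible etiology. Only SUID cases are ever
  excluded. Sibling non-independence is not adjusted by default (a
  robust-variance option exists) to mirror the source analysis.

## Synthetic data

Real registry data are restricted, so the generator provides ground truth.

* **Cohort**: exposures are Bernoulli at configured prevalences (factors in
  a correlation group share one latent uniform, giving comonotone
  dependence); SUID times are exponential with per-infant rate
  `base * exp(sum of exposure log-HRs)`, competing deaths exponential and
  covariate-free; first event wins; times are rounded up to whole days.
  Constant hazards suffice because Cox estimation is rank-based — any
  proportional-hazards baseline gives the same estimand, and the
  exponential admits closed-form checks. Defaults mirror the study
  conditions: cumulative SUID incidence 36.6/100,000, competing mortality
  (2686-227)/620,606, and exposure prevalences/true hazard ratios set to
  the significant cohort factors (nicotine 2%/HR 2.9, cannabis 1%/3.7,
  other substance 1.5%/2.6, depression 3%/2.1, multiparity 60%/1.5,
  preterm 8%/2.1, very preterm 1.5%/3.4, respiratory distress 1%/2.5,
  preexisting hypertension 2%/2.4, malformation 2%/1.5). Maternal
  adjustment covariates are generated with realistic marginals and null
  effects. All randomness derives from one seed with an independent stream
  per component (keyed by CRC32 of the component name), so adding a factor
  never perturbs the others. Default desk scale is 100,000 births; the full
  620k is a config choice.
* **Catalog**: disorders are drawn in `p_death` bands placed strictly
  inside the tier boundaries (with margin so that products with small
  co-findings cannot cross a boundary); intervention flags are Bernoulli at
  83%.
* **Findings**: each case is planted a category (probable 16%, possible
  47%) and a tier conditional on category (very strong 12% overall, drawn
  among probable cases only — a single possible finding cannot exceed the
  very-strong floor after the square-root rule; strong 34%). Variant
  classes and frequencies are drawn strictly inside the classification
  bands (including a small share of phenotype-upgraded VUS among probable
  calls and relaxed-band LP among possible calls), ~30% of genetic cases
  receive 1–3 extra near-unit-PRR findings (G x G), and loci are drawn from
  shuffled per-band queues, mostly without replacement (extreme locus
  heterogeneity with occasional recurrences). The generator recomputes the
  implied combined PRR with its own plain arithmetic and raises if a
  planted tier is ever violated.
* **G x E confounding scenario**: a carrier subset (0.5%) has hazard ratio
  30; one exposure is common among carriers (50% vs 2%) but has no direct
  effect. Its marginal association with SUID is entirely genetic
  confounding and should collapse when carrier cases (tiered strong) are
  excluded, while a directly causal factor should not attenuate. The
  magnitudes are configurable and chosen for a clear directional signal at
  desk scale, not fitted to any reported estimate.

What passing tests show — and what they do not: exact round-trip recovery
shows the classifier and PRR engine invert the generator's planted structure;
it does not validate the clinical interpretation step (ACMG scoring,
phenotype matching) that produces real findings tables. Cox
parameter-recovery and confounding tests show the estimation machinery is
correct under proportional hazards; real registries add misclassification,
sibling clustering and informative censoring that the generator deliberately
omits.

## Numerical choices and problem sizes

* Frequency comparisons are strict (`<`), matching the stated inequalities.
* Tie-breaks: disorder selection by `(-p_death, disorder_id)`; findings are
  classified in sorted order so outputs are order-independent.
* Test problem sizes: 100 replicate cohorts of 100,000 births (~200 events
  each) for the hazard-ratio coverage check; 20 seeds of 50,000 births for
  the confounding check; 212-case findings tables for round trips. These
  sizes give stable Monte-Carlo behaviour while keeping the default suite
  fast.
* The Wilson bound is validated against an independent root-finding oracle
  (Brent's method on the defining equation) to 1e-12 relative, and against
  statsmodels' Wilson interval.

## Known limitations

* PRR inputs (`p_death`, birth prevalence) are literature constants, not
  estimated; no uncertainty is propagated through the PRR products.
* The phenotype-match upgrade and MOI satisfaction are input booleans;
  zygosity checking and HPO matching are out of scope.
* No competing-risks (Fine–Gray) estimand; non-SUID death is treated as
  independent censoring.
* The generator's correlation model (shared latent uniform per group) is
  comonotone, not a general correlation structure.
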