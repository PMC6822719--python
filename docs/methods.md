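# Methods

## The experimental design being modelled

One Petri plate holds 10 seeds of each of two plant species and is exposed
to one fungal strain (or left uninoculated as a control) under one
temperature regime (summer or winter). Five replicate plates per strain ×
regime; 18 strains plus control gives 190 plates and 380 species-level
records. After incubation each seed is scored germinated, dead, or
dormant — a trinomial fate per seed, so each record is a vector of three
counts summing to the plate's seed number.

Three responses are analysed as per-plate fractions: germination,
mortality, and (summer only) seed-bank loss = germination + mortality.
Loss is summer-specific because summer germination of winter annuals is
lethal and therefore, like mortality, removes the seed from the seed
bank; winter germination does not.

## Effect sizes

All effects live on the raw fraction scale (differences of means of
per-plate fractions), deliberately untransformed so magnitudes read
directly as "additional fraction of seeds". Sign conventions are explicit
rather than positional in output tables: vs-control effects are
inoculated − control; host specificity is first-species − second-species,
and the species pair is printed in the row (`BRTO-PLOV`). Fractions are
averaged per plate and then across plates, not pooled as counts; with a
balanced seed count per plate the two coincide, but the per-plate
definition is the one the bootstrap resamples.

## Paired-plate bootstrap

Each of the `n_reps` (default 10,000) replicates resamples, with
replacement and preserving group size, the replicate plates of the
inoculated cell and — independently — those of the control cell, then
recomputes the effect. For host-specificity effects the resampling unit
is the whole plate: one index draw is shared by both species within each
group, so the within-plate correlation between species survives
resampling intact. This mirrors how the experiment itself sampled
variation: plates, not species-responses, are the independent units.

Numerical choices:

- **Quantile rule.** "Equal-tailed 95 % CI" is implemented as the 2.5 %
  and 97.5 % empirical quantiles with linear interpolation between order
  statistics (numpy's default). Any fixed rule is defensible at
  n_reps = 10,000; stating it makes results reproducible across
  implementations.
- **Bias** is the mean of the replicate statistics minus the observed
  statistic, reported alongside every interval.
- **Randomness.** One integer seed per call; the pipeline derives one
  child seed per output row from a single run seed via
  `numpy.random.SeedSequence`, in a fixed row order, so a run is
  byte-reproducible. No global RNG state anywhere.
- **Control resampling** is independent per contrast (each strain's
  bootstrap draws its own control resamples) — the simplest reading of a
  per-contrast resampling scheme. A shared-control variant would induce
  dependence between strains' intervals but identical marginal intervals.
- The bootstrap operates on untransformed fractions; the logit transform
  belongs only to the significance-test track.
- **Exact oracle.** `exhaustive_bootstrap` enumerates all joint
  with-replacement resamples (n^n per group) for small designs, giving
  the exact bootstrap distribution; Monte-Carlo CIs and bias are
  validated against it in the tests.

Percentile intervals at n = 5 plates per group under-cover (a known
property, not a defect); the calibration suite asserts nominal-band
coverage at 50 plates per group and treats the n = 5 behaviour as
documented.

## Significance tests

Per-plate fractions f are transformed as ln((f + c)/(1 − f + c)). The
smoothing constant c keeps 0 and 1 finite; the `auto` rule sets c to the
smallest non-zero per-plate fraction of that response in the dataset,
which is 0.1 whenever plates hold 10 seeds and some plate shows a single
positive count. The transform is odd about f = ½ and strictly increasing.

**t-tests.** Each inoculated cell vs its control cell, pooled-variance
(Student) form, df = n₁ + n₂ − 2, two-sided. Pooled rather than Welch
because the design is balanced with equal group sizes and the output
schema carries a single SE; cells whose transformed values show no
within-cell spread are flagged `degenerate` (p = 1 when means agree, p = 0
otherwise) instead of emitting infinities silently.

**Split-plot ANOVA.** Strain varies between plates (whole plot), species
within plates (sub plot), the plate is the random whole-plot unit. For S
strains and R replicate plates the balanced decomposition is

| source          | df       | tested against    |
|-----------------|----------|-------------------|
| strain          | S − 1    | plate(strain) MS  |
| plate(strain)   | S(R − 1) | —                 |
| species         | 1        | residual MS       |
| strain × species| S − 1    | residual MS       |
| residual        | S(R − 1) | —                 |

Degrees of freedom sum to 2SR − 1 (asserted on every run) and the five
sums of squares close the total SS. Control plates are excluded: the
factor under test is the identity of the inoculated strain, and S = 18
strains yields the interaction df (17, 72). Unbalanced layouts are
rejected with an explicit error — the closed-form decomposition is exact
only for balanced data, and general REML mixed models are out of scope.
A constant response yields all-zero SS and F reported as missing with a
`degenerate` flag. No multiple-testing correction is applied anywhere;
consumers receive raw p-values.

The winter mortality ANOVA is computed but flagged `low-signal` in the
report rather than omitted: skipping it would be a data-driven choice,
not a structural one, and flagging keeps the output schema stable.

## Synthetic-data generator

The generator emulates the design's dependence structure, not any real
strain's biology. Each cell (group × species × regime) has base rates
(p_germ, p_dead); each plate draws one b ~ N(0, σ_plate²) shared by both
species, and fate probabilities are the multinomial logit with the
dormant class as reference and b added to both non-reference logits
(weights p_germ·e^b, p_dead·e^b, p_dorm, renormalised). This keeps the
probability simplex valid for every b and makes the two species'
responses on a plate positively correlated — exactly the dependence the
paired bootstrap must respect. Generation is a pure function of the
config; identical configs (seed included) give bit-identical datasets.

- **σ_plate defaults to 0.5** on the log-odds scale. No empirical
  plate-variance estimate exists for this assay type; 0.5 produces
  visible but not dominant plate-to-plate correlation and is flagged as a
  convention.
- `standard_design_config` fixes a full 18-strain community with
  documented cell rates: low winter control germination (0.02 / 0.16 for
  the two species, matching the low baselines typical of freshly dormant
  winter-annual seed lots), several strains with strong host-specific
  summer loss in either direction, broad-spectrum mortality strains, and
  many near-null strains.
- **Marginal calibration.** With a plate effect the marginal expected
  fraction E[expit(logit(p) + b)] differs from the base rate p.
  `calibrate_marginal_germination` inverts that map by Gauss–Hermite
  quadrature so simulation studies can state effects on the marginal
  fraction scale — the estimand a difference of cell means actually
  targets.

What the generator does **not** emulate: temperature kinetics (regime
labels are metadata only), between-season dormancy carry-over,
overdispersion beyond the single shared plate effect, and any real
taxonomic signal in the strain labels. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
dependence structure, not the behaviour of any real fungal community.

## Calibration studies and problem sizes

The test suite and `scripts/acceptance.py` run three simulation studies,
sized to finish in seconds while leaving Monte-Carlo error well inside
the asserted bands:

- **Recovery**: a true marginal germination difference of 0.3
  (σ_plate = 0.5, 5 plates per group), 1,000 experiments; the mean
  estimated effect must lie within ±0.02 of 0.3.
- **Test size**: 2,000 null experiments of the full 18-strain design
  (equal cell rates, σ_plate = 0.5); the interaction test must reject at
  the 5 % level in 3–7 % of them.
- **Coverage**: 1,000 null experiments with 50 plates per group
  (σ_plate = 0); the 95 % percentile CI must cover zero 93–97 % of the
  time. Each interval uses 2,000 bootstrap replicates — coverage is
  insensitive to the replicate count at this scale, and the study repeats
  the interval a thousand times.

## Known limitations

- Only balanced designs are accepted by the ANOVA; there is no
  REML/likelihood path for unbalanced data.
- Percentile CIs only — no BCa or studentized intervals.
- Exactly two species per plate are supported; the pairing invariant and
  the host-specificity contrast are defined for a species pair.
- The generator's single shared plate effect cannot represent
  species-specific plate effects or strain-by-plate interactions.
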