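# Methods

## Population model

### State and update order

The population is a vector of counts: eggs, larvae and pupae indexed by
age-within-stage and (genotype, sex) class; adult males by genotype;
adult females by (own genotype, mate genotype), because a female mates
once on emergence and uses that male's sperm for life. One call to
`step` advances one day, in this order:

1. **Oviposition.** Each mated-female class lays `beta` eggs per female
   (Poisson in stochastic mode), scaled by the cross's viable-egg
   fraction and split over offspring classes by the inheritance cube.
   Start-of-day female counts are used, so a female lays before that
   day's mortality is applied; newly mated females therefore first lay
   the day after they emerge.
2. **Adult mortality.** Survival probability `1 − omega·mu_adult`
   (clamped at 0), with `omega` the genotype's hazard multiplier.
3. **Juvenile mortality and promotion.** All juvenile stages share the
   daily density-independent mortality `mu_aqua`; larvae additionally
   survive with probability `(alpha/(alpha+L))^(1/T_L)` where `L` is
   the total larval count across all genotypes *including doomed
   classes* — the resource-competition mechanism that makes egg
   releases effective. Final-age eggs hatch, final-age larvae pupate,
   final-age pupae emerge; classes flagged to die at `larva_exit` or
   `pupa_exit` are removed at the corresponding promotion, after a full
   life of resource consumption.
4. **Mating.** Newly emerged females choose a mate genotype with
   probability `c_m·M_m / Σ_k c_k·M_k` (males present after that day's
   mortality, including same-day emergers and same-day releases).
   If no males are present the females wait in an unmated pool and
   retry daily — necessary for near-elimination endgames.

The oviposition-before-mortality order was chosen because it makes the
calibration identity below hold exactly; the alternative (mortality
first) merely rescales `alpha` and changes nothing qualitative.

Stochastic mode uses one seeded `numpy` generator per realization
(binomial survival, Poisson egg totals, multinomial offspring and mate
choice) on integer counts; ensemble realization `i` of base seed `s`
uses `SeedSequence([s, i])`, so different intervention systems can be
compared on common random numbers.

### Calibration

Given `beta`, `mu_adult`, stage durations and the per-generation
density-free growth rate `Rm`, the juvenile mortality solves

    (beta / (2·mu_adult)) · (1 − mu_aqua)^(T_E+T_L+T_P) = Rm,

i.e. lifetime female egg output times density-free juvenile survival
equals `Rm` daughters per female. The larval scale `alpha` then has the
closed form `alpha = L_eq / (Rm − 1)` where `L_eq` is the stationary
larval census implied by the target female count: at equilibrium the
daily density factor must equal `Rm^(−1/T_L)`. With this, the returned
state is an exact fixed point of the deterministic `step` — the
one-year drift in the tests is ~1e-15, pure float error.

### Defaults

All defaults live in `sitsim/data/defaults.yaml`:

| parameter | default | why |
|---|---|---|
| beta | 20 eggs/female/day | standard temperate-climate *Ae. aegypti* fecundity |
| mu_adult | 0.123/day | ~8-day mean adult lifespan |
| T_E, T_L, T_P | 5, 6, 4 days | typical aquatic-stage durations |
| Rm | 8.2 per generation | from the daily growth rate ~1.096 used for *Ae. aegypti* in mosquito-control modeling, compounded over a ~23-day mean generation (15 juvenile days + 1/mu_adult) |
| N_F_eq | 10,000 females | full-scale experiment size; desk-scale work uses `scaled(0.1)` |
| release ratios | 200 eggs or 10 adult males per wild adult | field-trial-derived release intensities |
| c (pgSIT/RIDL+fsRIDL/IIT) | 0.78 / 0.05 / 1.0 | assay-measured, field-trial-derived, unimpaired |
| omega (IIT) | 2 | halved mean lifespan under geometric survival ≈ doubled daily hazard |

`Rm` matters: with `Rm` barely above 1 density dependence is negligible
(`alpha ≫ L_eq`) and egg releases lose their resource-competition
advantage, inverting the qualitative ranking of egg- versus
adult-release systems. A realistic multi-fold per-generation growth
rate is therefore the default; every value is overridable per scenario.

"Per wild adult" release sizing uses the pre-intervention equilibrium
adult census (males + females), fixed for the whole campaign;
`release_reference="females"` switches to females only. Released eggs
enter at age 1 split 1:1 by sex. Fitness multipliers are
genotype-linked, so wild-born fsRIDL carrier males inherit c = 0.05;
`released_only_fitness=True` treats the penalty as a rearing effect
instead (carriers get c = 1). Perfect sex-sorting of releases is
assumed (no accidental infected-female releases for IIT).

**Elimination** is declared when every individual, at any stage, of any
genotype that can still contribute to reproduction is gone: the wild
type plus any genotype with fertile, adulthood-reaching males (fsRIDL
carriers). "Fertile" means capable of siring offspring that reach
adulthood, so RIDL released males — all of whose progeny die at pupal
exit — do not block elimination, and pgSIT/IIT sterile males never do.

### Experiment sizes

Ensemble experiments default to desk scale — 0.1× population (1,000
females) and 100 realizations for the five-system comparison, 250
females and ~20 realizations for the elimination sweep — chosen as the
smallest sizes at which the qualitative comparisons are stable. The
full-scale configuration (10,000 females, 2,000 realizations) is a
constructible flag on the same code path.

## Fried competitiveness index

One mating per refractory female implies the mixed-cage hatch rate is a
mixture `h_mix = h0·P(wild mate) + h_sterile·P(test mate)` with
`P(test mate) = c·n_test/(n_wt + c·n_test)`; `fried_index` inverts
this. Estimator choices, fixed deliberately: hatch rates are pooled as
total hatched / total laid within each stratum (not a mean of
per-cage ratios); the default baseline is the two-wild-male control,
which keeps total male density equal between strata (the one-wild-male
control is selectable and gives a different answer — documented, never
averaged); the bootstrap resamples cages within strata and reports a
percentile interval, clamped at 0. With only five cages per stratum the
percentile interval is anticonservative — measured coverage is ~85% at
a nominal 95% — a known small-cluster bootstrap limitation worth
remembering when reading five-replicate assays.

## Turnbull NPMLE

Records are (last seen alive, first seen dead] intervals; `left ==
right` encodes an exact death, `right = inf` right-censoring. Mass can
only lie on maximal intersections, found by the endpoint-scan (a left
endpoint immediately followed by a right endpoint, with open/closed
order resolved by sorting an open left endpoint just after its value).
The EM self-consistency iteration starts uniform and stops when the
largest mass change is below `tol` (default 1e-8); the log-likelihood
is asserted non-decreasing each iteration, and non-convergence raises
rather than returning a partial fit. On exact + right-censored data the
NPMLE coincides with the Kaplan–Meier estimator; the tests verify this
pointwise to 1e-8 against an independent implementation.

Within a Turnbull interval the survival function is not identified:
`survival_band` reports the upper/lower step functions, while point
summaries use the midpoint-imputation convention (interval mass drops
at the interval midpoint). The median is the smallest drop time with
survival ≤ 0.5, bootstrapped over records (default 10,000 resamples)
for SD and percentile CI; resamples whose curve never reaches 0.5 are
dropped and counted. On a 3-day inspection grid the median estimate is
quantized to half-grid points, so single-study recovery of a median-30
exponential scatters over {28.5, 31.5} and occasionally one interval
further out.

The two-group comparison replaces a generalized log-rank test with a
permutation test on the integrated absolute difference of the two
NPMLE curves over the pooled finite observation window: exactly
specified, distribution-free, and directionally comparable. A
Bonferroni helper covers simple post-hoc families.

## Synthetic data

The assay generator reproduces the cage design (per-female mate draw,
Poisson eggs at 20/female so cages lay ~200 eggs, binomial hatch);
optional beta-binomial overdispersion is off by default since the
minimal stated model is binomial, though real replicate SDs suggest
extra-binomial variance. The survival generator draws exponential or
Weibull lifetimes, grids them to inspection intervals, and censors at
study end. What these generators do *not* emulate: male exhaustion or
courtship dynamics across a 12-hour mating window, female remating
beyond the refractory assumption, vial-level husbandry effects, or
seasonality/migration in the field population — so green tests show
estimator correctness under the stated sampling models, not robustness
to those violations.

## Known limitations

- Single randomly mixing population; no space, migration, seasonality,
  temperature dependence or egg diapause.
- No resistance evolution or multi-locus genetics; cubes are
  single-intervention.
- The mean-field deterministic mode differs from the stochastic mean by
  O(1/N) Jensen terms through the larval density factor (measured ≈ 1–2
  females at N = 500, within Monte-Carlo noise of 200 realizations).
- Under the shipped IIT parameterization (fully competitive released
  males at 10:1 with doubled hazard) IIT is a strong suppressor,
  ranking between pgSIT and RIDL; rankings among the adult-release
  systems are sensitive to the released males' competitiveness and
  longevity assumptions.
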