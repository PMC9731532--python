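# Methods

## Model and assumptions

The package implements the standard dietary-exposure chain for a genotoxic
carcinogen, specialised to benzo[a]pyrene (BaP).

**Exposure.** Per person, `EDI = Σ_food C_food · IR_food · 1000 / BW` in
ng kg⁻¹ day⁻¹, where `C_food` is a representative concentration for the food
category in µg/kg and `IR_food` the person's mean daily consumption in kg/day
derived from a 7-day bookkeeping diary (total mass divided by the full 7-day
window, so blank days count as zero consumption). Which statistic of the
category's concentration distribution multiplies the diary intake is genuinely
underdetermined in this kind of study design; the package defaults to the
**category mean** and exposes `--conc-stat median|p95` for upper-bound
scenarios. This is the largest single reproduction ambiguity and it is a
config knob, not a hidden choice.

**Margin of exposure.** `MOE_T25 = T25/EDI` and `MOE_BMDL10 = BMDL10/EDI`
with T25 = 2.4×10⁶ and BMDL10 = 7×10⁵ ng kg⁻¹ day⁻¹ by default, EFSA
low-concern cutoff 10⁴ (boundary inclusive: MOE = 10⁴ is low concern). A
person with EDI = 0 has no defined MOE; the code returns an explicit
undefined marker, excludes it from MOE summaries and reports the count —
never an infinity. Because the two MOEs are proportional, every person's
`MOE_T25/MOE_BMDL10` equals `T25/BMDL10` exactly; published subgroup tables of
this design show a ratio near 34.3, consistent with BMDL10 = 7×10⁴ rather
than the stated 7×10⁵. We do not silently resolve this: the default follows
the stated 7×10⁵, and `TABLE1_APPARENT_REFERENCE_POINTS` (or `--bmdl10 7e4`)
is the documented alternative.

**Lifetime risk.** `ILCR = (C·IR·EF·ED·CSF)/(BW·AT)`. Expressed through EDI
the body weight cancels: `ILCR = EDI·10⁻⁶·EF·ED·CSF/AT` with EF = 365
day yr⁻¹, ED = 43 yr, CSF = 7.3 kg day mg⁻¹, AT = 25,550 day. The default
probabilistic model draws EDI and ED independently (`mode="edi"`); ED is
lognormal with mean 43 yr and CV 0.1 — the source model states ED is
lognormal but gives no spread, so the CV is a documented knob (at CV 0.1 the
mean ILCR is insensitive to it: E[ILCR] depends on ED only through E[ED]).
An optional `mode="independent"` samples BW as well, anchoring the mg/day
intake at the nominal BW while the denominator BW varies, for sensitivity
analysis of the literal formula.

**Sampling engines.** Monte Carlo uses fresh uniforms per dimension;
Latin hypercube splits each dimension into `n_iter` equal-probability strata,
draws one uniform inside each stratum, and pairs strata across dimensions by
independent random permutations before the inverse-CDF transform, so each
marginal is exactly stratified. Both engines accept a lognormal spec, a point
mass, or an empirical per-person EDI sample (inverse empirical CDF with
linear interpolation). One root seed yields deterministic per-engine child
streams (`SeedSequence([seed, engine_index])`); fixed seed ⇒ bit-identical
output. For the mean of the (monotone) risk function, LHS estimator variance
is at most the MC variance, which the test suite verifies over 100 replicate
seeds.

**Classification.** ILCR < 10⁻⁶ acceptable, > 10⁻⁴ serious, otherwise
moderate; both boundaries strict (a value exactly on a threshold is
"between" them, hence moderate). Published low/medium/high proportions from
this study design are not reproducible from a 10⁻⁶ cutoff when the mean risk
is ≈3×10⁻⁵ (a lognormal centred there puts ≪1% below 10⁻⁶); the thresholds
here are configurable and the package reports what it computes rather than
reverse-engineering an undocumented cutoff.

**Lognormal calibration.** `fit_lognormal_from_summary(mean, median)` inverts
`median = exp(µ)`, `mean = exp(µ + σ²/2)`:
`µ = ln median`, `σ = √(2·ln(mean/median))`. For the whole-cohort pair
(7.10, 5.20) this gives µ = 1.6487, σ = 0.78922, and a fitted P95 of
5.20·exp(1.6449·σ) = 19.05 — about 8% below the published P95 of 20.63,
i.e. the real exposure distribution is heavier-tailed than a two-parameter
lognormal. The calibration result reports this fitted P95 as a diagnostic; a
three-parameter family would be an extension, deliberately not the default.

## Statistical conventions

* Median: middle order statistic; mean of the two middles for even n.
* P95: linearly interpolated empirical quantile at rank `1 + (n−1)·0.95`
  (numpy `method="linear"`), chosen so results are bit-stable and testable.
* Standard deviation of concentration summaries: sample sd (n−1); one
  observation reports sd 0 with a warning.
* Exceedance of a national limit: strict inequality against the limit carried
  on each record (limits differ by food class; GB 2762-2017 uses 5.0 µg/kg
  for grain/meat/aquatic products and 10.0 µg/kg for oils).
* Group comparison: Welch unequal-variance two-sample t-test, two-sided,
  α = 0.05 — the safe default for the unequal sizes/variances of
  literature-compiled groups.
* Percentages in demographic tables: half-up rounding to 2 decimals.

## Synthetic-data generator

The generator emulates the study conditions so that every stage runs with no
download:

* **Concentration DB** — 17 food categories, lognormal concentrations, 60
  records/category by default. Category means for olive oil (12.755 µg/kg),
  fried meat products (7.76), rice (0.53) and wheat products (0.94) match the
  published averages; the other 13 categories are realistic inventions. The
  log-sd values (0.55–0.80) produce the strong right skew and the olive-oil
  dominance seen in such data; draws are not truncated above, so a large
  sample's maximum can exceed the published 43 µg/kg range.
* **Cohort** — 637 participants. Region (222/415), sex (185/452) and
  education (99/399/139) margins are assigned exactly and independently
  shuffled, so demographic percentages (34.85/65.15, 29.04/70.96,
  15.54/62.64/21.82) reproduce deterministically while the joint
  cross-classification is random. Weight/height/age are truncated normals
  centred on the printed means and ranges (63.46 kg in 38–90; 158.5 cm in
  148–195; 19.4 yr in 15–33). The printed height mean is treated as a soft
  target only.
* **Diaries** — for each person, category and day, consumption is Bernoulli
  with the category's base daily probability; portion masses are lognormal.
  "Discretionary" high-BaP foods are additionally scaled by subgroup
  multipliers (core 1.20 vs peripheral 0.95; female 1.08 vs male 0.90;
  postgraduate 1.18 / bachelor 1.00 / junior college 0.82) and by a
  person-level lognormal propensity (log-sd 1.05, mean 1) split between
  frequency and portion size (√λ each) so the probability cap does not
  truncate the upper tail. This consumption model is the package's own
  construction — no per-food intake distributions are published — and its
  defaults were chosen with `scripts/tune_generator.py` so the default
  cohort's All-group EDI lands near the published summary: achieved
  mean/median/P95 ≈ 7.1/5.0/19.4 (seed 0) and 7.6/5.3/20.1 (seed 1) against
  7.10/5.20/20.63, with the published subgroup ordering (core > peripheral,
  female > male, postgraduate highest) emerging from the multipliers.

What passing tests on synthetic data do **not** show: agreement of per-food
intake patterns with any real diary data; the heavier-than-lognormal exposure
tail noted above; correlations between demographics and body weight; seasonal
or weekday/weekend diary structure (days are exchangeable). Conclusions about
real cohorts require real diaries.

## Numerical and design choices

* Concentrations stay in µg/kg everywhere below the exposure layer; a single
  named constant (1000) converts to ng in the EDI, and the ng→mg factor
  (10⁻⁶) lives in the risk module — every printed quantity stays in its
  conventional unit.
* Degenerate inputs: identical samples compare as t = 0, p = 1; two constant
  unequal samples as p = 0; a degenerate lognormal (σ = 0) is a point mass
  and both engines then reproduce the point formula exactly.
* Rows with non-numeric or negative concentrations are rejected (counted and
  warned), not fatal; missing required columns are fatal and name the column.
* A diary category with positive intake but no concentration entry is an
  error by default (`missing_category="skip"` downgrades it to a warning),
  because silently dropping intake biases exposure downward.
* Problem sizes: probabilistic runs default to 10⁴ iterations; the
  variance-comparison test uses 100 replicate seeds at 256 iterations, and
  calibration-recovery checks use 10⁵ draws — sizes at which the checked
  tolerances (mean within 3 SE, µ within 0.02, σ within 0.05) are
  comfortably resolved.

## Known limitations

* The representative-concentration choice (mean/median/P95) changes EDI by a
  factor comparable to the concentration skew; there is no data-driven way to
  pick it from published summaries alone.
* LHS stratification helps means and quantiles of monotone functionals; it
  does not certify tail probabilities beyond its marginal guarantee.
* The BMDL10 and risk-proportion inconsistencies described above are surfaced
  as configuration, not resolved.
* `compute_ilcr_point` requires a fixed ED; probabilistic ED belongs to the
  sampling engines.
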