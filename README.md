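# baprisk

Dietary exposure and cancer-risk assessment for benzo[a]pyrene (BaP), the
Group-1 polycyclic aromatic hydrocarbon formed when food is fried, grilled or
smoked. The package is aimed at food-safety and exposure-assessment
practitioners who have (a) a literature-compiled table of BaP concentrations in
foods and (b) a cohort with 7-day bookkeeping food diaries, and want the
standard chain of risk metrics:

* **EDI** — exposure daily intake, `EDI = Σ_food C·IR / BW` (ng kg⁻¹ day⁻¹),
  with `C` the food's BaP concentration (µg/kg), `IR` the person's mean daily
  consumption (kg/day) and `BW` body weight (kg);
* **MOE** — margins of exposure against two animal reference points,
  `MOE_T25 = T25/EDI` (T25 = 2.4×10⁶ ng kg⁻¹ day⁻¹) and
  `MOE_BMDL10 = BMDL10/EDI` (BMDL10 = 7×10⁵ by default), judged against the
  EFSA low-concern benchmark of 10⁴;
* **ILCR** — incremental lifetime cancer risk,
  `ILCR = EDI·10⁻⁶·EF·ED·CSF/AT` (EF = 365 day yr⁻¹, ED = 43 yr, CSF = 7.3
  kg day mg⁻¹, AT = 25,550 day), sampled probabilistically by Monte Carlo or
  Latin hypercube sampling and classified against the USEPA 10⁻⁶/10⁻⁴
  acceptable/serious thresholds.

A synthetic-data module generates concentration databases, cohorts and diaries
with the statistical structure of a 637-person college-student survey (17 food
categories, lognormal concentrations, exact demographic margins), so the whole
pipeline runs and is testable without any external download. A lognormal
calibration utility (`fit_lognormal_from_summary`) turns a published
mean/median exposure pair back into a sampling distribution.

## Worked example

```bash
baprisk simulate --seed 7 --out sim
baprisk assess --db sim/concentrations.csv --cohort sim/cohort.csv \
               --diary sim/diary.csv --n-iter 2000 --seed 7 --out assess
baprisk report --run-dir assess
```

prints (abridged):

```
Cohort: n=637 (seed=7)
  region: Core district 222 (34.85%), Peripheral areas 415 (65.15%)
  sex: Male 185 (29.04%), Female 452 (70.96%)
  education: Junior college 99 (15.54%), Bachelor 399 (62.64%), Postgraduate 139 (21.82%)

MC (n_iter=2000, seed=7): mean ILCR 2.632e-05, median 2.053e-05, P95 6.059e-05; acceptable/moderate/serious = 0.00/98.90/1.10 %
LHS (n_iter=2000, seed=7): mean ILCR 2.648e-05, median 2.052e-05, P95 6.414e-05; acceptable/moderate/serious = 0.00/98.90/1.10 %
```

Read: the simulated cohort reproduces the survey's demographic margins
exactly; the mean incremental lifetime cancer risk is ≈3×10⁻⁵ — between the
acceptable (10⁻⁶) and serious (10⁻⁴) thresholds, so most of the cohort sits in
the moderate-risk band, with a small high-risk tail. The two sampling engines
agree within Monte-Carlo error, and `assess/exposure_table.csv` holds the
subgroup EDI/MOE table (mean, median, P95 per region/sex/education group).

The same steps are available as library calls (`generate_cohort`,
`diary_to_intake`, `compute_exposure_results`, `run_monte_carlo`, `run_lhs`,
…); see `docs/methods.md` for the model details and every default.

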