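# Methods

This note documents the models and procedures ncakit implements, the
defaults and why they were chosen, what the synthetic data emulate (and do
not), and the numerical choices a careful user should know about.

## Data model and units

A profile is the *mean* concentration–time course of one analyte in one
matrix for one study arm. Serial-sacrifice (destructive-sampling) designs
yield one mean per nominal time (n animals per time point), not
per-subject curves, so all NCA here is naive-pooled mean-profile NCA; no
between-animal variance is propagated into the parameters.

Units are fixed by matrix — ng/mL for plasma, ng/g for solid tissues —
and times are canonicalized to hours on read (minute-valued rows are
converted). Molar conversion divides by the molar mass (474.6 g/mol for
metarrestin): ng/mL = µg/L, so C/MW is µmol/L directly; solid tissues are
converted assuming a density of 1 g/mL, which reproduces the conventional
6.2 µg/g ≈ 13 µM equivalence.

**BLQ handling.** Concentrations below the matrix LLOQ (validated at
1.0 ng/mL in plasma and 5.0 ng/g in liver homogenate; the liver value is
applied to other solid tissues assayed the same way) carry a flag and no
number. Source reports rarely state how BLQ values entered the NCA, so a
policy is explicit here. Default: BLQ at or before Tmax → 0 (true value
is between 0 and LLOQ; zero is the least-biased choice during
absorption), BLQ after Tmax → dropped (a zero would wreck the log-linear
terminal fit). `drop_all` and `zero_all` are available. Censoring is
idempotent and a profile with nothing quantifiable left is an error, not
an empty result.

## The NCA engine

- **AUC** uses the linear trapezoidal rule, matching how the reference
  values were computed. For an exponential decay sampled at step h the
  trapezoid overestimates with relative error ≤ (h²/12)λ²; this bound is
  verified in the tests and is the dominant error source on sparse grids
  (see "Limitations").
- **Partial AUCs** (0–24, 0–48 h) interpolate linearly at interval
  boundaries; intervals extending beyond the sampled range are refused
  rather than extrapolated.
- **λz** comes from OLS on (t, ln C). Window selection follows the
  "best fit" convention: every suffix window of ≥3 positive-concentration
  terminal points is fitted (the Cmax point itself is excluded for
  extravascular routes, where it still carries absorption; it is eligible
  for IV bolus), the window with the largest adjusted
  R² = 1 − (1 − R²)(n−1)/(n−2) wins, and windows within 10⁻⁴ of the best
  are treated as ties resolved toward more points. A manual window can be
  supplied instead. Windows with nonpositive slope are unacceptable; if
  none qualifies, λz is flagged not-calculated ("NC") and everything
  downstream of it (t½, AUC₀₋∞, CL, Vdss) is flagged too — the analysis
  returns partial results rather than failing.
- **t½ = 0.693/λz**, with the rounded constant 0.693 rather than ln 2,
  matching the convention under which the reference half-lives were
  derived; the difference is <0.03%.
- **AUC₀₋∞ = AUC₀₋t + C_last/λz**; the extrapolated fraction is always
  reported and logged.
- **C(0)**: single-dose IV bolus profiles missing a t=0 sample are
  anchored by log-linear back-extrapolation through the first two positive
  concentrations (falling back to the first value if the profile starts
  flat or rising); single-dose extravascular profiles are anchored at
  C(0)=0. Multiple-dose profiles are expected to include their own
  pre-dose sample.
- **CLp = dose/AUC₀₋∞** for IV (mg/kg and ng·h/mL give mL/h/kg; /60 →
  mL/min/kg). **Vdss = CLp·MRT** with MRT = AUMC₀₋∞/AUC₀₋∞ and the
  standard tail corrections C_last/λ and C_last(t_last/λ + 1/λ²); no
  formula is universal in reports, so the standard moment definition is
  used.
- **Bioavailability** is the dose-normalized PO/IV AUC₀₋∞ ratio. It may
  exceed 1 when absorption or clearance is dose-dependent; such values
  are reported as-is with an `exceeds_unity` flag, never clipped.
- **Chow (quasi-continuous) arms** are treated as a 24 h steady-state
  observation window: AUC₀₋₂₄ₕ and Cmean = AUC₀₋₂₄ₕ/24 only, λz/t½
  deliberately not attempted (flagged "NA") because continuous intake
  leaves no terminal phase.
- **Report rendering**: partitioning ratios to the nearest integer,
  accumulation ratios to one decimal, bioavailability to two decimals,
  other parameters to three significant figures; "NA" = not applicable to
  the route/design, "NC" = not calculable from the data. These mirror how
  such tables are conventionally printed and are what the string-level
  checks in the test suite assert against.

A note on one published value: the chow-arm plasma Cmean is sometimes
quoted as 0.2 µM, but the stated formula applied to the reported
AUC₀₋₂₄ₕ of 4160 ng·h/mL gives 173.3 ng/mL ≈ 0.37 µM. ncakit computes
Cmean by the formula and reports 173.3 ng/mL; the discrepancy in the
quoted molar value cannot be resolved from the published numbers.

## The synthetic-data generator

The generator exists so every estimator can be exercised against known
ground truth without raw study data. It is exact, not numerical: the
unit-dose plasma response of the disposition model is kept as a sum of
exponentials, and bolus trains and zero-order infusions are superposed
analytically.

- **Disposition**: one- or two-compartment linear kinetics. The package
  default is two-compartment with CL 48 mL/min/kg, Vss 17 L/kg, central
  volume 5 L/kg, and intercompartmental flow solved so the terminal
  half-life is 8.5 h — the parameters observed in the tumor-bearing
  cohort, which is the richest dataset (four matrices, single and
  multiple dose, 48 h sampling). A variant with the 5 h terminal
  half-life seen in wild-type mice at low dose is provided
  (`wildtype_disposition`).
- **Absorption**: first-order, with ka calibrated by root-finding so the
  continuous-time plasma Tmax hits a target (2 h for the low-dose
  wild-type arms, 6 h for the 25 mg/kg tumor-cohort arm, reflecting the
  slower absorption observed at high dose). Coincident rate constants
  (ka → k) are handled by an infinitesimal rate separation equivalent to
  the analytic limit.
- **Dose-dependent exposure** (AUC rising faster than dose, apparent
  F > 1 at high dose) is *not* modeled mechanistically — linear kinetics
  cannot — but emulated per arm by re-parameterizing apparent clearance
  so each preset reproduces its arm's reported AUC with F fixed at 0.84.
- **Tissues**: instantaneous partitioning C_tissue = Kp·C_plasma with
  Kp 19/33/44 for tumor/spleen/liver (the single-dose tissue/plasma AUC
  ratios); an optional first-order equilibration rate k_tp produces the
  delayed tissue peak seen for deep compartments. The in vivo
  tumor-specific accumulation under repeated dosing (MD:SD ≈ 5 in tumor
  vs ≈ 2 elsewhere, plausibly target-mediated retention) is outside the
  linear model: under it the accumulation ratio is the same ~1.2 in
  every matrix. Tests and demonstrations that concern accumulation
  therefore run on the published summary values, not the simulator.
- **Chow dosing** defaults to 12 equal boluses per day (mouse nibbling;
  produces realistically flat steady-state profiles); a zero-order
  infusion mode is available.
- **Sampling**: at each nominal time, n_per_timepoint (default 3)
  animals are drawn log-normally with median equal to the model value and
  CV = 15% — a deliberate default combining the ≤5% bioanalytical QC
  variance with biological variability, since no inter-animal CV was
  reported — then averaged into the mean profile; means below the matrix
  LLOQ are recorded BLQ. Seeds are mandatory; there is no global random
  state, and a fixed seed gives byte-identical CSV output.

What passing the recovery tests shows — and does not. Over 200 simulated
IV studies at the default conditions and the sparse 7-point sacrifice
grid, median |relative error| of CL and AUC₀₋∞ is ~7–8%, within the 10%
the suite requires. That error is mostly a deterministic trapezoid bias
from the 7→24 h gap, not noise: with the shorter wild-type 5 h terminal
half-life the same grid gives ~14% bias, so recovery quality is a
property of design + kinetics, not of the estimator alone. Real studies
share exactly this structure; synthetic passing means the code does what
the method promises, not that the method is unbiased on any design. The
generator also does not emulate nonlinear (saturable) kinetics,
enterohepatic recirculation, or physiologic organ networks.

## PD computations

- **Marker selection** consumes signed fold changes (x-fold
  down-regulation encoded as −x, never 1/x; any magnitude <1 is rejected
  as ratio-encoded). The filter keeps a gene iff |fc_tm/tv| ≥ 3 and
  |fc_pm/pv| < 2 and fc_tm/tv·fc_pv/tv > 9 and p < 0.001 — inequality
  strictness exactly as stated, all thresholds configurable. The signed
  convention is what makes the product criterion meaningful: it is
  positive only when the tumor's treatment response points back toward
  the normal-pancreas baseline. The two phrasings of the normal-pancreas
  filter ("exclude ≥2-fold" and "|fc| < 2") are logically one criterion
  and implemented once. The p-value is treated as a per-record filter; no
  additional multiple-testing correction is applied beyond it. Upstream
  differential-expression estimation is out of scope — the module starts
  from a fold-change table.
- **PNC prevalence** is the per-sample fraction of tumor cells containing
  ≥1 perinucleolar compartment, averaged unweighted across samples;
  groups are compared by a two-sample two-tailed t test (equal-variance
  by default — small n and no evidence against it; Welch available). The
  degenerate case (both groups constant, equal means) returns p = 1.
- **Exposure–response** regresses reference-normalized expression on
  intratumor AUC₀₋₂₄ₕ across dosing cohorts (≥3 required) and reports
  slope, R² and the two-tailed significance of the correlation.

## Problem sizes and determinism

The test suite and the acceptance script are sized to run in seconds:
200 replicate studies for parameter recovery, 10,000 synthetic genes for
the marker-filter oracle, dense grids of ~6,000 points for the
closed-form convergence checks. All randomness flows through explicit
seeds (`numpy.random.default_rng`); hypothesis-based property tests run
derandomized.

## Known limitations

- Mean-profile NCA only; no per-animal variance, no sparse-sampling
  standard errors (Bailer-type), no bioequivalence statistics.
- No compartmental *fitting* of observed data — simulation only.
- Linear trapezoid only (no log-linear down-slope rule), because that is
  the rule the reference analysis used; expect the documented upward AUC
  bias on wide late intervals.
- The simulator's linear kinetics cannot reproduce dose-dependent
  half-life or tumor-specific accumulation except by per-arm
  re-parameterization, which is how the presets do it.
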