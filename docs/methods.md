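# Methods

## The problem

Neonicotinoid seed treatments coat maize kernels with a systemic insecticide
(clothianidin or thiamethoxam, 0.25–1.25 mg AI/kernel) on the premise that the
plant takes the compound up and carries it to the tissues early-season pests
attack. Whether that premise holds depends on three quantifiable things this
package computes: how fast tissue-bound residue dissipates (and hence how long
a "protection window" lasts), what fraction of the applied dose ever enters
the plant, and whether the protection that is delivered overlaps the pests'
activity periods and pays for itself economically.

## Dissipation model

Tissue concentration is modelled as first-order decay,

    C(t) = C0 · e^(−k·t),

with t in days post planting (DPP), C in µg AI per g fresh tissue, fit by
Levenberg–Marquardt nonlinear least squares (`scipy.optimize.curve_fit`,
`method="lm"`) on raw concentrations — no background subtraction, no log
transform at the fitting stage. Untreated series therefore fit poorly (R² near
0 or negative): they contain only ambient background, and that is the expected
and informative outcome, not a failure.

Deterministic initialization: C0 starts at the maximum observed concentration;
k at the negated slope of an ordinary log-linear regression on the positive
concentrations (floor 1e-6). An exactly-constant series short-circuits to
(C0 = the constant, k = 0, R² = 0 by convention); the standalone `r_squared`
raises on zero-variance input because the ratio is genuinely undefined there —
the fit-level convention exists so a flat series still yields a usable record.

Fits are computed on date means across plots (one curve per year × treatment ×
region), the replicate-pooled view; plant-level fitting is available via
`decay_fit_table(..., per_plant=True)`.

Derived quantities:

* **DT50** = ln 2 / k.
* **Flattening day** t\* = −ln(f)/k: the day the instantaneous decay rate
  |dC/dt| has fallen to fraction f of its initial value. Default f = 0.05.
  This replaces a by-eye judgement of where a decay curve "levels off" with a
  closed form; with root-region rates around 0.15–0.2 day⁻¹ it lands in the
  15–25 DPP range. k ≤ 0 yields `inf` ("never flattens").

## Protection-window inference

Two estimators of the day protection ends, deliberately different in spirit:

1. **Decay flattening** (optimistic, curve-shape based): the flattening day of
   the fitted dissipation curve.
2. **Contrast convergence** (conservative, hypothesis-test based): at each
   sampling date, plant-level concentrations are averaged to plot means,
   natural-log transformed (after LOD substitution, so zeros cannot occur),
   and fit with a two-way fixed-effects model (treatment + block — the
   randomized-complete-block layout, error df (T−1)(B−1) = 9 for 4×4). Two
   planned contrasts are tested per date: untreated (naked + fungicide,
   weights +½, +½) vs the low rate (−1) and vs the high rate. Protection ends
   at the earliest sampled date from which the contrast p-value stays above α
   for every remaining date (one dip below α restarts the clock). No
   multiplicity correction is applied across dates: the contrasts are planned,
   not post hoc.

The ANOVA and contrast F statistics use the exact closed-form balanced
decomposition rather than a generic OLS fit; the test suite cross-checks them
against `statsmodels.anova_lm` on the same layouts. The contrast F is
L²/(MSE·Σw²ᵢ/nᵢ) on (1, df_error).

Per-year end days are reconciled across years by their arithmetic mean, with
the per-year components retained in the output. Trial-summary tables (yield,
stand, ratings) use the same RCB model with Tukey HSD compact-letter displays
(studentized-range quantile from `scipy.stats.studentized_range`; letters by
the interval-sweep algorithm, valid because the balanced design gives a single
HSD threshold).

## Translocation accounting

A region measuring `conc` µg/g across `mass` g of tissue has recovered
100·conc·mass/(1000·dose) percent of the kernel's dose. Subsampled homogenates
are handled by carrying the *total* region mass on the record. Regions
recovered >80% intact are "complete" (exactly 80% counts as incomplete);
plants with both root and shoot complete are "total samples", and only those
contribute whole-plant percentages (root + shoot; additivity is exact by
construction). The seed region's remaining fraction is reported separately —
residue still on the seed has not been translocated anywhere. Both per-plant
and per-date summaries are emitted (mean, max, n).

## Phenology

Degree-days per day come from either the simple average max(0, (Tmin+Tmax)/2 −
base) with an optional cap at cutoff − base, or single-sine interpolation
(Baskerville–Emin) with a horizontal upper cutoff, implemented as the
difference of two closed-form sine-above-threshold areas and verified against
numeric integration. Event dates are the first day the running sum reaches the
model threshold.

Pest activity presets (DPP axis, planting = 0): western corn rootworm onset
27 DPP (from direct larval scouting; nominal end 85 DPP), white grub end
41 DPP, wireworm end 56 DPP. The seedcorn maggot window is computed from the
degree-day model starting at adult emergence (default May 1); its base
temperature (3.9 °C) and threshold (360 DD) are *assumed defaults*, exposed in
`DegreeDayModel`, because the constants of the underlying published model are
configuration, not something this package can derive. Protection intervals
start at 0 DPP — the seed is protected from sowing. Overlap of [0, end] with
[start, end] gives covered days; the remainder is the pest activity left after
protection lapses.

## Economics

EIL = C/(V·b·K): control cost C ($/ha) over commodity value V ($/100 kg) times
yield loss per unit node-injury b (100 kg/ha per unit of the 0–3 scale) times
efficacy K ∈ (0, 1]. The product V·b is never hard-coded: it is calibrated
from the anchor (EIL 0.245 node-injury at C = $17.5/ha, V = $14.96/100 kg,
K = 1), giving V·b ≈ 71.43 $/ha per node-injury unit (b ≈ 4.775), and rescales
proportionally in V (e.g. to the 2012 value $28.46/100 kg). Because EIL is
linear in C, the calibration is insensitive to which season's yield
expectation stood behind the anchor. The inverse, C\* = rating·V·b·K, is the
break-even control cost for an observed rating; `compute_eil` and
`break_even_cost` are exact inverses.

K estimation from damage ratios is offered in two modes and the mode travels
with the number: `"ratio"` = treated/untreated (the arithmetic behind the
published 0.395-type estimates) and `"pedigo"` = 1 − treated/untreated (the
definitional "proportionate reduction in injury"). They sum to one; the
package surfaces the discrepancy rather than silently picking a side. Note
0.128/0.3245 = 0.3945, which the tests accept against 0.395 at ±0.001.

GUS = log10(DT50)·(4 − log10(Koc)); classes high (> 2.8), medium (1.8–2.8),
low (< 1.8).

## Synthetic trial generator

The generator reproduces the statistical structure the analysis assumes, with
ground truth retained for recovery tests:

* Expected concentration = background + dose·c0_per_dose_unit[region]·e^(−k·t).
* **Noise** is mean-one multiplicative lognormal (σ² = ln(1 + CV²)):
  concentrations are positive and right-skewed, which is also what justifies
  the log transform in the contrast models. Default CV 0.3 — an assumption
  (within-date measurement CV is not something the design pins down), chosen
  as typical of residue assays on field-collected seedlings.
* **Background** 0.01 µg/g, additive and treatment-independent: untreated
  plots in maize country are never neonicotinoid-free (lateral subsurface
  movement, carry-over), so "naked" seed still shows residue. This is the
  simplest model producing the poor untreated fits and the eventual
  convergence of treated and untreated concentrations.
* **Blocks** multiply concentrations by a shared mean-one lognormal factor
  (SD 0.1) per year × block; ratings/stand/yield get additive block effects.
* **Kinetics defaults**: k = 0.16 (root), 0.30 (seed), 0.12 (shoot) day⁻¹;
  C0 per mg/kernel = 65 (root), 120 (seed), 25 (shoot) µg/g. These place root
  flattening in the mid-to-high teens DPP and make the high rate separate from
  controls longer than the low rate — the qualitative regime the analysis is
  about. Region mass follows a logistic in t crossing 1 g in the mid-teens
  DPP; seed mass is constant ≈ 0.25 g. With these scales whole-plant
  recoveries peak below ≈ 1.6% of the dose; the split across tissues is not
  calibrated to any particular field dataset.
* **Design**: two years, schedules {6,8,10,13,15,17,20,34} and
  {5,7,9,12,14,16,19,47,61} DPP; 4 treatments (0, 0, 0.25, 1.25 mg/kernel) ×
  4 blocks × 5 plants per plot-date; seed region recoverable only to 20 DPP.
* **Ratings**: untreated mean 0.3245 on the 0–3 node-injury scale; insecticide
  treatments reduced by efficacy 0.6055 (treated mean 0.128); Gaussian plot
  noise (SD 0.15), clipped to [0, 3].
* Default seed 20170310.

What the generator does **not** emulate: weather-driven or bi-exponential
dissipation (k is constant per series), spatial plot layout and inter-plot
leaching dynamics, censoring mechanisms beyond the detection limit, missing
plots, and any correlation between residue levels and root damage. Passing
tests therefore demonstrate that the estimators recover the assumed structure
at realistic noise, not that real field data satisfy that structure.

## Numerical and design choices

* Below-LOD records (LOD 0.1 ng/g = 1e-4 µg/g) are substituted at LOD/2 by
  default (`zero` and `drop` available); substitution is idempotent and
  separate from flagging.
* The error df of every per-date model is derived from the data actually
  present, not assumed from the design.
* Balanced-only ANOVA: a missing cell raises an explicit unbalanced-design
  error rather than silently switching to approximate sums of squares.
* The parameter-recovery benchmark (200 series, 8 dates, 5 plants/date,
  CV 0.3) samples an even 0–21 DPP grid: recovering C0 requires observations
  near t = 0, and a benchmark should isolate estimator error from schedule
  artefacts (a 5-DPP first sample plus a 47-DPP gap adds ~4 points of
  median C0 extrapolation error on its own).
* Monte-Carlo problem sizes (2000 null replicates for the type-I check, 100
  replicates for the convergence-ordering check, 200 series for recovery) were
  chosen to put the binomial/median sampling error comfortably inside the
  asserted bands.
* `convergence_date` demands p > α at a date *and all later sampled dates*;
  raising α can therefore only delay the date or lose it, never advance it —
  the property tests assert exactly that direction.

## Known limitations

* Protection is defined by residue similarity to controls, not by any
  dose–mortality relationship; no LD50 layer exists here.
* The decay-flattening window depends on the choice of f; 0.05 is a
  convention, and the window moves as −ln(f)/k.
* The multivariate repeated-measures formulation of the per-date analyses is
  intentionally out of scope; per-date univariate models + planned contrasts
  are the implemented route.
* Censored observations are substituted, not modelled; a likelihood treatment
  of below-LOD data would be the principled upgrade if censoring were heavy.
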