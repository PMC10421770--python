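# Methods

## Structural model

The model tracks molar amounts (µmol of TFV-equivalents) in four
compartments — subcutaneous depot, TFV central, TFV peripheral, PBMC
TFV-DP:

    dA_depot/dt = in_sc(t) − ka·A_depot                      ka = 1/max(MAT, 1e-4 d)
    dA_c/dt     = F·ka·A_depot + in_iv(t)
                  − (Cl/V)·A_c − (Clp/V)·A_c + (Clp/Vp)·A_p − form(C)
    dA_p/dt     = (Clp/V)·A_c − (Clp/Vp)·A_p
    dA_dp/dt    = form(C) − Kout·A_dp                        C = A_c/V (µM)

with `form(C) = (Vm/Km)·C` in the default linear mode, or
`Vm·C/(Km + C)` with `Vm = (Vm/Km)·Km` when a Michaelis constant is
supplied. The topology is fixed by the parameter set the analysis uses
(depot mean absorption time, two-compartment TFV disposition, a single
TFV→TFV-DP formation clearance, first-order TFV-DP loss). Assumptions worth
stating explicitly:

* **TAF is treated as instantaneously hydrolyzed to TFV on absorption.**
  TAF's plasma half-life is minutes and the estimated mean absorption time
  is under a minute, so plasma TAF itself is not modeled; dosing in mg TAF
  is converted to µmol at the molecular weight of the free base
  (476.47 g/mol) and enters the TFV mass balance one-to-one.
* **Apparent bioavailability F applies at the depot→central transfer**, with
  IV dosing the reference (F ≡ 1; IV input enters the central compartment
  directly). F may exceed 1: under sustained subcutaneous delivery the
  metabolite exposure per unit dose is higher than under IV bolus dosing,
  and F absorbs that apparent gain. The elimination bookkeeping carries a
  `(1−F)·ka·A_depot` term so that administered = retained + eliminated holds
  identically, whatever F.
* **MAT is floored at 1e-4 d** (~8.6 s). Below that the depot adds nothing
  observable and only stiffens the system.
* **The PBMC compartment volume is not identifiable** and is fixed to
  1 L-equivalent internally; TFV-DP readouts in fmol/10⁶ cells follow from
  the fixed conversion 1.0 fmol/10⁶ cells = 5.0 × 10⁻³ µM (mean cell volume
  0.2 µL per 10⁶ PBMCs). The absolute numerical value of Vm/Km is therefore
  a convention tied to that scale; only ratios and fits on a consistent
  scale are meaningful. Published tables report this parameter on two
  different scales (an intrinsic-clearance scale, ~1e-4 L/d, and a
  formation-rate scale, ~1e-6 to 1e-3 L/d); the package exposes a single
  formation term and leaves the scale to the user.
* **Default mode is linear formation**; the saturable term exists but the
  reported dog analyses found the Michaelis–Menten contribution negligible.

Closed forms used as oracles: the terminal half-life is
`ln 2 / β` with `β` the slow eigenvalue of the two-compartment disposition
matrix (`k10 = Cl/V`, `k12 = Clp/V`, `k21 = Clp/Vp`); when the
inter-compartmental clearance is negligible the β phase carries no mass and
the one-compartment value `ln 2 · V/Cl` is returned instead. Under constant
subcutaneous input R (µmol/d) the unique steady state is
`Css = F·R/(Cl + Vm/Km)` and `A_dp = (Vm/Km)·Css/Kout`.

## Simulation

Dosing discontinuities (infusion start/stop, implant placement, removal,
depletion of a finite reservoir load) are known a priori, so integration is
split into segments at those times rather than event-detected. Within a
segment the linear model is linear time-invariant with constant input and
is propagated **exactly** by a matrix exponential of the augmented
(state, input) system — no truncation error, no stiffness concern from the
large absorption rate constant. The saturable mode falls back to a
stiff-capable ODE solver (LSODA, rtol 1e-8 / atol 1e-10 by default) with
dense output, decoupling the output grid from solver steps. An implant
event with a finite load stops releasing at `start + load/rate` if that
precedes removal. A fifth state accumulates all elimination fluxes so mass
conservation is checkable at every output time.

## Estimation

The observation model is proportional-error: `y = f·(1 + ε)` with
matrix-specific CV σ (plasma TFV and PBMC TFV-DP fitted on their assay
scales — the objective is scale-invariant within a matrix). The ELS
objective

    O = Σ_i [ (y_i − f_i)² / (σ_m² f_i²) + ln(σ_m² f_i²) ]

equals −2·log-likelihood of the Gaussian model up to `n·ln 2π`. The error
CVs may be fixed or (default) profiled out analytically,
`σ̂_m² = mean(((y−f)/f)²)`; profiling keeps the objective a function of the
kinetic parameters only and makes noise-free data recover parameters
exactly (with a large *fixed* σ the ELS optimum sits below the data by
O(σ²) — a known property of the objective, not a defect).

Fitting is per animal: systemic parameters fixed (from IV/implant
co-modeling), F and/or Vm/Km free, log-transformed for positivity,
Nelder-Mead from three default starts (1×, 0.2×, 5× the initial values)
followed by a quasi-Newton polish; best objective wins, ties broken by the
lexicographically smallest log-parameter vector. CV% of the estimates comes
from the curvature of the objective at the optimum (covariance ≈ 2·H⁻¹ on
the log scale, where a standard error is directly a CV). Results carry the
start points, objective values and evaluation counts; non-convergence is
flagged, never silent.

**Fast scaling path.** With systemic parameters fixed and linear formation,
plasma TFV is proportional to F and PBMC TFV-DP to F·(Vm/Km), provided the
(small) formation loss from the central compartment is folded in at its
reference value. One base simulation then serves every objective
evaluation; the folding error is of order Δ(Vm/Km)/Cl — about 1% per e-fold
of Vm/Km at the default scale, far below the observation noise. The full
ODE path remains available (`fast=False`) and is used automatically
whenever other parameters are free or the model is saturable.

**Co-modeling.** `comodel` alternates per-animal fits (animal-level F,
Vm/Km) with a pooled refinement of a declared shared systemic subset,
anchored by at least one IV-dosed animal (enforced), until the pooled
objective change falls below a relative tolerance. Error CVs are profiled
globally per matrix between passes. Group summaries (mean, CV% = 100·sample
SD/mean, median, min, max) reproduce the per-group reporting structure of
the dog studies. Whether the per-animal formation clearance is estimated
with systemic parameters fixed (default) or jointly refined is the caller's
choice via `shared`.

**BLQ policy.** Below-LLOQ records are excluded from fitting by default;
LLOQ/2 inclusion is available behind a flag but is markedly worse here —
early-time TFV-DP predictions are orders of magnitude below LLOQ/2, so
imputation drags the formation clearance upward severely. Exclusion leaves
a residual upward median bias in Vm/Km of roughly 5–10% at the study's
censoring levels (~20% of PBMC records), a known limitation of
likelihood-free censoring handling; F, whose plasma data are rarely
censored, shows no such bias.

## Data normalization

BLQ concentrations are imputed at half the assay LLOQ for plots and
summaries; when the LLOQ is per sample (fluid/tissue ng per sample, PBMC
fmol per sample) it is divided by the median sample mass or cell count
first. Percent-quantifiable always uses the pre-imputation flags. Empirical
quartiles use linear (type-7) interpolation throughout — the convention is
fixed and documented because the source tables do not state one. Molar
conversions use MW(TFV) = 287.21 g/mol and the 0.2 µL/10⁶-cells PBMC
volume. Literature summaries are harmonized to median + IQR: from
median + SD (or mean + SD) by normal-theory quartiles
`center ∓ 0.6745·SD`; from median + range by first estimating
SD ≈ (max − min) / ξ(n) with ξ(n) = 2·Φ⁻¹((n − 0.375)/(n + 0.25)) — the
expected normal range — then applying the same quartile rule. The
range-based coefficient is exposed (`range_coefficient`) so other variants
can be swapped in.

## Synthetic studies

The generator emulates the preclinical designs: the beagle-dog implant
schedule (day 1 samples at 0.5, 6 and 24 h, then days 2–37, implants placed
day 0 and removed day 30), the IV study (1.0 mg/kg infused over 30 min,
rich 0.25–24 h sampling then daily to day 7) and the mouse serial-sacrifice
design (days 3/7/14/21/28, three animals per timepoint). Defaults are the
study conditions: per-implant release rate 2.1 mg/d with lognormal CV 30%
across implants, implant load 120 mg, body weights lognormal around
10.5 kg (CV 12%) for dogs, proportional noise CVs 74.6% (plasma) and 105%
(PBMC), LLOQs 1 ng/mL (plasma TFV) and 5 fmol/10⁶ cells (PBMC TFV-DP).

Noise is multiplicative lognormal with **mean one**
(`exp(N(−σ²/2, σ²))`, σ² = ln(1 + CV²)): this is the data-generating
counterpart of the proportional-error model `y = f(1+ε)` the estimator
assumes (a median-one lognormal would inflate the mean by exp(σ²/2) ≈ 1.25
at 75% CV and build a ~20% bias into every mean-model fit). The generator's
true formation clearance defaults to 2.0 L/d on the internal
1 L-equivalent PBMC scale — about 100× below Cl, so formation remains a
negligible clearance pathway, while simulated TFV-DP sits one to two orders
of magnitude above the assay LLOQ as real dog data does. One global seed
fans out to per-animal substreams, so adding an animal never perturbs
existing ones and the same seed reproduces a study bit-for-bit.

What the generator does **not** emulate: the ~14-day rise to Cmax seen in
dogs with two implants in one pocket (unexplained in vivo; no functional
form is asserted), inter-occasion variability, time-varying release rates,
assay batch effects, or tissue/fluid matrices. Passing recovery tests
therefore show that the estimator is consistent under the stated noise
model — not that the structural model is correct for any particular animal.

## Numerical choices and scales

* Amounts in µmol, times in days, volumes in litres; unit conversion only
  at the I/O boundary.
* Event intervals are half-open `[start, stop)`; profiles are continuous
  across boundaries.
* Simulation output is clamped at zero to absorb solver-level negative
  round-off (linear-path results are non-negative to machine precision).
* Profiled σ² is floored at 1e-12 to keep the objective finite on exact
  fits; optimizer failures return a large penalty rather than propagating
  exceptions mid-search.
* The Monte-Carlo recovery study uses 100 virtual single-implant dogs with
  two free parameters each; it completes in a few seconds thanks to the
  scaling fast path.

## Known limitations

* No population (random-effects) model and no Bayesian machinery: group
  summaries are summaries of independent per-animal fits.
* Censoring is handled by exclusion, not by a censored likelihood; see the
  bias note above.
* Vaginal/rectal tissue and fluid concentrations are normalized and
  summarized but not linked to the systemic model.
* The saturable formation mode has no closed-form steady state and is
  integrated numerically; its parameters are not separately identifiable
  from sparse data when `C ≪ Km`.
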