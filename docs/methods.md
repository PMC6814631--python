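# Methods

This note documents the models, estimators and numerical choices behind
`ivivc`, a toolkit for building and validating a nonlinear level-A
in vitro–in vivo correlation (IVIVC) for extended-release (ER) oral
formulations against an immediate-release (IR) oral reference arm.

## The problem

A level-A IVIVC is a point-to-point map between a formulation's in vitro
cumulative dissolution curve, F_diss(t), and its in vivo cumulative
absorption curve, Fa(t), estimated from plasma concentrations. Once
validated, the map lets an in vitro dissolution test stand in for an
in vivo bioavailability study after formulation or process changes. The
workflow here follows the classical two-stage numerical procedure used by
commercial PK software:

1. fit parametric dissolution models per formulation;
2. estimate each subject's unit impulse response (UIR) from the IR
   reference arm (strip-Ka);
3. numerically deconvolve every ER plasma profile against that subject's
   UIR to get Fa(t);
4. fit a correlation between F_diss and Fa shared by all formulations;
5. predict plasma profiles by convolution and judge prediction errors
   against the FDA/EMA criteria, including leave-one-out
   cross-validation.

## Dissolution models

Two sigmoid release families, both with mean dissolution time MDT (h),
slope factor b and plateau F_inf (fixed to 1 by default, a config switch
frees it for incomplete-release products):

* Hill: `F(t) = F_inf * t^b / (MDT^b + t^b)` — half release at t = MDT;
* Weibull: `F(t) = F_inf * (1 - exp(-(t/MDT)^b))` — 63.2% release at MDT.

Fits are unweighted least squares with multi-start (MDT initialized by
interpolating the characteristic release point, b from {0.5, 1, 2}), in
log-parameter space so MDT, b stay positive. Family choice is by
`AIC = n ln(SSE/n) + 2k` with k the number of free parameters; for
numerically perfect fits the SSE is floored at a small relative value so
the comparison stays defined, and exact ties go to Weibull. The t = 0
point is included in the residuals (both families pass through zero, so
this only pins determinism).

The regulatory similarity factor
`f2 = 50 log10(100 / sqrt(1 + mean((R - T)^2)))` (R, T in percent) uses
the shared post-zero timepoints up to one point past 85% release of the
reference — the regulatory truncation convention; the t = 0 point, where
both profiles are identically zero, is excluded so that it cannot inflate
similarity.

## Strip-Ka unit impulse response

The reference arm is oral, so its plasma profile convolves absorption
with disposition. Each subject's profile is fitted to

    C(t) = sum_i A_i [exp(-alpha_i (t - t_lag)) - exp(-ka (t - t_lag))]

for t > t_lag, by unweighted least squares; n = 1..3 exponentials and
lag/no-lag are all fitted and the lowest AIC wins (k = 2n + 1 without
lag). The absorption rate ka is then *stripped*: the stored kernel is
`UIR(t) = sum_i (A_i / dose) exp(-alpha_i t)`, the response to a unit
mass absorbed instantaneously. Deconvolved Fa is therefore expressed
relative to the IR reference's bioavailability scale.

Numerical design (none of which is dictated by the procedure itself, all
of which matters in practice):

* **Variable projection.** The nonlinear search runs over
  (log alpha_i, log gap, t_lag) only; at every step the coefficients A_i
  are profiled out by nonnegative least squares (disposition coefficients
  of a compartmental model are nonnegative). This makes convergence
  robust to poor starts. A consequence is that "flip-flop" fits
  (ka below a disposition rate) are excluded: with an oral-only
  reference the two orderings are not distinguishable anyway, and the
  stripped kernel is undefined across the boundary.
* **The degenerate ridge.** As ka approaches a disposition rate alpha,
  the oral curve tends smoothly to the t·exp(-alpha t) limit — the fit
  stays finite but the stripped coefficient A/(ka - alpha) diverges, and
  with it the kernel. ka is therefore parameterized as
  `ka = max(alpha) * (1 + gap)` with gap >= 0.1, and a soft logarithmic
  barrier activates when gap < 0.5, i.e. when the strip amplification
  ka/(ka - alpha) would exceed ~3. A matching soft barrier activates when
  ka exceeds 10/Tmax: absorption that fast is indistinguishable from a
  bolus on the sampling schedule, and letting ka run away collapses the
  amplification to 1. The two barriers bracket the region where ka is
  actually identifiable; their thresholds were calibrated on simulated
  studies so that the two failure modes contribute balanced error to the
  downstream correlation parameters.
* **Starts** come from curve stripping: the terminal log-linear slope
  seeds the slowest rate, faster rates sit on a geometric ladder, and the
  absorption gap is seeded from the observed peak time.
* Adequacy is reported as R² of the selected fit; values below 0.95 warn.

## Numerical deconvolution

The in vivo input is modeled as a piecewise-constant rate over the grid
intervals (the "point-area" discretization). Because the UIR is a sum of
exponentials, the response of a unit amount spread over an interval has a
closed form, so the observation model is an exactly assembled linear
system `C_obs = M @ amounts`. Interval amounts are recovered by
nonnegative least squares, which enforces a nondecreasing cumulative Fa
by construction; Fa may exceed 1 (relative bioavailability vs the IR
reference can exceed unity) and is not capped.

Defaults: the grid is the observation schedule (no super-resolution, no
regularization; a second-difference smoothing penalty is available and
required if a finer grid is requested, since extra intervals make the
system singular). Censored observations enter the objective as 0 ng/mL —
they are below 0.05 ng/mL by definition, negligible against ER
concentrations. The forward convolution reuses the same matrix builder,
so deconvolve/convolve are exact adjoints and round trips close to
solver tolerance; an initial jump fa(0) > 0 is treated as a bolus.

## Stage-2 correlation

The nonlinear Emax time-scale model maps the in vivo clock onto the
in vitro one,

    T_vitro = A1 * T_vivo / (A2 + T_vivo) - B2,    clamped at 0,

with one common (A1, A2, B2) for all formulations and no absorption scale
factor, so `Fa_pred(t) = F_diss(T_vitro(t))`. A1 - B2 is the asymptotic
in vitro time: release after that point is never absorbed. Negative
mapped times (early t_vivo, where the B2 offset dominates) mean zero
dissolved — the only self-consistent reading of the offset. Fits are
least squares pooled over formulations and grid times, multi-started
from (15, 5, 8) h and (16, 6, 10) h plus ±50% perturbations; standard
errors come from the Gauss-Newton covariance. Classical linear variants
(`Fa(t) = abs_scale * F_diss(time_scale (t - time_shift))`) are provided
for comparison; on data whose time relationship is genuinely nonlinear
they under-predict Cmax, which is the documented motivation for the Emax
form.

**Bias-matched fitting.** The point-area deconvolution on a sparse late
sampling grid is slightly biased (the recovered Fa plateau sits a few
percent low), and the Emax parameters amplify that bias — A2 in
particular. The pipeline therefore fits the stage-2 model against the
candidate curve *passed through the same deconvolution discretization*:
deconvolution is linear, so the composite map from a candidate absorption
curve to its deconvolved image is a precomputable matrix per formulation
(averaged over subjects). Fitting observed-deconvolved against
model-deconvolved cancels the discretization bias; with noise-free data
the full pipeline then recovers the generating (A1, A2, B2) to ~0.1%.
Plain pointwise fitting remains available (`observation_model=None`).

## NCA and validation

Cmax/Tmax are read directly off each profile (earliest time on ties);
AUC_last uses the linear trapezoid over the quantifiable range; lambda_z
is the best-adjusted-R² log-linear regression over candidate terminal
windows of >= 3 points strictly after Tmax, longer windows winning ties
within 1e-4; `AUC_inf = AUC_last + C_last/lambda_z` with observed C_last;
`t_half = ln 2 / lambda_z`. Censored samples before the first
quantifiable concentration count as 0; embedded and trailing ones are
excluded from both the trapezoid and the regression. Profiles without a
usable terminal phase report AUC_inf as unavailable rather than failing.

For validation, each formulation's predicted Fa (dense 0.1 h grid) is
convolved with every subject's own UIR at that subject's observation
times; predicted concentrations are censored with the same assay LLOQ as
the observations so both sides truncate alike. Observed and predicted
Cmax/AUC_last/AUC_inf are summarized as geometric means across subjects
(subjects without an estimable terminal phase drop out of that parameter
on both sides), and

    %PE = 100 (predicted - observed) / observed

is evaluated per formulation. Internal validation requires average
|%PE| <= 10% for Cmax and AUC_inf with every formulation <= 15%;
external validation requires <= 10%. Leave-one-out cross-validation
refits stage 2 on each three-formulation subset and validates externally
on the held-out one.

## Synthetic crossover generator

The generator emulates a five-period, single-dose crossover in N = 20
healthy subjects: an IR 24 mg reference arm and four ER 30 mg arms with
HPMC (hydroxypropyl methylcellulose) loads of 10/15/20/35%, plasma
sampled at 0, 0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 10, 12, 16, 24, 36, 48,
72 h, dissolution at 0, 1, 2, 4, 6, 8, 10, 12, 16, 20, 24 h, LLOQ
0.05 ng/mL.

Per subject, a biexponential disposition (population kernel
10 e^{-0.8t} + 0.9 e^{-0.0693t} ng/mL per mg — terminal half-life about
10 h, distribution phase under 1 h) and an absorption rate ka (population
3 /h, floored at 1.3× the fastest disposition rate so the stripped
kernel exists for every subject) are drawn with 25% lognormal
between-subject CV. The IR arm follows the closed-form oral
polyexponential. Each ER arm's cumulative input is composed exactly as
the correlation model assumes: the formulation's true Weibull curve
(b = 1.2; MDT chosen so 80% release falls at 6/8/10/16 h for A/B/C/D)
warped by the Emax map with truth (A1, A2, B2) = (11.6, 2.66, 3.49) h,
scaled by dose and a per-formulation relative bioavailability (1.0 in
the canonical fixture). The input rate is convolved with the subject's
*stripped* kernel — the object the strip-Ka analysis estimates — by
exact per-segment exponential integration of a piecewise-linear rate on
a 0.0125 h grid. Proportional residual error is lognormal with 10% CV;
dissolution noise is additive with SD 1% of label; values below the
LLOQ are censored. Subject-level parameters and measurement noise use
separate random streams, so a different noise seed perturbs the data
but not the ground truth.

Composing the truth through the model's own assumptions makes parameter
recovery well-posed: with noise at zero the pipeline must return the
generating constants, and it does (to ~0.1%). Two deliberate
simplifications follow from it. First, each formulation's absorption
plateau equals F_diss(A1 - B2), so the slowest formulation absorbs only
~50% — the generator reproduces the model's world, not every summary
statistic of the motivating study (whose raw data exist only as
figures). Second, a `two_stage` mode replaces the composed input with an
explicit fast/slow absorption profile (change-point at 4.5 h) to probe
the deconvolution under model misspecification; the recovered mean
absorption profile shows the same break. What passing tests on this
generator do *not* establish: robustness to carryover between periods
(washout is assumed complete), assay runs with drifting bias, dropout,
or absorption physiology (gut transit, regional permeability) beyond the
first-order/two-stage abstractions.

Simulation scale in the shipped tests: the canonical N = 20 study for
end-to-end checks, 50-replicate panels for model-selection rates,
N = 8 for the noise-consistency ladder — sizes at which each check's
statistic is stable under its fixed seed.

## Known limitations

* Per-subject ka is weakly identified from four early samples; the
  stripped-kernel scale inherits that variance, which dominates the
  spread of recovered (A1, A2, B2) across replicate studies (A1 within
  about ±9% across a 10-seed panel at study noise).
* Holding out the slowest-releasing formulation in cross-validation
  extrapolates beyond the fitted release-rate range; its external AUC
  prediction error can sit at the 10% regulatory boundary.
* The Emax parameters are strongly correlated (A1 and B2 jointly set the
  absorption plateau); individual parameter uncertainties are wide even
  when the fitted curve is tight.
* No mixed-effects (population) estimation anywhere: every stage is
  per-subject or pooled-mean, mirroring the two-stage procedure.
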