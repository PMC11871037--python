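# Methods

## The compartment model

The oral test is described by a gastrointestinal compartment (1) feeding a
plasma compartment (2). A bolus of glucose (1 g/kg body weight, 5% w/w
[U-¹³C₆] tracer) enters the gut at *t* = 0. Glucose leaves the gut at the
apparent absorption rate *k*ₐ; a fraction *F* = *k*₁/(*k*₁ + *k*_L) of it
reaches plasma (rate *k*₁) while the remainder is lost (rate *k*_L, e.g.
first-pass uptake). Plasma glucose — tracer and tracee alike — is cleared
at the fractional rate *k*₂ ("glucose effectiveness"). Endogenous glucose
production (EGP) by the liver feeds only the unlabelled pool.

With a tracer dose *D* and distribution volume *V*, plasma tracer
concentration follows the closed form

    c(t) = A · ka/(ka − k2) · (e^(−k2·t) − e^(−ka·t)),   A = F·D/V,

with the analytic limit A·ka·t·e^(−ka·t) at ka → k2 (a removable
singularity; note the limit carries a single factor of ka).

**Identifiability.** The tracer curve identifies (ka, k2, A) only. F is
derived from A by fixing the distribution volume at 0.2 mL per g body
weight — a documented plumbing constant, configurable, never fitted. A
derived F > 1 is reported as a volume-misspecification warning rather
than an error, because the fit itself is still valid.

**Fitting.** Unweighted nonlinear least squares by Levenberg–Marquardt
(lmfit), parameterised as ka = k2 + δ with δ > 0 so the two exponential
rates cannot swap labels. Default initial guesses ka = 0.05 /min,
k2 = 0.02 /min, amplitude = 2 × max observed tracer concentration —
order-of-magnitude values for a mouse OGTT. Standard errors come from the
Jacobian at the optimum.

## MID natural-abundance correction

Raw isotopologue intensities m0…m6 of the measured ion (default: glucose
pentaacetate ammonium adduct, C₁₆H₂₆NO₁₁, six labellable carbons) are
corrected by least squares against a convolution matrix whose column *j*
is the theoretical spectrum of a species with exactly *j* ¹³C labels and
natural abundance (IUPAC frequencies, overridable) on every remaining
atom. Columns are truncated to the retained mass window, so they sum to
≤ 1; the default window m0…m6 contains the fully labelled tracer species.
A narrower m0…m4 window is selectable but cannot report m6 enrichment —
in that mode only 1 − m0 enrichment is available. Tracer enrichment is
read as the corrected m6 fraction by default.

Negative least-squares components are *reported, not clipped*, so users
see noise and conditioning; a non-negative solve is opt-in. Downstream,
the pipeline clips the derived enrichment series at zero (the only
physically meaningful floor) before constructing tracer concentrations.

## EGP reconstruction

The unlabelled pool obeys

    dQu/dt = F·ka·Du·e^(−ka·t) + EGP(t) − k2·Qu(t),

so EGP(t) = dQu/dt + k2·Qu − F·ka·Du·e^(−ka·t), with Du the unlabelled
dose over the pool volume (0.95 × total dose for the 5% tracer bolus) and
(ka, k2, F) shared with the tracer fit — justified because tracer and
tracee travel in one bolus. Negative reconstructed values are retained
(clipping would silently bias the overall mean upward) and their share is
reported. Summaries: steady state = mean over 90–120 min ("last 30 min"),
overall = mean over 5–120 min, both on a uniform 1-min grid.

**Numerical scheme.** Differentiating an interpolant of Qu directly is
badly conditioned on the sparse sampling grid: the absorption transient
changes on a ~20-min scale while late samples are 30 min apart. A monotone
piecewise-cubic (PCHIP) interpolant of Qu produces pointwise EGP errors
up to ~86% on noiseless synthetic data; even a C² cubic spline of Qu
leaves ~4–5%. The package therefore subtracts the *closed-form bolus
response* Q_b(t) = F·ka·Du/(ka−k2)(e^(−k2t) − e^(−ka t)) — computed from
the fitted kinetics, carrying all fast dynamics — and interpolates only
the slow EGP-driven residual R = Qu − Q_b with a not-a-knot C² cubic
spline; then EGP = dR/dt + k2·R, which is algebraically identical to the
formula above. On noiseless simulations this is exact for constant EGP
and within ~2% pointwise for the suppression dip. PCHIP and a penalised
smoothing spline remain available as modes for noisy or non-smooth data.

## Insulin response

Blood-spot concentrations are converted to plasma scale by the empirical
factor 1.28 before fitting. The fitted form
INS(t) = C(e^(−ke·t) − e^(−ka·t)) is zero at t = 0, but animals have
nonzero fasting insulin, so the measured t = 0 value is taken as the
baseline and the increment above it is fitted (ka = ke + δ, δ > 0).
Time-averages use the analytic AUC
C[(e^(−ke·t₁) − e^(−ke·t₂))/ke − (e^(−ka·t₁) − e^(−ka·t₂))/ka] — no
quadrature — plus the baseline when requested; the sensitivity indices
use baseline-inclusive averages by default, since total insulin exposure
is what suppresses EGP and drives disposal. A flat increment returns a
flagged C → 0 fit, and consumers fall back to the baseline-only average.

**A caveat on C.** On the six-point sampling design the amplitude C lies
on a flat likelihood ridge with ka: under 10% assay noise its median
relative error is ~20–40% even when the optimiser starts at the truth.
The functional the indices consume — the fitted 0–120 min average — is
well identified (median error ~3% under the same conditions), and that is
the quantity the recovery tests assert. Treat reported C, ke, ka values
as a curve parameterisation, not as separately interpretable constants.

## Sensitivity indices

- IS-P = k2 / ĪNS₀→₁₂₀ — clearance per unit insulin exposure.
- IS-L = (ĒGP × ĪNS)/(EGP × INS) over a window (default 5–120 min,
  matching the EGP overall window), with the bars read as *arithmetic
  means over the analysed cohort*, grouped per sex and per test by
  default (configurable). The EGP input is the overall average. These
  interpretations are deliberate choices where several were defensible;
  they make IS-L a dimensionless relative index centred near 1.
- HOMA-IR = G₀·I₀/22.5 (mM × µU/mL) and
  Matsuda = 10000/√(G₀·I₀·Ḡ·Ī) (glucose in mg/dL, trapezoidal
  time-averages over the sampled 0–120 min window) — the
  literature-standard forms, each isolated in one auditable function.
  Insulin ng/mL → µU/mL uses the conventional factor 23.1 (configurable
  constant).

The insulin equation's rise rate and the tracer absorption rate are
independent constants despite the shared symbol kₐ in common notation;
the package names them ka_ins and ka.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested; its defaults are fixed, not tuning knobs.

- **Design**: three exposure groups (LF control, HF, GDM) × two sexes;
  each dam contributes one male and one female offspring, so
  dam-as-experimental-unit statistics are well defined. Nine glucose/MID
  sampling times (0–120 min) and six insulin times per test.
- **Baseline parameters** (LF): ka = 0.05 /min, F = 0.8, k2 = 0.02 /min,
  fasting glucose 9 mM (6-h-fasted mouse), insulin C = 2 ng/mL,
  ke = 0.015 /min, ka_ins = 0.06 /min, baseline 0.4 ng/mL; body weight
  27 g (M) / 22 g (F). Between-animal scatter is lognormal with CVs of
  7–15% — typical biological variation. The fasting steady state
  EGP_basal = k2 × G_fast holds by construction.
- **Ground-truth EGP**: basal × (1 − depth · dip(t)) where dip is a
  double-exponential (e^(−t/τ₁) − e^(−t/τ₂)) normalised to peak 1;
  OGTT default τ = (40, 8) min puts the minimum near 16 min, MMTT
  τ = (120, 25) min delays it to ~50 min, and MMTT also scales ka by 0.6
  (slower gastric emptying). Default depth 0.6. Any smooth positive shape
  would do; this one matches the qualitative physiology of
  insulin-suppressed hepatic output.
- **Group effects** (multiplicative, optionally sex-specific): GDM
  ka × 1.30, insulin C × 0.70, basal EGP × 0.75 in females; HF ka × 1.05.
  An egp_basal shift moves fasting glucose with it to preserve the
  fasting balance.
- **Measurement model**: raw MID spectra are the forward
  natural-abundance convolution of the true (m0, m6) mixture;
  multiplicative lognormal noise (mean-one) at CV 3% (glucose),
  2% (per MID channel), 10% (insulin) — typical assay precision, all
  configurable. Insulin is emitted on blood-spot scale (plasma / 1.28).
- **What it does not emulate**: litter-size variation and within-litter
  correlation beyond the shared dam id, β-cell secretion dynamics,
  macronutrient-specific incretin effects, assay drift, missing samples,
  or enrichment-dependent MS noise. Passing recovery tests therefore
  demonstrates correctness of the estimation chain under the stated
  model, not robustness to every failure mode of real data.

## Statistics

Same-sex siblings are averaged per dam before any test. Group endpoints
are compared by one-way ANOVA + Tukey HSD (per sex) and by two-way
sex × group ANOVA with type-II sums of squares (robust to unbalanced
cells; equal to type-I when balanced). Two-sided α = 0.05. Repeated-
measures/mixed-effects modelling of whole time courses is out of scope;
curves are summarised by partial trapezoidal AUCs (e.g. 0–30 min) first.

## Problem sizes and numerics

Recovery studies use 20-mouse cohorts with 5 noise replicates each
(100 fits) — enough for stable medians while keeping the full suite and
the acceptance script at a few seconds to a few tens of seconds. ODE
integration uses LSODA at rtol 1e-10; correction matrices are refused
beyond condition number 1e8; window means are exact means of grid
values. Degenerate inputs (flat insulin, zero suppression, kL = 0) have
dedicated paths and tests.

## Known limitations

- F rests entirely on the assumed distribution volume; report it
  alongside the volume used.
- EGP reconstruction inherits the fitted (ka, k2, F); tracer-fit bias
  propagates directly, and the first ~5 min are excluded from summaries
  because the interpolant is unconstrained there.
- IS-L depends on the reference-cohort definition; comparisons are only
  meaningful within one reference grouping.
- The m0–m4 window mode cannot measure a uniformly labelled hexose
  tracer's m6 species; it exists for compatibility with narrower
  acquisitions.
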