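# Methods

This note records the scientific and numerical choices behind
`hepaclear`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## In vitro estimators

**Depletion.** The metabolic stability assay is fitted single-phase:
ordinary least squares of ln(peak-area ratio) against time over the
whole 0–60 min schedule. The compound class this package targets
depletes slowly and monophasically, so no lag or biphasic option is
offered. A non-positive slope is a *finding* (stable compound), returned
as a flagged result with zero clearance rather than an error. On
noise-free exponential input the log-linearisation is exact. Note the
consequence of slow depletion: at 5% analytical CV the single-replicate
clearance estimate has a relative standard error near 80%, because only
~8% of the signal decays inside the sampling window. The estimator is
unbiased (tested on 2000 synthetic replicates), but any single replicate
is indicative at best — the same limitation applies to the real assay.

**Integration plot.** X_hep/C_buff is regressed on AUC_buff/C_buff by
OLS using all points in the 10–120 s window (an optional `max_time_s`
cutoff restricts to the early linear phase; default uses all points,
since the slope is dominated by the late, high-leverage points and the
assay is designed to stay linear through 120 s). The buffer AUC is a
linear trapezoid anchored at t = 0 with the *nominal* dose concentration
— the assay defines its own start concentration, and no t = 0 sample
exists. The slope is converted from per-second to µL/min. A negative
intercept (V₀ < 0) is physically impossible and raises a quality
warning, not an error, since small negative intercepts arise from noise.

**Temperature split.** Passive diffusion is the 4 °C slope; active
uptake is the 37 °C excess, clamped at zero with the clamping recorded
(physical non-negativity; a 4 °C slope above the 37 °C slope indicates
assay noise, not negative transport).

**Binding.** Dialysis fractions unbound are plain receiver/donor ratios.
The intracellular fraction unbound uses the on-ice cell-to-buffer
partition ratio, assuming cellular binding is temperature-independent
and active transport is fully abolished on ice. Apparent fractions
above 1 are clamped with a warning. The incubation fraction unbound for
the repeated-dosing group is taken equal to control (binding in the
suspension is non-specific).

## IVIVE and the dispersion model

Scaling uses hepatocellularity 108×10⁶ cells/g liver and 36 g liver/kg
body weight — standard rat values, overridable in `ScalingContext`.
f_u,buff defaults to 1 (protein-free assay buffer).

The dispersion context uses D_N = 0.17 and Q_h = 3.69 L/h/kg (rat), and
derives f_u,blood = f_u,p/R_b. The *control* plasma fraction unbound
(0.0078) is used for both treatment groups, each with its own R_b: the
group f_u,p values are statistically indistinguishable, and fixing one
value isolates the transporter effect in the group comparison. Both
constants are config-overridable.

Numerics of F_h: the exponent (a−1)/2D_N is evaluated as 2R_N/(1+a)
(algebraically identical via a²−1 = 4R_N·D_N), which is stable as
D_N → 0; the second exponential underflows harmlessly. The
implementation reproduces the parallel-tube limit exp(−R_N) at
D_N = 10⁻⁶ and the well-stirred limit 1/(1+R_N) at D_N = 10⁶ to better
than 10⁻³ relative, and lies between the two limits for every finite
D_N (property-tested).

Fold error and AAFE are implemented with *signed* logarithms — the AAFE
formula as conventionally written in this workflow reduces to the
geometric-mean fold error, a bias measure in which over- and
under-prediction cancel. Because the name suggests absolute values, an
`absolute=True` variant (a true spread measure, ≥ 1) is provided behind
a flag; the default follows the printed formula.

The Kp_uu-route intrinsic clearance is always computed from the supplied
inputs. Published tables of this workflow sometimes carry the product at
unrounded Kp_uu precision; with the rounded Kp_uu 0.11 the control
product is 17.6 rather than 17.3 mL/min/kg. The package does not
force-match rounded intermediates.

## Non-compartmental analysis

Linear trapezoid by default (log-down behind a flag), matching common
NCA software defaults. The terminal slope λz is chosen by maximising
adjusted R² over all candidate terminal windows of ≥ 3 points excluding
C_max, ties resolved toward the longer window — a deterministic rule
where common practice is discretionary. AUC extrapolates by C_last/λz;
AUMC by t_last·C_last/λz + C_last/λz². CL = dose/AUC₀₋∞,
Vd_ss = CL·MRT. Below-quantification values are dropped, not
zero-imputed: bolus profiles are monotone enough near the tail that
imputation would only corrupt the terminal fit. Tissue Kp corrects for
residual vascular blood, Kp = (C_t − f_v·C_b)/((1−f_v)·C_p), with
vascular fractions supplied by configuration (no hard-coded defaults).

## Minimal PBPK model

Structure: central blood compartment, one adjustment compartment
(first-order k_in/k_out, fitted empirically to capture distribution
kinetics the liver alone cannot), and a liver of `n_units = 5` serial
units. Each unit holds an extracellular (sinusoidal) and a
hepatocellular space; per-unit volumes and PS/CL terms are whole-liver
values over n. Driving forces are unbound concentrations: f_u,b on the
extracellular side, f_u,hepa intracellularly. There is no active efflux
and no biliary term (biliary excretion of parent drug is negligible for
this compound class). Five tanks in series emulate intermediate axial
dispersion: n = 1 reproduces the well-stirred limit and large n the
parallel-tube limit (tested), so the liver submodel is consistent with
the dispersion model used on the IVIVE side; at steady state the
unbound hepatocyte/extracellular ratio equals
PS_inf/(PS_diff + CL_int,met), the extended-clearance identity.

Default parameter sets `CONTROL_PARAMS` / `REPEATED_PARAMS` carry the
study values (k_in 2.7/h, k_out 1.0/h, V_central 0.018 L/kg, liver
0.037 = 0.01 + 0.027 L/kg, Q_h 3.69 L/h/kg; group-specific uptake,
metabolism and binding). Where the tabulated passive-diffusion values
conflict with narrative ones (0.3/0.86 vs 0.8/0.6 L/h/kg), the tabulated
set is the source of record and the narrative set ships as `*_ALT`
fixtures. An `uptake_scaling` multiplier (default 1.0) exposes the
empirical ×1.6 calibration applied to uptake clearances when matching
observed in vivo clearance; it is off by default so that parameter sets
remain traceable to the assays. An optional `k_el` adds lumped
first-order central elimination, used only by reduced one-compartment
configurations in closed-form checks.

Integration: LSODA with analytic (constant) Jacobian, rtol 10⁻⁸,
atol 10⁻¹⁰, dense output; reporting grid 0–10 h at 0.01 h. The system
is linear, so dose-proportionality is exact and mass balance (sum of
all states plus cumulative eliminated = dose) holds to ~10⁻¹³ relative.
Exposure metrics integrate the dense solution on a fine quadrature grid
independent of the sampling schedule. Clearance summaries integrate to
300 h (≈ 30 terminal half-lives) so the extrapolated tail is negligible.

## Monte Carlo and sensitivity

Uncertain parameters (PS_inf,act, PS_diff, CL_int,met, f_u,hepa; assay
mean ± SD) are sampled independently — no correlation structure is
measured by the assays — from lognormals matched to the arithmetic
moments. The moment-matching transform is the standard
μ_ω = ln(μ_x²/√(σ_x²+μ_x²)), σ_ω = √ln(1+σ_x²/μ_x²); both the analytic
moments and 10⁶-draw sampling moments round-trip within 1% (tested).
One independent generator stream per parameter, streams keyed by
(seed, index in sorted-name order), so runs are bit-reproducible and
insensitive to later additions. Failed draws are excluded and counted;
more than 1% failures aborts the run. Percentiles (default
5/20/35/50/65/80/95) use linear interpolation between order statistics.
Default n = 1000 draws on a 0.1 h grid runs in well under a minute.

NSC uses a forward +10% perturbation, matching the workflow it
implements; the implementation converges to the analytic logarithmic
derivative as the perturbation shrinks (verified against the
one-compartment closed form −1/1.1/0.1·… = −0.909 at +10% and −1 in the
limit). Categories are left-closed at 0.2 and 0.5.

## Synthetic data

The generator emulates: monophasic depletion (exponential decay ×
lognormal noise, t = 0 anchored at 1), linear-phase uptake with buffer
depletion tracked by closed-form mass balance (cleared drug counted as
cell-associated; no metabolism on the 2-minute time scale), dialysis
pairs, and IV plasma profiles sampled from the PBPK model at 9 time
points over 10 h with bile/urine cumulative amounts as configured tiny
fractions (default 0.1%/0.02%) of eliminated mass. Noise is
multiplicative lognormal with unit median — CV 5% in vitro, 10% in vivo.

The ground-truth fixtures mirror the study's measured values; the
control in vitro block (PS_inf,hep 11.9, passive 1.29 µL/min/10⁶ cells)
scales exactly to the control PBPK uptake block (2.5 + 0.3 L/h/kg with
`uptake_scaling = 1`), so end-to-end recovery tests compare like with
like.

What the generator does **not** emulate: inter-animal variability
(profiles are single-"subject"), assay-specific artefacts
(chromatographic interference, matrix effects, oil-spin carryover),
the 14-day induction dynamics (the two groups are distinct static
parameter sets), and absorption after intraperitoneal dosing. Passing
simulate-and-refit tests therefore demonstrates estimator correctness
and pipeline consistency under idealised noise, not robustness to real
bioanalytical failure modes.

## Known limitations

* Whole-body scaling is rat-specific; no human scaling is provided.
* The λz window rule is one defensible convention among several; NCA
  results on sparse, noisy tails can differ across conventions.
* The adjustment-compartment parameters are consumed as given, not
  refitted; the package contains no parameter-estimation machinery.
* Group comparison statistics are limited to descriptive summaries.
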