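# hepaclear

Hepatocyte-assay IVIVE, dispersion-model hepatic clearance, and minimal
PBPK modelling of time-dependent pharmacokinetics in rat.

## The problem

Some drugs change their own pharmacokinetics under repeated dosing: after
two weeks of daily administration, systemic exposure can drop several-fold
without any change in metabolic enzyme activity, because the drug induces
its own hepatic **uptake** transporters. Disentangling uptake induction
from metabolic induction requires (i) separate cell-level measurements of
metabolism, uptake and binding in hepatocytes isolated from treated and
untreated animals, (ii) a scaling framework that turns those measurements
into whole-body clearance predictions under different rate-limiting
assumptions, and (iii) a mechanistic model that shows the resulting
plasma/liver concentration profiles are consistent with observation.
`hepaclear` implements that full chain for the rat, plus a synthetic-data
generator so every estimation stage can be validated by
simulate-and-refit.

## The model

**In vitro assays** (`hepaclear.invitro`). Substrate depletion in
hepatocyte suspension is monophasic: ln-linear regression of the parent
peak-area ratio gives the depletion rate k and
CL_int,met,vitro = k·V_inc (µL/min per 10⁶ cells). Initial uptake
clearance comes from the integration plot,

> X_hep(t)/C_buff(t) = PS_inf,hep · AUC_buff(0–t)/C_buff(t) + V₀,

whose slope is PS_inf,hep; running the assay at 37 °C and on ice splits
the slope into active (PS_inf,act) and passive (PS_diff) components.
Equilibrium dialysis gives fractions unbound (f_u = C_receiver/C_donor);
on-ice cell/buffer partitioning gives the intracellular fraction unbound
f_u,hepa = V_cell·C_buffer/A_cell; and the 37 °C/4 °C partition ratio
gives the steady-state unbound liver-to-medium ratio
Kp_uu,ss = Kp(37 °C)/Kp(4 °C).

**IVIVE** (`hepaclear.ivive`). Cell-level clearances scale physiologically
(108×10⁶ cells/g liver × 36 g liver/kg). The extended clearance concept
combines them:

> CL_int,all = CL_int,met · (PS_inf,act + PS_diff) / (PS_eff,act + PS_diff + CL_int,met)

with three limiting cases: metabolism-limited (CL_int,all ≅ CL_int,met),
uptake-limited (CL_int,all ≅ PS_inf), and the Kp_uu route
(CL_int,all = CL_int,met·Kp_uu,ss). Hepatic clearance follows from the
axial dispersion model, F_h = 4a/[(1+a)²e^{(a−1)/2D_N} − (1−a)²e^{−(a+1)/2D_N}]
with a = √(1+4R_N·D_N), R_N = f_u,blood·CL_int,all/Q_h, D_N = 0.17, and
CL_h = Q_h(1−F_h)·R_b. Predictions are scored by fold error and the
geometric-mean fold error (AAFE).

**Minimal PBPK** (`hepaclear.mpbpk`). A central compartment, one
first-order adjustment compartment, and a liver of five serial units —
each split into extracellular and hepatocellular spaces with active +
passive uptake, passive back-flux and intracellular metabolism driven by
unbound concentrations — emulate the dispersion model mechanistically.
The system is linear; mass balance is conserved to solver tolerance.

**Uncertainty and sensitivity** (`hepaclear.uncertainty`). Assay
mean ± SD values are propagated as moment-matched lognormals
(μ_ω = ln(μ_x²/√(σ_x²+μ_x²)), σ_ω = √ln(1+σ_x²/μ_x²)) through 1000
simulations, summarised as 5/20/35/50/65/80/95th percentile bands.
Local sensitivity uses normalized sensitivity coefficients
NSC = ((r′−r)/r)/((p′−p)/p) at +10% perturbation, classified
low/medium/high at |NSC| = 0.2 and 0.5.

## Worked example

```bash
python examples/ivive_clearance_table.py
```

prints (abridged):

```
   group  method  clint_all_ml_min_kg    fh  clh_ml_h_kg  observed_cl_ml_h_kg  fold_error
 control       1              160.380 0.995       74.811                30.02       2.492
 control       2               46.267 0.999       21.632                30.02       0.721
repeated       1              205.335 0.994       95.744               137.90       0.694
repeated       2              167.962 0.995       78.370               137.90       0.568
```

Reading: scaling the control group's depletion-assay clearance
(1.32 µL/min/10⁶ cells ÷ f_u,inc 0.032 × 108 × 36/1000) gives
CL_int,all = 160.4 mL/min/kg, and the dispersion model turns that into a
predicted hepatic clearance of 74.8 mL/h/kg — 2.5-fold above the observed
30.02 mL/h/kg. The metabolism-limited route (method 1) barely changes
between groups, while the uptake-limited route (method 2) predicts both
groups within fold-error ≲ 1.8 and reproduces the ~4.6-fold clearance
increase after repeated dosing: the time-dependence is an uptake
phenomenon. Other examples cover assay fitting (`assay_fitting.py`), PBPK
simulation (`pbpk_simulation.py`) and Monte Carlo/sensitivity analysis
(`uncertainty_and_sensitivity.py`). A thin CLI (`hepaclear ivive|simulate|
nca|fixtures`) wraps the same functions for config-driven runs.

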