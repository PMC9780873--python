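"""Predict hepatic clearance from hepatocyte assay values.

Starts from the measured in vitro numbers for the control and
repeated-dosing rat groups (intrinsic metabolic clearance from the
depletion assay, uptake clearance from the integration plot, binding
fractions from dialysis), scales them to whole body, and predicts
hepatic clearance with the dispersion liver model under each of the
three rate-limiting assumptions.
"""

from hepaclear import (
    DispersionContext,
    ExtendedClearanceParams,
    ivive_report,
    scale_clint_met,
    scale_ps_inf,
)

groups = {}
for name, clint_vitro, ps_vitro, ps_passive_vitro, kpuu in [
    ("control", 1.32, 11.9, 1.29, 0.11),
    ("repeated", 1.69, 43.2, 3.70, 1.7),
]:
    clint_met = scale_clint_met(clint_vitro, fu_inc_hepa=0.032)
    ps_total = scale_ps_inf(ps_vitro)
    ps_diff = scale_ps_inf(ps_passive_vitro)
    groups[name] = ExtendedClearanceParams(
        clint_met=clint_met,
        ps_inf_act=ps_total - ps_diff,
        ps_diff=ps_diff,
        kpuu_ss=kpuu,
    )

contexts = {
    "control": DispersionContext(fu_p=0.0078, r_b=3.95),
    "repeated": DispersionContext(fu_p=0.0078, r_b=4.53),
}
observed = {"control": 30.02, "repeated": 137.9}

report = ivive_report(groups, contexts, observed)
print(report.round(3).to_string(index=False))
print(
    "\nEach row is one group x rate-limiting assumption: method 1 treats "
    "metabolism, method 2 hepatic uptake, method 3 the unbound partition "
    "coefficient as rate-determining. clh is the dispersion-model hepatic "
    "plasma clearance (mL/h/kg); fold_error compares it with the observed "
    "systemic clearance. Only the uptake-limited route (method 2) tracks "
    "the ~4.6-fold clearance increase after repeated dosing."
)
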