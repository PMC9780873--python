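"""Estimate in vitro kinetic parameters from synthetic assay data.

Generates noisy hepatocyte assay time courses at known ground truth,
then refits them: a substrate-depletion trace for intrinsic metabolic
clearance, and paired 37 degC / 4 degC uptake traces for the
integration-plot uptake clearance and its active/passive split.
"""

from hepaclear import (
    CONTROL_TRUTH,
    fit_depletion,
    fit_integration_plot,
    make_depletion,
    make_uptake,
    split_active_passive,
)

import numpy as np

fits = [
    fit_depletion(make_depletion(CONTROL_TRUTH, noise_cv=0.05, seed=s))
    for s in range(10)
]
clints = np.array([f.clint_met_vitro for f in fits])
print(f"depletion (10 replicates): CL_int,met,vitro median = "
      f"{np.median(clints):.2f} uL/min/1e6 cells, range "
      f"{clints.min():.2f}-{clints.max():.2f} (truth 1.32)")
print("  -> the compound depletes only ~8% over 60 min, so single-replicate"
      "\n     estimates scatter widely; the median is unbiased")

f37 = fit_integration_plot(make_uptake(CONTROL_TRUTH, 37, noise_cv=0.05, seed=7))
f4 = fit_integration_plot(make_uptake(CONTROL_TRUTH, 4, noise_cv=0.05, seed=8))
split = split_active_passive(f37.slope, f4.slope)
print(f"uptake slope 37C = {f37.slope:.2f}, 4C = {f4.slope:.2f} uL/min/1e6 cells")
print(f"active = {split.ps_act_vitro:.2f}, passive = {split.ps_diff_vitro:.2f} "
      f"(truth 10.61 / 1.29)")
print(
    "\nThe 4 degC assay freezes active transport, so the slope difference "
    "isolates the transporter-mediated component of hepatocyte uptake."
)
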