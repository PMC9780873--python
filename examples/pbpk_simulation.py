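"""Simulate the minimal PBPK model and summarise exposure.

Runs an IV bolus (3 mg/kg) through the five-unit permeability-limited
liver model for both treatment groups, reports plasma/liver exposure and
systemic clearance, and checks mass balance.
"""

from hepaclear import CONTROL_PARAMS, REPEATED_PARAMS, build_model, model_auc, simulate_iv_bolus
from hepaclear.mpbpk import default_grid

for name, params in [("control", CONTROL_PARAMS), ("repeated", REPEATED_PARAMS)]:
    res = simulate_iv_bolus(build_model(params), dose=3.0, t_grid=default_grid())
    res_long = simulate_iv_bolus(build_model(params), 3.0, default_grid(300.0, 0.5))
    cl = 3.0 / model_auc(res_long) * 1000.0
    print(f"{name:9s} plasma AUC(0-10h) = {model_auc(res):7.2f} mg*h/L   "
          f"liver AUC(0-10h) = {model_auc(res, matrix='liver'):7.2f} mg*h/L   "
          f"CL = {cl:6.1f} mL/h/kg   "
          f"mass-balance err <= {res.mass_balance_error()[1:].max():.1e}")

print(
    "\nThe repeated-dosing parameter set (induced active uptake, higher "
    "intracellular fraction unbound) clears the drug several-fold faster, "
    "reproducing the direction of the observed time-dependent clearance."
)
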