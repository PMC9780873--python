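"""Monte Carlo uncertainty bands and normalized sensitivity coefficients.

Propagates the assay-derived parameter uncertainty (lognormal, moment-
matched to mean +/- SD) through the control PBPK model and tabulates
which parameters drive plasma and liver exposure.
"""

import numpy as np

from hepaclear import (
    CONTROL_PARAMS,
    LognormalSpec,
    MonteCarloRun,
    run_monte_carlo,
    sensitivity_table,
)
from hepaclear.mpbpk import default_grid

specs = (
    LognormalSpec("ps_inf_act", 2.5, 0.8),
    LognormalSpec("ps_diff", 0.3, 0.09),
    LognormalSpec("clint_met", 9.8, 1.0),
    LognormalSpec("fu_hepa", 0.004, 0.002),
)
run = MonteCarloRun(specs, n_draws=1000, seed=1)
bands = run_monte_carlo(run, CONTROL_PARAMS, dose=3.0, t_grid=default_grid(10.0, 0.1))

p = dict(zip(bands.percentiles, bands.plasma))
for t_query in (0.5, 2.0, 8.0):
    i = int(np.argmin(np.abs(bands.times - t_query)))
    print(f"t = {t_query:4.1f} h  plasma conc 5th/50th/95th pct: "
          f"{p[5.0][i]:.3f} / {p[50.0][i]:.3f} / {p[95.0][i]:.3f} mg/L")

print()
print(sensitivity_table(CONTROL_PARAMS).round(3).to_string(index=False))
print(
    "\nNSC is the fractional change in AUC per fractional parameter change "
    "(+10%). Plasma exposure is dominated by active uptake; liver exposure "
    "by metabolism and intracellular binding."
)
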