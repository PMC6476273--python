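"""The two-cell amplifier–reporter sensor and its Bar1 threshold.

Simulates 260-minute endpoint GFP of the consortium across doses for the
three sensor configurations (their constitutive seeds differ), then sweeps
the Bar1 pool: Bar1 degrades the constitutively leaked alpha-factor, so
basal output falls as Bar1 rises while the capped maximum response is
retained.
"""

import numpy as np

from gpcrtune import SensorVariant, bar1_sweep, default_twocell_rates, twocell_dose_response
from gpcrtune.twocell import transition_dose_grid

rates = default_twocell_rates()
grid = transition_dose_grid(n=9)

print("260-min endpoint GFP (M) per variant (dose grid spans the model's")
print("response transition, which the printed rate constants place at")
print("sub-femtomolar ligand):")
for name in ("digital_noBar1", "digital_withBar1"):
    curve = twocell_dose_response(rates, SensorVariant.named(name), dose_grid=grid)
    print(f"  {name:17s} basal {curve.responses[0]:.3e}  "
          f"max {curve.responses.max():.3e}")

sweep = bar1_sweep(factors=(0.0, 1.0, 10.0, 100.0))
print("\nBar1 sweep (constitutive leak calibrated to the 10.4 nM no-Bar1 level):")
print(sweep.summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\nbasal falls monotonically with Bar1 while emax is retained; the Hill"
    "\nslope barely moves because at these rate constants Bar1 capture stays"
    "\nfirst-order in alpha-factor (a linear sink shifts EC50, it cannot"
    "\nsteepen the curve)."
)
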