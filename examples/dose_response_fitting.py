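"""4PL fitting, curve metrics and consortium linearization.

Generates a noisy triplicate dose-response around a known 4PL, fits it,
derives the sensor figures of merit (logEC50, Hill slope, sensitivity,
operational range, tightness, dynamic range), then composes a 1:1:1 mixture
of three strains with staggered EC50s and shows the flattened (linearized)
population response.
"""

import numpy as np

from gpcrtune import (
    FourPL,
    MixtureSpec,
    NoiseModel,
    compose_mixture,
    curve_metrics,
    fit_fourpl,
    gen_dose_response,
    span_fold_change,
)

truth = FourPL(A=100.0, B=1.3, C=3e-8, D=1e4)
doses = np.concatenate([[0.0], np.logspace(-10, -5, 12)])
ds = gen_dose_response(truth, doses, n_reps=3, noise=NoiseModel(cv=0.05, seed=7))
fit, report = fit_fourpl((ds.readouts["dose_M"].to_numpy(),
                          ds.readouts["response"].to_numpy()))
m = curve_metrics(fit)
print(f"fitted 4PL: A={fit.A:.1f} B={fit.B:.3f} C={fit.C:.3e} D={fit.D:.1f} "
      f"(truth C={truth.C:.1e}), R^2={report.r_squared:.4f}")
print(f"logEC50 {m.logEC50:.3f}, Hill {m.hill_slope:.3f}, "
      f"sensitivity {m.sensitivity:.2e} M (lowest dose giving 2x basal)")
print(f"operational range {m.operational_range_orders:.2f} orders, "
      f"tightness {m.tightness:.4f}, dynamic range {m.dynamic_range:.0f}")

members = [FourPL(100.0, 1.3, c, 1e4) for c in (3e-9, 3e-8, 3e-7)]
grid = np.concatenate([[0.0], np.logspace(-11, -4, 21)])
mixture = compose_mixture(MixtureSpec(members, [1 / 3] * 3), grid)
mfit, _ = fit_fourpl(mixture)
mm = curve_metrics(mfit)
print(f"\n1:1:1 consortium of EC50s 3 nM / 30 nM / 300 nM:")
print(f"  member Hill {members[0].B:.2f} -> mixture Hill {mfit.B:.2f}; "
      f"operational range {m.operational_range_orders:.2f} -> "
      f"{mm.operational_range_orders:.2f} orders "
      f"({span_fold_change(m.operational_range_orders, mm.operational_range_orders):.1f}-fold wider)")
print("Averaging staggered sensors flattens the slope: the population reads")
print("linearly over a wider concentration span than any single strain.")
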