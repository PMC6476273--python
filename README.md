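# gpcrtune

Mass-action models and dose-response analytics for rationally tuned GPCR
signaling in engineered yeast.

When the *S. cerevisiae* pheromone pathway is stripped to its core — one
receptor (Ste2 or a heterologous GPCR), the heterotrimeric G protein
(Gα = Gpa1, Gβγ = Ste4/Ste18), the Ste5 scaffold and a reporter — the
dose-response curve of the strain becomes a designable object: its
sensitivity, basal activity, amplitude and operational range follow from the
expression levels of those few components. `gpcrtune` is a simulation and
analysis toolkit for that design space, aimed at synthetic biologists and
modellers building yeast biosensors:

* **Ternary complex model** (`gpcrtune.ternary`) — a cubic ternary complex
  model of receptor activation: receptor states occupy a cube with axes
  ligand occupancy (R ↔ LR), conformation (R ↔ R\*) and G-protein coupling
  (R ↔ RG), with cooperativity factors ν, ζ, μ coupling the axes. Active
  coupled receptor (R\*G, LR\*G) catalyses G-protein activation, releasing
  Gα·GTP and activated Gβγ\*; Ste5 binds Gβγ\* into the output complex
  [Gβγ\*·STE5] and competes for inactive Gβγ. Sixteen species, four exact
  conservation laws, stiff BDF integration, and promoter-library sweeps of
  R/Gα/Gβγ abundance.
* **Transcriptional feedback variant** (`gpcrtune.feedback`) — the same
  receptor cube plus synthesis, internalization, degradation and a two-step
  delay chain (X1 → X2) whose active output drives positive feedback
  production of receptor and Gα, reproducing the native pathway's
  self-amplification.
* **Two-cell digital sensor** (`gpcrtune.twocell`) — an amplifier cell that
  converts ligand into secreted α-factor and a reporter cell that converts
  α-factor into GFP, both through reduced receptor → G protein → effector →
  transcriptional-delay cascades with capped product pools; the reporter
  secretes the protease Bar1, which captures and destroys α-factor
  (Bar1 + αf → InactiveBar1 → Bar1) to threshold activation. Includes Bar1
  sweeps and multi-start bounded least-squares recovery of rate parameters
  from endpoint data.
* **Dose-response analytics** (`gpcrtune.doseresponse`) — 4PL fitting
  f(x) = (A − D)/(1 + (x/C)^B) + D in log-dose space and the derived sensor
  figures of merit: logEC50, Hill slope B, sensitivity (lowest dose giving a
  2-fold change over basal), operational range (log₁₀ span between 5% and
  95% of the activated response, closed form (2/|B|)·log₁₀19), tightness
  (1/basal) and dynamic range (Emax/basal); growth rates
  ln(OD(t+3h)/OD(t))/3; residual/R² reports; and consortium composition
  (weighted population averaging of member curves).
* **Synthetic data** (`gpcrtune.synth`) — seeded generators for plate-reader
  dose-response tables, 10,000-cell lognormal flow-cytometry populations
  summarised by geometric mean, two-cell model endpoints and OD600 series;
  every dataset carries its generating truth for recovery tests.
* **Quantitation** (`gpcrtune.quant`) — monoisotopic diagnostic-ion m/z
  (e.g. melatonin [M+H]⁺ = 233.1285, [M+H−C₂H₅NO]⁺ = 174.0913), linear
  standard-curve quantitation, and 4PL inversion to read concentrations off
  sensor fluorescence.

Configuration files (flat JSON/YAML keyed by parameter name) and CSV
curve/sweep interchange live in `gpcrtune.io`. The package is a library:
`examples/` holds one short narrative script per capability.

## Worked example

Sweep Gα abundance around the base parameter set and summarise each curve:

```python
import numpy as np
from gpcrtune import default_ternary_rates, sweep_component

rates, totals = default_ternary_rates()
sweep = sweep_component(
    rates, totals, "Ga_tot",
    factors=np.logspace(-1, 1, 5),
    dose_grid=np.concatenate([[0.0], np.logspace(-12, -4, 9)]),
)
print(sweep.summary.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

```
 factor    basal     emax  fold_change
    0.1 1.56e-16 1.68e-16         1.08
  0.316  1.2e-16 1.57e-16         1.31
      1 1.56e-17 1.22e-16         7.82
   3.16 5.47e-19 1.09e-17         19.9
     10 1.31e-19 3.72e-19         2.84
```

`basal` is the equilibrated zero-ligand readout [Gβγ\*·STE5], `emax` the
maximum endpoint over the dose grid, and `fold_change = emax/basal` the
ON/OFF ratio. Basal falls monotonically as Gα rises (free Gβγ is
sequestered into heterotrimer), while the fold change peaks at an interior
Gα level — under-expressed Gα leaks signal, over-expressed Gα sponges it,
and the optimum sits in between. The same call with `"R_tot"` shows Emax
rising monotonically with receptor abundance.

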