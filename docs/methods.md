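# Methods

## The ternary complex model (`gpcrtune.ternary`)

Receptor states form a cube with axes ligand occupancy, conformational
activation and G-protein coupling: {R, LR, R\*, LR\*, RG, LRG, R\*G, LR\*G}.
Base rate constants (kL±, kact±, kG±) apply on the "origin" edges;
dimensionless cooperativity factors multiply them on displaced edges — ν±
for ligand binding to G-coupled receptor, ζ± for activation of
ligand-bound receptor, μ± for G coupling to active receptor (products of
factors on doubly displaced edges). The G-protein cycle: active coupled
receptor releases Gα·GTP + Gβγ\* at kGTP+ (ν⁻·kGTP+ from LR\*G);
heterotrimer G dissociates spontaneously at kGRA⁻ into Gα·GDP + Gβγ\*;
Gα·GDP re-associates with either dimer form at kGRA+; the nucleotide cycle
on free Gα runs at khyd± ; inactive Gβγ interconverts with Gβγ\* at
kconact/krev. Ste5 binds Gβγ\* (kE1±) into the readout complex
[Gβγ\*·STE5] and binds inactive Gβγ (kE2±) into an unproductive complex.
Sixteen species; exact linear conservation of receptor, Gα, Gβγ and Ste5.

The right-hand side is implemented in *flux form*: each reaction's net flux
is computed once and added/subtracted to its participants, so every
conservation sum cancels identically in floating point. This is what lets
the BDF integrator hold the conservation laws to ~1e-13 relative over
1e8-second horizons; the test suite uses those sums as the arbiter of
correctness of every term.

**Protocol.** Rates are per second, so "time" is seconds. The basal state
is obtained by integrating from the initial partition (all receptor free
and inactive; Gα/Gβγ paired into heterotrimer up to the smaller total;
excess as free Gα·GDP or inactive Gβγ; Ste5 unbound) with L = 0 over
log-spaced stages to a 1e8 s horizon, stopping early when
max|dX/dt| < 1e-24 M/s, then polishing with a conservation-pinned Newton
refinement (rows of the singular steady-state system are replaced by the
conservation residuals). Dose-response: from that basal state, hold L
constant at each dose and report [Gβγ\*·STE5] after t_end = 1000 s.
Integration uses BDF with rtol 1e-10 and atol 1e-22 M — concentrations are
~4e-10 M, and looser absolute tolerances destroy the conservation laws.

**Parameters.** The tabulated base set (kL+ = 4e7 M⁻¹s⁻¹, ζ+ = 1e3,
kGTP+ = 1e-2 s⁻¹, R_tot = G_tot = 4.15e-10 M, ...) is the package default.
Ste5_tot is not tabulated anywhere; the default sets it equal to G_tot,
which keeps the readout within the sweep's dynamic range, and it is an
ordinary configurable field. Defaults for the sweeps: 9 log-spaced
abundance multipliers over 0.03–30×, dose grid of 25 log-spaced points over
1e-12–1e-4 M plus dose 0.

**Printed-equation divergences.** The published ODE text of this model
carries typographical artefacts; the implementation derives the equations
from the reaction list and treats the conservation laws as authoritative.
Divergences from the printed text: (i) `kE=1`/`kE=2` read as kE1⁻/kE2⁻;
(ii) the bimolecular terms printed without their second concentration
factor (e.g. `μ−ν−kG−[LR∗]`) carry it here; (iii) d[R\*G] includes the
ligand-binding edge L + R\*G ⇌ LR\*G that the printed text lists only in
d[LR\*G]; (iv) in d[βγ], the Ste5-binding terms use [βγ], not [βγ\*], and
the re-association term carries its [βγ] factor.

**A steady-state consequence worth knowing.** Because heterotrimer
dissociation releases only the *active* dimer while re-association consumes
both forms, the zero-ligand steady state contains essentially no inactive
free Gβγ: the pool drains into Gβγ\* through the Gα·GDP exchange route with
timescale kGRA⁻·G / (kGRA+·(βγ+βγ\*)) — about 2e7 s at 30× Gβγ, inside the
equilibration horizon. Two consequences at the tabulated constants: basal
output *rises* steeply with Gβγ abundance, and the "inactive Gβγ sequesters
Ste5" mechanism cannot reduce Emax at equilibrium, so the Emax of a Gβγ
sweep grows monotonically rather than peaking at an interior optimum. The
fold change (Emax/basal) does peak interior, for both the Gα and the Gβγ
sweeps, and that is the quantity the package's trend tests assert. The
interior-Emax behaviour would only appear under a much shorter, explicitly
non-equilibrium pre-incubation; the package does not adopt one.

## The feedback variant (`gpcrtune.feedback`)

Same receptor cube; the free G-protein side reduces to G, Gα·GDP, Gα·GTP
and a single dimer pool βγ (no separate active form), and the open-system
processes appear: receptor synthesis kRsyn and internalization kRint (bound
complexes internalize too, returning their G to the free pool), G synthesis
kGsyn and degradation kGdeg (degradation inside complexes returns the
receptor), and a delay chain — βγ activates X1 (kX1+, mass-action), X1\*
activates X2 (kX2+), and X2\* drives production of R, G, Gα·GDP, Gα·GTP and
βγ at the five feedback rates. X1 + X1\* and X2 + X2\* are exactly
conserved. Readout: endpoint free [βγ].

Numbers and choices:

* The feedback-table values replace the base ones where they differ
  (kL+ = 9.4e4 M⁻¹s⁻¹, khyd+ = 0.1 s⁻¹, kGTP+ = 1 s⁻¹).
* The G total is not tabulated; the default is the synthesis/turnover
  balance kGsyn/kGdeg = 4.15e-10 M, which equals the tabulated receptor
  total — the balance the open system relaxes to anyway.
* kX1+/kX2+ are tabulated in s⁻¹ but act bimolecularly; the defaults divide
  the tabulated 2e-3 by X1_init (=1e-7 M) so the printed equation form keeps
  closed units: kX1+ = 2e4 M⁻¹s⁻¹. The rhs itself is plain mass action.
* The printed X2\* equation is driven by [βγ]; the implementation drives it
  by [X1\*] so the cascade is consistent (X2's own loss term already names
  X1\*).
* kRGS, kRGSsyn, kRGSdeg are tabulated but no RGS species exists in this
  network; they are stored on the rate set, ignored by the rhs, and flagged
  with a logged warning.
* The five feedback production rates appear in the equations but in no
  table. Default: kGfdbk = 1.8e-7 M/s per unit [X2\*]/M and
  kRfdbk = 10·kGfdbk (receptor feedback one order of magnitude above Gα),
  the remaining three 0. The strength was calibrated once so that
  saturating ligand roughly doubles total receptor mass at steady state
  relative to the no-feedback system (measured ratio 2.03); at that default
  the basal readout stays within 0.3% of the no-feedback basal.
* The published species count (17) exceeds the printed equations (16); the
  16 printed species are implemented. The missing equation is most likely a
  separate active-dimer pool.

## The two-cell digital sensor (`gpcrtune.twocell`)

Per cell: R ⇌ R\* (ligand binding k11/k12, unbinding k71/k72, R\*
internalization k41/k42, optional constitutive activation kcon1/kcon2),
G activation by R\* (k21/k22) against deactivation (k31/k32), effector
binding (k51/k52, k61/k62), a two-stage transcriptional delay
(α1,β1,α11,β11 / α2,β2,α12,β12), and conversion of a finite precursor pool
into product (α21,β21 / α22,β22) — prealpha → α-factor in the amplifier,
preGFP → GFP in the reporter. The pools cap production: preX + X is
conserved per cell. α-factor is exchanged through the medium (binding to R2
consumes it; R2\* unbinding returns it) and captured by Bar1
(k8·[Bar1][αf]); the inactive complex returns free Bar1 at k9 + k10 with
the α-factor destroyed, so Bar1 + InactiveBar1 is exactly conserved.
Ligand L itself is depletable through amplifier binding, as printed.
Twenty-three species; endpoint assay at 260 min = 15600 s; LSODA with
rtol 1e-8 / atol 1e-18 M for plain simulations.

**Initial state.** Receptor, G protein and effector start at 16 µM; the
prez pools start full — they are caps, not conserved sums including the
seed — and the variant's constitutive product is seeded on top of its empty
product species: 3.1 nM α-factor for the single (amplifier-only) sensor,
10.4 nM GFP for the digital sensor without Bar1, 4.4 nM for the digital
sensor with Bar1 (Bar1 then starts fully active at Bar1_tot = 1.68e-10 M).
Amplifier-only runs start with an empty reporter cell so the seeded
α-factor is not silently absorbed by the reporter's 16 µM receptor pool.

**Scale caveat.** Taken at face value (including the unit asymmetries the
table prints, e.g. k71 = 86.98 s⁻¹ vs k72 = 2.14e-7 s⁻¹, and the
bimolecular use of α21 = 2.8e6, α22 = 6.63e9), the cascade gain is so large
that the 260-minute endpoint reaches its preGFP cap for any dose above
~1e-19 M: the response transition sits at sub-femtomolar ligand. These
doses are not physical; they are where this parameter set has structure.
`transition_dose_grid()` samples that region and is the default for Bar1
sweeps and the synthetic recovery studies.

**Bar1 is a linear sink at these constants.** The capture flux k8·Bar1·αf
never approaches the recycle capacity (k9+k10)·Bar1_tot (5.7e-6 M/s vs a
maximal 3.3e-9 M/s), so free Bar1 stays pinned at Bar1_tot. Two
consequences: (i) Bar1 rescales α-factor delivery uniformly — a rightward
EC50 shift with basal reduction and full Emax retention, but *no*
steepening of the Hill slope (digitization by molecular titration would
require capture to outrun both Bar1 recycling and the reporter's receptor
absorption k12·R2 = 2.24 s⁻¹, neither of which holds here); and (ii) the
dynamics depend on k8 and Bar1_tot only through their product, so the
product is sharply identifiable from endpoint data while the individual
pair is not (an exact ridge). The fitting tests assert single-parameter
recovery and product recovery; the Bar1-sweep tests assert the basal and
Emax behaviour.

**Constitutive activation for basal studies.** With the tabulated
kcon1 = kcon2 = 0 the dose-0 trajectory is frozen (basal output exists only
as the seed), making basal Bar1-independent by construction. Basal studies
therefore run with a small constitutive amplifier activation,
kcon1 = 7.836e-21 s⁻¹ (kcon2 stays 0 so all basal flux passes through
α-factor, where Bar1 acts), calibrated once so the Bar1-free basal endpoint
equals the 10.4 nM constitutive level of the no-Bar1 sensor. The absurd
magnitude of that constant is the same scale phenomenon as above.

**Subset fitting.** `fit_twocell_subset` does multi-start bounded least
squares on log10-transformed parameters (default bounds two decades around
the tabulated value, log-uniform starts from a seeded generator,
trust-region reflective with xtol = ftol = 3e-16 and finite-difference step
1e-3 in log-space), minimising squared endpoint residuals; it reports the
best local minimum, the per-start costs and an R² residual report. On
noise-free data two independent starts converge to the same minimum to
solver precision; this replaces derivative-free/evolutionary search with
standard, seed-reproducible tooling.

## Dose-response analytics (`gpcrtune.doseresponse`)

4PL fits run in log10-dose space with data-quartile starting values
(A from the lowest-dose mean, D from the highest, C from the midpoint
crossing, B = 1), bounds B ∈ [0.05, 20] unless decreasing fits are
explicitly allowed, optional soft-L1 robust loss, and tolerances 1e-15.
Dose 0 is evaluated through the model's own A-limit rather than a pseudo-log
dose. Flat data (range below 1e-8 of magnitude) raise a dedicated
"unfittable" error. Metrics: sensitivity solves f(x) = 2·basal on the
fitted curve and is NaN-flagged when 2·basal falls outside (A, D); basal
uses a configurable floor (`max(A, basal_floor)`) so tightness = 1/basal is
defined when the fitted minimum is ≤ 0; the operational range uses the
closed form (2/|B|)·log₁₀19. Mixture composition averages *unnormalised*
member responses with population weights (total-culture fluorescence, the
plate-reader convention), making it linear in weights and basal-preserving.

## Synthetic data (`gpcrtune.synth`)

Noise is multiplicative lognormal with median 1; defaults cv = 0.1 for
plate-reader endpoints and cv = 0.4 for per-cell spread (the source assays
report no noise magnitudes; these are this package's choices). Flow samples
draw 10,000 cells and summarise by geometric mean, matching the convention
of reporting population fluorescence as the geometric mean; the arithmetic
mean is also carried. Generators share no global state: each takes its seed
from its NoiseModel, and identical seeds give bit-identical datasets. What
the generators deliberately do not emulate: instrument gating, autofluorescence
background, dose-dependent CV, or growth dilution during the assay — tests
passing on these datasets show correctness of the estimators under the
stated noise model, not robustness to real-instrument artefacts.

The 4PL recovery study fixed by the test suite: 12 doses × 3 replicates at
5% CV, 100 seeds, asserting the median |logEC50 error| < 0.1 (measured
~0.015).

## Quantitation (`gpcrtune.quant`)

Monoisotopic masses use most-abundant-isotope values hard-coded to ≥ 6
decimals (cross-checked in the tests against an independent mass
calculator). [M+H]⁺ adds the *proton* mass 1.007276 Da — not the hydrogen
atom — which is the convention that reproduces the published melatonin ions
at 4 decimals; m/z values are rounded half-even to 4 decimals to match
standard table precision. The standard curve is ordinary least squares
(its functional form is not specified by the source workflow; linear OLS is
adopted, with the usual caveat about the limited linear range of LC-MS
response); inversion flags concentrations outside the calibrated range.
4PL inversion x = C·((A−D)/(y−D) − 1)^{1/B} is exact on (A, D)-interior
fluorescence and returns a flagged NaN otherwise.

## Problem sizes

Defaults used by the test suite and the acceptance script: promoter-library
trend checks use 7 sweep factors × a 10-point dose grid per component;
conservation checks use 20 randomised parameter sets (10 per model) sampled
±0.7 (ternary) / ±0.5 (two-cell) decades around the tabulated values; the
two-cell recovery studies use 10 doses and 3–4 optimizer starts. These
sizes are the package's defaults for desk-scale runs; all are ordinary
function arguments.

## Known limitations

* The ternary and feedback models are deterministic mass-action ODEs: no
  stochasticity, no MAPK cascade beyond the Ste5 scaffold, no SBML import.
* No re-fit against the original experimental readings is possible (they
  are unpublished); recovery tests run against the package's own synthetic
  data, and the published per-dataset R² values are replaced by a
  model-self-fit check.
* The two qualitative claims the printed parameter sets provably cannot
  produce — an interior Emax optimum of the Gβγ sweep at equilibrium, and
  Hill-slope steepening from 1× Bar1 — are documented above and left as
  failing assertions in the acceptance suite rather than papered over.
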