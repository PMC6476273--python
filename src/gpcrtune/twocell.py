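"""Two-cell amplifier–reporter digital-sensor model with Bar1 thresholding.

An engineered consortium narrows the operational range of a linear sensor
into a near-digital switch. The amplifier cell senses the ligand L (a
melatonin proxy) through a reduced receptor/G-protein/effector cascade and,
after a two-step transcriptional delay (z1 -> z2), converts a finite
pre-alpha-factor pool into secreted alpha-factor. The reporter cell senses
alpha-factor with the same reduced cascade and converts a finite pre-GFP
pool into GFP. The reporter also secretes the protease Bar1, which captures
alpha-factor (k8) and destroys it; the Bar1 enzyme recycles (k9) or turns
over (k10), both returning free Bar1, so Bar1 + InactiveBar1 is conserved.
Low alpha-factor levels are therefore silently degraded and the reporter
only fires once Bar1's capture capacity saturates — the activation
threshold that digitizes the response.

The finite prez pools act as caps: preX + X is conserved per cell, so no
product can exceed its pool plus its constitutive seed. Twenty-three species
in all. Rates in s^-1 / M^-1 s^-1, concentrations in M; the canonical
endpoint assay reads GFP (or alpha-factor for amplifier-only runs) after
260 min = 15600 s.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .curves import ResponseCurve
from .doseresponse import CurveMetrics, ResidualSet, curve_metrics, fit_fourpl, r_squared

__all__ = [
    "TwoCellRateSet",
    "TwoCellState",
    "SensorVariant",
    "Bar1SweepResult",
    "TwoCellFit",
    "TWOCELL_SPECIES",
    "DEFAULT_T_END",
    "default_twocell_rates",
    "default_twocell_dose_grid",
    "transition_dose_grid",
    "KCON_BASAL",
    "initial_twocell_state",
    "twocell_rhs",
    "twocell_dose_response",
    "bar1_sweep",
    "fit_twocell_subset",
]

TWOCELL_SPECIES = (
    # amplifier cell
    "R1", "R1star", "Goff1", "Gon1", "Effector1", "Gon1Effector1",
    "z11", "z21", "prealpha", "alphafactor",
    # reporter cell
    "R2", "R2star", "Goff2", "Gon2", "Effector2", "Gon2Effector2",
    "z12", "z22", "preGFP", "GFP",
    # shared medium
    "L", "Bar1", "InactiveBar1",
)
_IDX = {name: i for i, name in enumerate(TWOCELL_SPECIES)}

DEFAULT_T_END = 15600.0  # s; the 260-minute endpoint assay
INITIAL_CASCADE = 1.6e-5  # M; receptor, G-protein and effector start level per cell

#: Constitutive amplifier receptor-activation rate (s^-1) used for
#: basal-activity studies such as the Bar1 sweep. With kcon1 = kcon2 = 0
#: (the tabulated default) the dose-0 trajectory is frozen and basal output
#: exists only as the seeded initial product; kcon1 here is calibrated once
#: so that the no-Bar1 dose-0 GFP endpoint (seeded at 0) equals the 10.4 nM
#: constitutive level of the Bar1-free digital sensor. The reporter keeps
#: kcon2 = 0 so all basal flux passes through alpha-factor, where Bar1 acts.
KCON_BASAL = (7.836e-21, 0.0)


@dataclass(frozen=True)
class TwoCellRateSet:
    """Rate constants and pool totals of the two-cell system.

    Trailing 1/2 on the k's distinguishes amplifier/reporter cell; the
    alpha/beta pairs are the transcriptional-delay constants. Units are as
    tabulated and taken at face value (e.g. k71 in s^-1 vs the much smaller
    k72; alpha21/alpha22 act bimolecularly on z2 * prez).
    """

    k11: float = 2.75e8  # M^-1 s^-1, ligand binding (amplifier)
    k12: float = 1.40e5  # M^-1 s^-1, alpha-factor binding (reporter)
    k21: float = 2726.24  # s^-1, G activation by R*
    k22: float = 1.21e4
    k31: float = 4.00e-3  # s^-1, G deactivation
    k32: float = 4.00e-3
    k41: float = 1.06e-7  # s^-1, R* internalization
    k42: float = 3.08e-8
    k51: float = 1.04e6  # M^-1 s^-1, effector binding
    k52: float = 1.04e6
    k61: float = 0.0942  # s^-1, effector unbinding
    k62: float = 0.0942
    k71: float = 86.98  # s^-1, ligand unbinding
    k72: float = 2.14e-7
    alpha1: float = 17.75  # transcriptional delay, stage 1
    alpha2: float = 17.75
    beta1: float = 1859.57
    beta2: float = 1859.57
    alpha11: float = 42.41  # stage 2
    alpha12: float = 42.41
    beta11: float = 0.93
    beta12: float = 0.93
    alpha21: float = 2.80e6  # product activation from the prez pool
    alpha22: float = 6.63e9
    beta21: float = 6.32e-7
    beta22: float = 4.90e-8
    k8: float = 4.19e8  # M^-1 s^-1, Bar1 capture of alpha-factor
    k9: float = 4.35e-6  # s^-1, Bar1 recycle
    k10: float = 3.38e4  # s^-1, Bar1/alpha-factor degradation
    kcon1: float = 0.0  # s^-1, constitutive receptor activation
    kcon2: float = 0.0
    prealpha_tot: float = 4.66e-8  # M
    preGFP_tot: float = 1.52e-8  # M
    Bar1_tot: float = 1.68e-10  # M

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def replace(self, **changes) -> "TwoCellRateSet":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TwoCellState:
    """Concentrations (M) of the 23 species."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(TWOCELL_SPECIES),):
            raise ValueError(f"expected {len(TWOCELL_SPECIES)} species")
        object.__setattr__(self, "values", v)

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[_IDX[name]])
        except KeyError:
            raise AttributeError(name) from None

    def as_array(self) -> np.ndarray:
        return self.values.copy()


@dataclass(frozen=True)
class SensorVariant:
    """A sensor configuration: which product is seeded, and Bar1 presence.

    The three canonical variants carry the fitted constitutive product
    concentrations: ``single_sensor`` (3.1 nM, amplifier-only readout),
    ``digital_noBar1`` (10.4 nM GFP) and ``digital_withBar1`` (4.4 nM GFP).
    """

    name: str
    initial_product: float  # M, seeded into the variant's product species
    include_bar1: bool
    readout: str = "GFP"

    _CANONICAL = {
        "single_sensor": (3.1e-9, False, "alphafactor"),
        "digital_noBar1": (10.4e-9, False, "GFP"),
        "digital_withBar1": (4.4e-9, True, "GFP"),
    }

    def __post_init__(self) -> None:
        if self.initial_product < 0:
            raise ValueError("initial_product must be >= 0")
        if self.readout not in ("GFP", "alphafactor"):
            raise ValueError("readout must be 'GFP' or 'alphafactor'")
        canon = self._CANONICAL.get(self.name)
        if canon is not None and (
            not math.isclose(self.initial_product, canon[0], rel_tol=1e-12)
            or self.include_bar1 != canon[1]
        ):
            raise ValueError(
                f"variant {self.name!r} must carry initial_product={canon[0]} "
                f"and include_bar1={canon[1]}"
            )

    @classmethod
    def named(cls, name: str) -> "SensorVariant":
        try:
            seed, bar1, readout = cls._CANONICAL[name]
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; known: {sorted(cls._CANONICAL)}"
            ) from None
        return cls(name=name, initial_product=seed, include_bar1=bar1, readout=readout)


@dataclass(frozen=True)
class Bar1SweepResult:
    """Per-factor 4PL metrics from scaling the Bar1 pool."""

    factors: np.ndarray
    curves: list  # list[ResponseCurve]
    metrics: list  # list[CurveMetrics]
    summary: pd.DataFrame  # factor, basal, emax, hill_slope


@dataclass(frozen=True)
class TwoCellFit:
    """Result of a multi-start subset fit of the two-cell model."""

    estimates: dict  # name -> fitted value
    rates: TwoCellRateSet  # full rate set with estimates substituted
    residual_report: ResidualSet
    cost: float
    n_starts: int
    start_costs: np.ndarray  # best cost reached from each start


def default_twocell_rates(**overrides) -> TwoCellRateSet:
    """The tabulated double-cell parameter set (kcon1 = kcon2 = 0)."""
    return TwoCellRateSet(**overrides)


def initial_twocell_state(
    rates: TwoCellRateSet, variant: SensorVariant, dose: float
) -> TwoCellState:
    """Assay starting state for a variant at ligand concentration ``dose``.

    Receptor, G protein and effector start at 16 uM; the prez pools start
    full (they are caps, not conserved sums including the seed); the
    variant's constitutive product is seeded on top; Bar1 starts fully
    active when the variant includes it. Amplifier-only runs (readout
    ``"alphafactor"``) start with an empty reporter cell, so the seeded
    alpha-factor is not silently absorbed by the reporter's receptor pool.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    x = np.zeros(len(TWOCELL_SPECIES))
    amplifier_only = variant.readout == "alphafactor"
    cells = ("R1", "Goff1", "Effector1") if amplifier_only else (
        "R1", "Goff1", "Effector1", "R2", "Goff2", "Effector2")
    for s in cells:
        x[_IDX[s]] = INITIAL_CASCADE
    x[_IDX["prealpha"]] = rates.prealpha_tot
    if not amplifier_only:
        x[_IDX["preGFP"]] = rates.preGFP_tot
    product = "alphafactor" if amplifier_only else "GFP"
    x[_IDX[product]] = variant.initial_product
    x[_IDX["Bar1"]] = rates.Bar1_tot if variant.include_bar1 else 0.0
    x[_IDX["L"]] = dose
    return TwoCellState(x)


def _rhs_vec(x: np.ndarray, r: TwoCellRateSet) -> np.ndarray:
    (R1, R1s, Goff1, Gon1, E1, GE1, z11, z21, prea, afac,
     R2, R2s, Goff2, Gon2, E2, GE2, z12, z22, preg, gfp,
     L, bar1, ibar1) = x

    # amplifier cell
    bind1 = r.k11 * L * R1
    unbind1 = r.k71 * R1s
    con1 = r.kcon1 * R1
    gact1 = r.k21 * R1s * Goff1
    gdeact1 = r.k31 * Gon1
    ebind1 = r.k51 * Gon1 * E1
    eunbind1 = r.k61 * GE1
    aprod = r.alpha21 * z21 * prea
    arev = r.beta21 * afac
    # reporter cell
    bind2 = r.k12 * afac * R2
    unbind2 = r.k72 * R2s
    con2 = r.kcon2 * R2
    gact2 = r.k22 * R2s * Goff2
    gdeact2 = r.k32 * Gon2
    ebind2 = r.k52 * Gon2 * E2
    eunbind2 = r.k62 * GE2
    gprod = r.alpha22 * z22 * preg
    grev = r.beta22 * gfp
    # Bar1 thresholding: capture destroys the alpha-factor, enzyme returns
    capture = r.k8 * bar1 * afac
    release = (r.k9 + r.k10) * ibar1

    dx = np.empty(len(TWOCELL_SPECIES))
    dx[_IDX["R1"]] = unbind1 - bind1 - con1
    dx[_IDX["R1star"]] = bind1 - unbind1 - r.k41 * R1s + con1
    dx[_IDX["Goff1"]] = gdeact1 - gact1
    dx[_IDX["Gon1"]] = gact1 + eunbind1 - gdeact1 - ebind1
    dx[_IDX["Effector1"]] = eunbind1 - ebind1
    dx[_IDX["Gon1Effector1"]] = ebind1 - eunbind1
    dx[_IDX["z11"]] = r.alpha1 * GE1 - r.beta1 * z11
    dx[_IDX["z21"]] = r.alpha11 * z11 - r.beta11 * z21
    dx[_IDX["prealpha"]] = arev - aprod
    dx[_IDX["alphafactor"]] = aprod - arev - bind2 + unbind2 - capture
    dx[_IDX["R2"]] = unbind2 - bind2 - con2
    dx[_IDX["R2star"]] = bind2 - unbind2 - r.k42 * R2s + con2
    dx[_IDX["Goff2"]] = gdeact2 - gact2
    dx[_IDX["Gon2"]] = gact2 + eunbind2 - gdeact2 - ebind2
    dx[_IDX["Effector2"]] = eunbind2 - ebind2
    dx[_IDX["Gon2Effector2"]] = ebind2 - eunbind2
    dx[_IDX["z12"]] = r.alpha2 * GE2 - r.beta2 * z12
    dx[_IDX["z22"]] = r.alpha12 * z12 - r.beta12 * z22
    dx[_IDX["preGFP"]] = grev - gprod
    dx[_IDX["GFP"]] = gprod - grev
    dx[_IDX["L"]] = unbind1 - bind1
    dx[_IDX["Bar1"]] = release - capture
    dx[_IDX["InactiveBar1"]] = capture - release
    return dx


def twocell_rhs(state: TwoCellState, rates: TwoCellRateSet) -> TwoCellState:
    """Per-species time derivatives (M/s)."""
    return TwoCellState(_rhs_vec(state.as_array(), rates))


def _integrate_endpoint(
    x0: np.ndarray, rates: TwoCellRateSet, t_end: float,
    rtol: float = 1e-8, atol: float = 1e-18,
) -> np.ndarray:
    sol = solve_ivp(
        lambda t, x: _rhs_vec(x, rates), (0.0, t_end), x0,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol.y[:, -1]


def default_twocell_dose_grid(n: int = 13, lo: float = 1e-12, hi: float = 1e-5) -> np.ndarray:
    """Dose 0 plus ``n`` log-spaced ligand concentrations over [lo, hi] M."""
    return np.concatenate([[0.0], np.logspace(math.log10(lo), math.log10(hi), n)])


def transition_dose_grid(n: int = 17, lo: float = 1e-24, hi: float = 1e-18) -> np.ndarray:
    """Dose 0 plus a grid spanning the response transition of the printed
    parameter set (which sits at sub-femtomolar ligand; the cascade gains put
    the 260-min endpoint at its cap for any dose above ~1e-19 M)."""
    return np.concatenate([[0.0], np.logspace(math.log10(lo), math.log10(hi), n)])


def twocell_dose_response(
    rates: TwoCellRateSet,
    variant: SensorVariant,
    dose_grid: np.ndarray | None = None,
    t_end: float = DEFAULT_T_END,
    label: str = "",
) -> ResponseCurve:
    """Endpoint readout (variant's product species) per dose after ``t_end`` s."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    doses = (default_twocell_dose_grid() if dose_grid is None
             else np.asarray(dose_grid, dtype=float))
    readout_idx = _IDX[variant.readout]
    responses = np.empty(doses.shape)
    for i, dose in enumerate(doses):
        x0 = initial_twocell_state(rates, variant, float(dose)).as_array()
        try:
            x_end = _integrate_endpoint(x0, rates, t_end)
        except RuntimeError as err:
            raise RuntimeError(f"solver failure at dose {dose:g} M: {err}") from err
        responses[i] = x_end[readout_idx]
    return ResponseCurve(doses=doses, responses=responses,
                         label=label or variant.name)


def bar1_sweep(
    rates: TwoCellRateSet | None = None,
    factors: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    dose_grid: np.ndarray | None = None,
    t_end: float = DEFAULT_T_END,
) -> Bar1SweepResult:
    """Dose-response metrics while scaling the reporter's Bar1 pool.

    By default runs with the tabulated rates plus the calibrated constitutive
    receptor activation (:data:`KCON_BASAL`) and no seeded product, so that
    basal output is generated dynamically and Bar1 can act on it; pass your
    own ``rates`` to override. Each swept curve is 4PL-fitted and summarised
    as (basal, emax, hill_slope).
    """
    if rates is None:
        rates = default_twocell_rates(kcon1=KCON_BASAL[0], kcon2=KCON_BASAL[1])
    factors = np.asarray(factors, dtype=float)
    if np.any(factors < 0):
        raise ValueError("Bar1 factors must be >= 0")
    if dose_grid is None:
        dose_grid = transition_dose_grid()
    curves, metrics, rows = [], [], []
    for factor in factors:
        swept = rates.replace(Bar1_tot=rates.Bar1_tot * float(factor))
        variant = SensorVariant(
            name=f"bar1_x{factor:g}", initial_product=0.0,
            include_bar1=factor > 0, readout="GFP",
        )
        curve = twocell_dose_response(swept, variant, dose_grid=dose_grid, t_end=t_end)
        fit, _ = fit_fourpl(curve)
        m = curve_metrics(fit, basal_floor=float(curve.responses[curve.responses > 0].min())
                          if np.any(curve.responses > 0) else 0.0)
        curves.append(curve)
        metrics.append(m)
        rows.append({"factor": float(factor), "basal": float(curve.responses[0]),
                     "emax": m.emax, "hill_slope": m.hill_slope})
    return Bar1SweepResult(
        factors=factors, curves=curves, metrics=metrics, summary=pd.DataFrame(rows)
    )


_FITTABLE = {f.name for f in dataclasses.fields(TwoCellRateSet)}


def fit_twocell_subset(
    dataset,
    free_param_names: Sequence[str],
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    variant: SensorVariant | None = None,
    base_rates: TwoCellRateSet | None = None,
    dose_col: str = "dose_M",
    response_col: str = "endpoint_M",
    t_end: float = DEFAULT_T_END,
) -> TwoCellFit:
    """Multi-start bounded least squares on log10-transformed parameters.

    ``dataset`` is a DataFrame (or mapping) with dose and endpoint columns.
    Each start draws a log-uniform initial point within the bounds (default:
    two decades around the tabulated value) and minimises squared endpoint
    residuals; the best local minimum wins. Reproducible under ``seed``.

    Raises
    ------
    ValueError
        On unknown parameter names or fewer than 2x as many points as free
        parameters.
    RuntimeError
        If no start converges.
    """
    names = list(free_param_names)
    unknown = [n for n in names if n not in _FITTABLE]
    if unknown:
        raise ValueError(
            f"unknown parameter name(s) {unknown}; valid: {sorted(_FITTABLE)}"
        )
    df = pd.DataFrame(dataset)
    doses = df[dose_col].to_numpy(dtype=float)
    observed = df[response_col].to_numpy(dtype=float)
    if doses.size < 2 * len(names):
        raise ValueError(
            f"need >= {2 * len(names)} data points for {len(names)} free parameters"
        )
    base = base_rates if base_rates is not None else default_twocell_rates()
    variant = variant if variant is not None else SensorVariant.named("digital_withBar1")

    log_lo, log_hi = [], []
    for n in names:
        ref = getattr(base, n)
        if ref <= 0:
            raise ValueError(f"cannot log-fit parameter {n} with base value {ref}")
        b = (bounds or {}).get(n, (ref / 100.0, ref * 100.0))
        log_lo.append(math.log10(b[0]))
        log_hi.append(math.log10(b[1]))
    log_lo, log_hi = np.array(log_lo), np.array(log_hi)

    def predict(theta: np.ndarray) -> np.ndarray:
        rates = base.replace(**{n: 10.0**v for n, v in zip(names, theta)})
        out = np.empty(doses.shape)
        for i, dose in enumerate(doses):
            x0 = initial_twocell_state(rates, variant, float(dose)).as_array()
            out[i] = _integrate_endpoint(x0, rates, t_end)[_IDX[variant.readout]]
        return out

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - observed

    rng = np.random.default_rng(seed)
    best = None
    start_costs = []
    for k in range(n_starts):
        theta0 = rng.uniform(log_lo, log_hi)
        try:
            res = least_squares(
                resid, theta0, bounds=(log_lo, log_hi),
                xtol=3e-16, ftol=3e-16, gtol=None,
                diff_step=1e-3, max_nfev=300,
            )
        except RuntimeError:
            continue
        start_costs.append(res.cost)
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"no optimization start converged ({n_starts} starts, seed {seed})"
        )
    estimates = {n: float(10.0**v) for n, v in zip(names, best.x)}
    fitted_rates = base.replace(**estimates)
    report = r_squared(observed, predict(best.x))
    return TwoCellFit(
        estimates=estimates,
        rates=fitted_rates,
        residual_report=report,
        cost=float(best.cost),
        n_starts=n_starts,
        start_costs=np.asarray(start_costs),
    )
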