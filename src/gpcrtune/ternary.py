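"""Cubic ternary complex model of a minimized yeast pheromone pathway.

The receptor Ste2 is modelled on three independent axes — ligand occupancy
(alpha-factor, L), conformational activation (R vs R*), and heterotrimeric
G-protein coupling — giving the eight receptor states of a cube:

    R, LR, R*, LR*, RG, LRG, R*G, LR*G

Cooperativity factors couple the axes: nu (ligand binding when G-bound),
zeta (activation when ligand-bound), mu (G binding when active). Active,
G-coupled receptor catalyses G-protein activation (kGTP+), releasing
Galpha-GTP and an activated free Gbetagamma dimer (bg*), which is the
pathway's signal carrier. The downstream scaffold Ste5 binds bg* into the
output complex bg*STE5 — the model readout — and also binds inactive bg,
which at high Gbetagamma levels sequesters Ste5 and caps the response.
Constitutive routes (receptor-independent G dissociation kGRA-, basal
bg -> bg* conversion kconact) set the basal signal.

Sixteen species in all; four exact conservation laws (receptor, Galpha,
Gbetagamma, Ste5) hold along every trajectory and are used throughout the
test suite as the arbiter of correctness of the derivative terms.

Rates are in s^-1 / M^-1 s^-1 and concentrations in M; "time" below is
therefore seconds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._steady import refine_steady_state
from .curves import ResponseCurve

__all__ = [
    "TernaryRateSet",
    "TernaryTotals",
    "TernaryState",
    "EquilibrationResult",
    "SweepResult",
    "SPECIES",
    "default_ternary_rates",
    "initial_ternary_state",
    "ternary_rhs",
    "equilibrate",
    "ternary_dose_response",
    "sweep_component",
    "default_dose_grid",
    "default_sweep_factors",
]

#: Canonical state-vector ordering of the 16 species.
SPECIES = (
    "R", "LR", "Rstar", "LRstar", "RG", "LRG", "RstarG", "LRstarG",
    "G", "aGDP", "aGTP", "bg", "bgStar", "STE5", "bgStarSTE5", "bgSTE5",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: Conservation groups: (label, member indices). Each sum is invariant.
CONSERVATION_GROUPS = (
    ("receptor", tuple(_IDX[s] for s in SPECIES[:8])),
    ("Galpha", tuple(_IDX[s] for s in ("RG", "LRG", "RstarG", "LRstarG", "G", "aGDP", "aGTP"))),
    ("Gbetagamma", tuple(_IDX[s] for s in ("RG", "LRG", "RstarG", "LRstarG", "G", "bg", "bgStar", "bgStarSTE5", "bgSTE5"))),
    ("Ste5", tuple(_IDX[s] for s in ("STE5", "bgStarSTE5", "bgSTE5"))),
)

# rows replaced by conservation residuals during steady-state refinement
_CONS_ROWS = (_IDX["R"], _IDX["aGDP"], _IDX["bg"], _IDX["STE5"])

DEFAULT_T_END = 1000.0  # s; endpoint readout time
EQUILIBRATION_HORIZON = 1e8  # s
DEFAULT_ABS_TOL = 1e-24  # M/s; steady-state criterion on max |dX/dt|
RTOL = 1e-10
ATOL = 1e-22  # M; concentrations are ~1e-10 M


@dataclass(frozen=True)
class TernaryRateSet:
    """Rate constants of the cubic ternary complex network.

    Bimolecular constants in M^-1 s^-1, unimolecular in s^-1; the nu/zeta/mu
    pairs are dimensionless cooperativity factors (> 0).
    """

    kL_plus: float = 4e7
    kL_minus: float = 0.31
    kact_plus: float = 1.0
    kact_minus: float = 1e3
    kG_plus: float = 1e8
    kG_minus: float = 0.1
    kGRA_plus: float = 7e8
    kGRA_minus: float = 1.3e-3
    khyd_plus: float = 1e-4
    khyd_minus: float = 1e-4
    kGTP_plus: float = 1e-2
    nu_plus: float = 1.0
    nu_minus: float = 1.0
    zeta_plus: float = 1e3
    zeta_minus: float = 1.0
    mu_plus: float = 1.0
    mu_minus: float = 1.0
    kconact: float = 1e-10
    krev: float = 1e-10
    kE1_plus: float = 1e3
    kE1_minus: float = 1.0
    kE2_plus: float = 1e9
    kE2_minus: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("nu_plus", "nu_minus", "zeta_plus", "zeta_minus", "mu_plus", "mu_minus"):
                if not v > 0:
                    raise ValueError(f"cooperativity factor {f.name} must be > 0")
            elif v < 0:
                raise ValueError(f"rate {f.name} must be >= 0")

    def replace(self, **changes) -> "TernaryRateSet":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TernaryTotals:
    """Total component concentrations (M) and the held-constant ligand level.

    Gbg_tot and Ste5_tot are independent knobs so the Gbetagamma arm can be
    swept while receptor and Galpha stay fixed.
    """

    R_tot: float = 4.15e-10
    Ga_tot: float = 4.15e-10
    Gbg_tot: float = 4.15e-10
    Ste5_tot: float = 4.15e-10
    L: float = 1e-4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def replace(self, **changes) -> "TernaryTotals":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TernaryState:
    """Concentrations (M) of the 16 species."""

    R: float = 0.0
    LR: float = 0.0
    Rstar: float = 0.0
    LRstar: float = 0.0
    RG: float = 0.0
    LRG: float = 0.0
    RstarG: float = 0.0
    LRstarG: float = 0.0
    G: float = 0.0
    aGDP: float = 0.0
    aGTP: float = 0.0
    bg: float = 0.0
    bgStar: float = 0.0
    STE5: float = 0.0
    bgStarSTE5: float = 0.0
    bgSTE5: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TernaryState":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(SPECIES),):
            raise ValueError(f"expected {len(SPECIES)} species, got {x.shape}")
        return cls(**{s: float(v) for s, v in zip(SPECIES, x)})


@dataclass(frozen=True)
class EquilibrationResult:
    """Basal (zero-ligand) steady state plus convergence diagnostics."""

    state: TernaryState
    converged: bool
    max_rate: float  # max |dX/dt| at the returned state, M/s
    t_elapsed: float  # model seconds integrated before convergence


@dataclass(frozen=True)
class SweepResult:
    """One component sweep: response curves and per-factor summary table."""

    component: str
    factors: np.ndarray
    curves: list  # list[ResponseCurve], one per factor
    summary: pd.DataFrame  # columns: factor, basal, emax, fold_change


def default_ternary_rates() -> tuple[TernaryRateSet, TernaryTotals]:
    """The tabulated base parameter set of the promoter-library simulations.

    Totals default to R_tot = Ga_tot = Gbg_tot = Ste5_tot = 4.15e-10 M
    (Ste5_tot is not tabulated; equal molarity is this package's default).
    """
    return TernaryRateSet(), TernaryTotals()


def initial_ternary_state(totals: TernaryTotals) -> TernaryState:
    """Pre-equilibration partition of the totals.

    All receptor mass starts free and inactive; Galpha and Gbetagamma pair
    into heterotrimer G up to the smaller total, with any excess left as free
    aGDP or free inactive bg; Ste5 starts unbound. Conservation sums equal
    the totals exactly.
    """
    g = min(totals.Ga_tot, totals.Gbg_tot)
    return TernaryState(
        R=totals.R_tot,
        G=g,
        aGDP=totals.Ga_tot - g,
        bg=totals.Gbg_tot - g,
        STE5=totals.Ste5_tot,
    )


def _rhs_vec(x: np.ndarray, r: TernaryRateSet, L: float) -> np.ndarray:
    """Mass-action derivatives, built reaction-by-reaction in flux form.

    Writing each reaction flux once and distributing it with +/- signs makes
    every conservation sum cancel exactly in floating point, which is what
    lets linear-multistep integrators hold the conservation laws to solver
    tolerance over 1e8-second horizons.
    """
    (R, LR, Rs, LRs, RG, LRG, RsG, LRsG,
     G, aGDP, aGTP, bg, bgS, S5, bgS_S5, bg_S5) = x

    # receptor cube edges: ligand binding
    f_L_R = r.kL_plus * L * R - r.kL_minus * LR
    f_L_Rs = r.zeta_plus * r.kL_plus * L * Rs - r.zeta_minus * r.kL_minus * LRs
    f_L_RG = r.nu_plus * r.kL_plus * L * RG - r.nu_minus * r.kL_minus * LRG
    f_L_RsG = (r.zeta_plus * r.nu_plus * r.kL_plus * L * RsG
               - r.zeta_minus * r.nu_minus * r.kL_minus * LRsG)
    # activation
    f_act_R = r.kact_plus * R - r.kact_minus * Rs
    f_act_LR = r.zeta_plus * r.kact_plus * LR - r.zeta_minus * r.kact_minus * LRs
    f_act_RG = r.mu_plus * r.kact_plus * RG - r.mu_minus * r.kact_minus * RsG
    f_act_LRG = (r.mu_plus * r.zeta_plus * r.kact_plus * LRG
                 - r.mu_minus * r.zeta_minus * r.kact_minus * LRsG)
    # G-protein coupling
    f_G_R = r.kG_plus * R * G - r.kG_minus * RG
    f_G_LR = r.nu_plus * r.kG_plus * LR * G - r.nu_minus * r.kG_minus * LRG
    f_G_Rs = r.mu_plus * r.kG_plus * Rs * G - r.mu_minus * r.kG_minus * RsG
    f_G_LRs = (r.mu_plus * r.nu_plus * r.kG_plus * LRs * G
               - r.mu_minus * r.nu_minus * r.kG_minus * LRsG)
    # receptor-catalysed G activation: R*G -> R* + aGTP + bg*
    f_gtp_Rs = r.kGTP_plus * RsG
    f_gtp_LRs = r.nu_minus * r.kGTP_plus * LRsG
    # spontaneous heterotrimer dissociation and re-association
    f_gra = r.kGRA_minus * G                      # G -> aGDP + bg*
    f_reassoc_bg = r.kGRA_plus * aGDP * bg        # aGDP + bg  -> G
    f_reassoc_bgS = r.kGRA_plus * aGDP * bgS      # aGDP + bg* -> G
    # nucleotide cycle on free Galpha
    f_hyd = r.khyd_plus * aGTP                    # aGTP -> aGDP
    f_exch = r.khyd_minus * aGDP                  # aGDP -> aGTP
    # constitutive bg activation
    f_con = r.kconact * bg - r.krev * bgS
    # Ste5 scaffolding (active and inactive dimer compete for Ste5)
    f_E1 = r.kE1_plus * S5 * bgS - r.kE1_minus * bgS_S5
    f_E2 = r.kE2_plus * S5 * bg - r.kE2_minus * bg_S5

    dx = np.empty(16)
    dx[0] = -f_L_R - f_act_R - f_G_R                          # R
    dx[1] = f_L_R - f_act_LR - f_G_LR                         # LR
    dx[2] = -f_L_Rs + f_act_R - f_G_Rs + f_gtp_Rs             # R*
    dx[3] = f_L_Rs + f_act_LR - f_G_LRs + f_gtp_LRs           # LR*
    dx[4] = -f_L_RG - f_act_RG + f_G_R                        # RG
    dx[5] = f_L_RG - f_act_LRG + f_G_LR                       # LRG
    dx[6] = -f_L_RsG + f_act_RG + f_G_Rs - f_gtp_Rs           # R*G
    dx[7] = f_L_RsG + f_act_LRG + f_G_LRs - f_gtp_LRs         # LR*G
    dx[8] = -f_G_R - f_G_LR - f_G_Rs - f_G_LRs - f_gra + f_reassoc_bg + f_reassoc_bgS  # G
    dx[9] = f_gra - f_reassoc_bg - f_reassoc_bgS + f_hyd - f_exch                      # aGDP
    dx[10] = f_gtp_Rs + f_gtp_LRs - f_hyd + f_exch            # aGTP
    dx[11] = -f_reassoc_bg - f_con - f_E2                     # bg
    dx[12] = f_gtp_Rs + f_gtp_LRs + f_gra - f_reassoc_bgS + f_con - f_E1  # bg*
    dx[13] = -f_E1 - f_E2                                     # STE5
    dx[14] = f_E1                                             # bg*STE5
    dx[15] = f_E2                                             # bgSTE5
    return dx


def ternary_rhs(state: TernaryState, rates: TernaryRateSet, L: float) -> TernaryState:
    """Per-species time derivatives (M/s) at ``state`` with ligand held at L."""
    return TernaryState.from_array(_rhs_vec(state.as_array(), rates, L))


def _integrate(x0, rates, L, t_end, rtol=RTOL, atol=ATOL) -> np.ndarray:
    sol = solve_ivp(
        lambda t, x: _rhs_vec(x, rates, L),
        (0.0, t_end),
        x0,
        method="BDF",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed (t_end={t_end}): {sol.message}")
    return sol.y[:, -1]


def equilibrate(
    rates: TernaryRateSet,
    totals: TernaryTotals,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> EquilibrationResult:
    """Zero-ligand basal state of the network.

    Integrates from :func:`initial_ternary_state` with L = 0 over log-spaced
    stages up to a 1e8 s horizon, stopping early once max |dX/dt| < abs_tol,
    then polishes with a conservation-pinned Newton refinement. If neither
    reaches ``abs_tol`` the result carries ``converged=False`` (no exception).
    """
    x = initial_ternary_state(totals).as_array()
    rhs = lambda x_: _rhs_vec(x_, rates, 0.0)  # noqa: E731
    t_done = 0.0
    if float(np.max(np.abs(rhs(x)))) >= abs_tol:
        for t_stage in (1e2, 1e4, 1e6, EQUILIBRATION_HORIZON):
            x = _integrate(x, rates, 0.0, t_stage - t_done)
            t_done = t_stage
            if float(np.max(np.abs(rhs(x)))) < abs_tol:
                break
    max_rate = float(np.max(np.abs(rhs(x))))
    if max_rate >= abs_tol:
        cons = tuple(zip(_CONS_ROWS, (g for _, g in CONSERVATION_GROUPS)))
        x = refine_steady_state(rhs, x, cons)
        max_rate = float(np.max(np.abs(rhs(x))))
    x = np.clip(x, 0.0, None)
    return EquilibrationResult(
        state=TernaryState.from_array(x),
        converged=max_rate < abs_tol,
        max_rate=max_rate,
        t_elapsed=t_done,
    )


def default_dose_grid(n: int = 25, lo: float = 1e-12, hi: float = 1e-4) -> np.ndarray:
    """Dose 0 plus ``n`` log-spaced ligand concentrations over [lo, hi] M."""
    return np.concatenate([[0.0], np.logspace(math.log10(lo), math.log10(hi), n)])


def ternary_dose_response(
    rates: TernaryRateSet,
    totals: TernaryTotals,
    dose_grid: np.ndarray | None = None,
    t_end: float = DEFAULT_T_END,
    label: str = "",
    basal: EquilibrationResult | None = None,
) -> ResponseCurve:
    """Endpoint dose-response of the readout complex bg*STE5.

    Every dose starts from the same equilibrated zero-ligand state, holds the
    ligand constant, integrates ``t_end`` seconds and reports the endpoint
    [bg*STE5]. Dose 0 reports the equilibrated basal readout itself. A
    precomputed ``basal`` equilibration may be passed to amortise sweeps.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    doses = default_dose_grid() if dose_grid is None else np.asarray(dose_grid, dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise ValueError("dose_grid must be sorted strictly ascending")
    eq = equilibrate(rates, totals) if basal is None else basal
    x0 = eq.state.as_array()
    responses = np.empty(doses.shape)
    for i, dose in enumerate(doses):
        if dose == 0.0:
            responses[i] = x0[_IDX["bgStarSTE5"]]
            continue
        try:
            x_end = _integrate(x0, rates, float(dose), t_end)
        except RuntimeError as err:
            raise RuntimeError(f"solver failure at dose {dose:g} M: {err}") from err
        responses[i] = x_end[_IDX["bgStarSTE5"]]
    return ResponseCurve(doses=doses, responses=responses, label=label)


def default_sweep_factors(n: int = 9, lo: float = 0.03, hi: float = 30.0) -> np.ndarray:
    """Log-spaced abundance multipliers bracketing the base parameter set."""
    return np.logspace(math.log10(lo), math.log10(hi), n)


def sweep_component(
    rates: TernaryRateSet,
    totals: TernaryTotals,
    component: str,
    factors: np.ndarray | None = None,
    dose_grid: np.ndarray | None = None,
    t_end: float = DEFAULT_T_END,
) -> SweepResult:
    """Promoter-library sweep: scale one total, re-run the dose-response.

    ``component`` is one of ``"R_tot"``, ``"Ga_tot"``, ``"Gbg_tot"``; the
    other totals stay fixed. The per-factor summary reports basal (dose-0
    readout), Emax (max response over the grid) and fold_change = Emax/basal.
    """
    if component not in ("R_tot", "Ga_tot", "Gbg_tot"):
        raise ValueError(
            f"unknown component {component!r}; expected R_tot, Ga_tot or Gbg_tot"
        )
    factors = default_sweep_factors() if factors is None else np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("sweep factors must be > 0")
    curves, rows = [], []
    for factor in factors:
        swept = totals.replace(**{component: getattr(totals, component) * float(factor)})
        curve = ternary_dose_response(
            rates, swept, dose_grid=dose_grid, t_end=t_end,
            label=f"{component} x{factor:g}",
        )
        basal = curve.responses[curve.doses == 0.0]
        basal = float(basal[0]) if basal.size else float(curve.responses[0])
        emax = float(curve.responses.max())
        rows.append(
            {"factor": float(factor), "basal": basal, "emax": emax,
             "fold_change": emax / basal if basal > 0 else math.inf}
        )
        curves.append(curve)
    return SweepResult(
        component=component,
        factors=factors,
        curves=curves,
        summary=pd.DataFrame(rows),
    )
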