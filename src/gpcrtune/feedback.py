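"""Ste2/Gpa1 positive transcriptional feedback variant of the ternary model.

Native pheromone signaling upregulates its own receptor (Ste2) and Galpha
(Gpa1) through the pheromone-responsive transcription factor. This module
extends the receptor/G-protein cube with the open-system processes that
matter on the transcriptional timescale — receptor synthesis (kRsyn) and
internalization (kRint), G-protein synthesis (kGsyn) and degradation
(kGdeg) — and a two-step delay chain standing in for the MAPK cascade and
gene expression: free Gbetagamma activates X1, active X1 activates X2, and
active X2 drives feedback production of pathway components at the five
``*fdbk`` rates. The pathway readout is free [Gbetagamma].

The network keeps the 8 receptor cube states but reduces the free G-protein
side to G, aGDP, aGTP and a single (undifferentiated) free dimer bg; with
the X chain that is 16 species. X1 + X1* and X2 + X2* are exactly conserved
(activation is pure interconversion); receptor and G-protein mass are open
unless synthesis, degradation, internalization and feedback are all zero, in
which case the ternary conservation laws reappear.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._steady import integrate_to, refine_steady_state

__all__ = [
    "FeedbackRateSet",
    "FeedbackState",
    "FeedbackSimulation",
    "FEEDBACK_SPECIES",
    "default_feedback_rates",
    "feedback_rhs",
    "initial_feedback_state",
    "equilibrate_feedback",
    "simulate_feedback",
]

logger = logging.getLogger(__name__)

FEEDBACK_SPECIES = (
    "R", "LR", "Rstar", "LRstar", "RG", "LRG", "RstarG", "LRstarG",
    "G", "aGDP", "aGTP", "bg", "X1", "X1star", "X2", "X2star",
)
_IDX = {name: i for i, name in enumerate(FEEDBACK_SPECIES)}

#: Default feedback-production strength for Galpha (M/s per unit [X2*]/M).
#: Calibrated once so that saturating ligand roughly doubles total receptor
#: mass at steady state relative to the no-feedback system (the Ste2 rate is
#: one order of magnitude above this, matching the reported feedback ratio).
DEFAULT_FEEDBACK_STRENGTH_G = 1.8e-7


@dataclass(frozen=True)
class FeedbackRateSet:
    """Feedback-model rate constants.

    The receptor-cube constants reuse the ternary symbols but carry the
    feedback table's values (note kL_plus, khyd_plus and kGTP_plus differ
    from the base ternary set). kRGS/kRGSsyn/kRGSdeg are tabulated but no
    RGS species exists in this network; they are stored and ignored.

    kX1_plus/kX2_plus are applied bimolecularly (M^-1 s^-1): the tabulated
    per-second activation rates are divided by X1_init/X2_init so the printed
    delay-chain equations keep their form with closed units.

    The five ``*fdbk`` production rates (M/s per unit active-X2 fraction,
    i.e. applied as rate * [X2*]) are not tabulated; kGfdbk and kRfdbk
    default via :func:`default_feedback_rates`, the rest to 0.
    """

    kL_plus: float = 9.4e4
    kL_minus: float = 0.31
    kact_plus: float = 1.0
    kact_minus: float = 1e3
    kG_plus: float = 1e8
    kG_minus: float = 0.1
    kGRA_plus: float = 7e8
    kGRA_minus: float = 1.3e-3
    khyd_plus: float = 1e-1
    khyd_minus: float = 1e-4
    kGTP_plus: float = 1.0
    nu_plus: float = 1.0
    nu_minus: float = 1.0
    zeta_plus: float = 1e3
    zeta_minus: float = 1.0
    mu_plus: float = 1.0
    mu_minus: float = 1.0
    # synthesis / turnover
    kRsyn: float = 1.2e-14  # M/s
    kRint: float = 2.9e-4  # 1/s
    kGsyn: float = 9.55e-14  # M/s
    kGdeg: float = 2.3e-4  # 1/s
    # tabulated but unused (no RGS species in this network)
    kRGS: float = 4.0e5
    kRGSsyn: float = 3.3e-11
    kRGSdeg: float = 3.0e-4
    # delay chain
    kX1_plus: float = 2.0e-3 / 1.0e-7  # M^-1 s^-1; tabulated 2e-3 / X1_init
    kX1_minus: float = 2.0e-4
    kX2_plus: float = 2.0e-3 / 1.0e-7  # M^-1 s^-1; tabulated 2e-3 / X2_init
    kX2_minus: float = 2.0e-4
    # feedback production (per unit [X2*])
    kRfdbk: float = 0.0
    kGfdbk: float = 0.0
    kaGDPfdbk: float = 0.0
    kaGTPfdbk: float = 0.0
    kbgfdbk: float = 0.0
    # totals / initial pools
    R_tot: float = 4.15e-10  # M
    G_tot: float = 9.55e-14 / 2.3e-4  # M; synthesis/degradation balance
    X1_init: float = 1.0e-7  # M
    X2_init: float = 1.0e-7  # M
    L_tot: float = 1e-4  # M; tabulated saturating ligand

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def replace(self, **changes) -> "FeedbackRateSet":
        return dataclasses.replace(self, **changes)

    def without_feedback(self) -> "FeedbackRateSet":
        return self.replace(
            kRfdbk=0.0, kGfdbk=0.0, kaGDPfdbk=0.0, kaGTPfdbk=0.0, kbgfdbk=0.0
        )


@dataclass(frozen=True)
class FeedbackState:
    """Concentrations (M) of the 16 feedback-model species."""

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
    X1: float = 0.0
    X1star: float = 0.0
    X2: float = 0.0
    X2star: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in FEEDBACK_SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "FeedbackState":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(FEEDBACK_SPECIES),):
            raise ValueError(f"expected {len(FEEDBACK_SPECIES)} species")
        return cls(**{s: float(v) for s, v in zip(FEEDBACK_SPECIES, x)})


@dataclass(frozen=True)
class FeedbackSimulation:
    """Trajectory and endpoint of one feedback-model run."""

    times: np.ndarray
    states: np.ndarray  # (len(FEEDBACK_SPECIES), n_times)
    endpoint: FeedbackState
    readout: float  # endpoint free [bg], M
    receptor_mass: float  # endpoint total receptor (all 8 cube states), M


def default_feedback_rates(
    feedback_strength_G: float = DEFAULT_FEEDBACK_STRENGTH_G,
    ratio_R_over_G: float = 10.0,
) -> FeedbackRateSet:
    """Tabulated feedback parameter set with the feedback strengths filled in.

    ``kGfdbk = feedback_strength_G`` and ``kRfdbk = ratio_R_over_G *
    feedback_strength_G`` (Ste2 feedback one order of magnitude above Gpa1 by
    default); the aGDP/aGTP/bg production rates stay 0 unless overridden.
    """
    if feedback_strength_G < 0:
        raise ValueError("feedback_strength_G must be >= 0")
    rates = FeedbackRateSet(
        kGfdbk=feedback_strength_G,
        kRfdbk=ratio_R_over_G * feedback_strength_G,
    )
    if rates.kRGS or rates.kRGSsyn or rates.kRGSdeg:
        logger.warning(
            "kRGS/kRGSsyn/kRGSdeg are tabulated but unused: "
            "no RGS species exists in this network"
        )
    return rates


def _rhs_vec(x: np.ndarray, r: FeedbackRateSet, L: float) -> np.ndarray:
    (R, LR, Rs, LRs, RG, LRG, RsG, LRsG,
     G, aGDP, aGTP, bg, X1, X1s, X2, X2s) = x

    # receptor cube (identical structure to the ternary model)
    f_L_R = r.kL_plus * L * R - r.kL_minus * LR
    f_L_Rs = r.zeta_plus * r.kL_plus * L * Rs - r.zeta_minus * r.kL_minus * LRs
    f_L_RG = r.nu_plus * r.kL_plus * L * RG - r.nu_minus * r.kL_minus * LRG
    f_L_RsG = (r.zeta_plus * r.nu_plus * r.kL_plus * L * RsG
               - r.zeta_minus * r.nu_minus * r.kL_minus * LRsG)
    f_act_R = r.kact_plus * R - r.kact_minus * Rs
    f_act_LR = r.zeta_plus * r.kact_plus * LR - r.zeta_minus * r.kact_minus * LRs
    f_act_RG = r.mu_plus * r.kact_plus * RG - r.mu_minus * r.kact_minus * RsG
    f_act_LRG = (r.mu_plus * r.zeta_plus * r.kact_plus * LRG
                 - r.mu_minus * r.zeta_minus * r.kact_minus * LRsG)
    f_G_R = r.kG_plus * R * G - r.kG_minus * RG
    f_G_LR = r.nu_plus * r.kG_plus * LR * G - r.nu_minus * r.kG_minus * LRG
    f_G_Rs = r.mu_plus * r.kG_plus * Rs * G - r.mu_minus * r.kG_minus * RsG
    f_G_LRs = (r.mu_plus * r.nu_plus * r.kG_plus * LRs * G
               - r.mu_minus * r.nu_minus * r.kG_minus * LRsG)
    f_gtp_Rs = r.kGTP_plus * RsG
    f_gtp_LRs = r.nu_minus * r.kGTP_plus * LRsG
    # reduced G cycle: dissociation and re-association act on the single bg pool
    f_gra = r.kGRA_minus * G
    f_reassoc = r.kGRA_plus * aGDP * bg
    f_hyd = r.khyd_plus * aGTP
    f_exch = r.khyd_minus * aGDP
    # delay chain; X2 activation is driven by X1* (consistent cascade)
    f_x1 = r.kX1_plus * bg * X1 - r.kX1_minus * X1s
    f_x2 = r.kX2_plus * X1s * X2 - r.kX2_minus * X2s

    dx = np.empty(16)
    dx[0] = (-f_L_R - f_act_R - f_G_R
             + r.kRsyn - r.kRint * R + r.kGdeg * (RG + RsG) + r.kRfdbk * X2s)
    dx[1] = f_L_R - f_act_LR - f_G_LR - r.kRint * LR + r.kGdeg * LRG
    dx[2] = -f_L_Rs + f_act_R - f_G_Rs + f_gtp_Rs - r.kRint * Rs
    dx[3] = f_L_Rs + f_act_LR - f_G_LRs + f_gtp_LRs - r.kRint * LRs + r.kGdeg * LRsG
    dx[4] = -f_L_RG - f_act_RG + f_G_R - r.kRint * RG - r.kGdeg * RG
    dx[5] = f_L_RG - f_act_LRG + f_G_LR - r.kRint * LRG - r.kGdeg * LRG
    dx[6] = -f_L_RsG + f_act_RG + f_G_Rs - f_gtp_Rs - r.kRint * RsG - r.kGdeg * RsG
    dx[7] = f_L_RsG + f_act_LRG + f_G_LRs - f_gtp_LRs - r.kRint * LRsG - r.kGdeg * LRsG
    dx[8] = (-f_G_R - f_G_LR - f_G_Rs - f_G_LRs - f_gra + f_reassoc
             + r.kGsyn - r.kGdeg * G + r.kRint * (RG + RsG + LRG + LRsG)
             + r.kGfdbk * X2s)
    dx[9] = (f_gra - f_reassoc + f_hyd - f_exch
             + r.kaGDPfdbk * X2s - r.kGdeg * aGDP)
    dx[10] = (f_gtp_Rs + f_gtp_LRs - f_hyd + f_exch
              + r.kaGTPfdbk * X2s - r.kGdeg * aGTP)
    dx[11] = (f_gra + f_gtp_Rs + f_gtp_LRs - f_reassoc
              + r.kbgfdbk * X2s - r.kGdeg * bg)
    dx[12] = -f_x1  # X1
    dx[13] = f_x1  # X1*
    dx[14] = -f_x2  # X2
    dx[15] = f_x2  # X2*
    return dx


def feedback_rhs(state: FeedbackState, rates: FeedbackRateSet, L: float) -> FeedbackState:
    """Per-species time derivatives (M/s) with ligand held constant at L."""
    return FeedbackState.from_array(_rhs_vec(state.as_array(), rates, L))


def initial_feedback_state(rates: FeedbackRateSet) -> FeedbackState:
    """All receptor free and inactive, all G as heterotrimer, X chains inactive."""
    return FeedbackState(
        R=rates.R_tot, G=rates.G_tot, X1=rates.X1_init, X2=rates.X2_init
    )


_X_CONSERVATION = (
    (_IDX["X1"], (_IDX["X1"], _IDX["X1star"])),
    (_IDX["X2"], (_IDX["X2"], _IDX["X2star"])),
)


def equilibrate_feedback(
    rates: FeedbackRateSet, abs_tol: float = 1e-24, horizon: float = 1e8
) -> FeedbackState:
    """Zero-ligand steady state (synthesis balanced against turnover)."""
    x = initial_feedback_state(rates).as_array()
    rhs = lambda x_: _rhs_vec(x_, rates, 0.0)  # noqa: E731
    x = integrate_to(rhs, x, horizon, rtol=1e-10, atol=1e-22)
    if float(np.max(np.abs(rhs(x)))) >= abs_tol:
        x = refine_steady_state(rhs, x, _X_CONSERVATION)
    return FeedbackState.from_array(np.clip(x, 0.0, None))


def simulate_feedback(
    rates: FeedbackRateSet,
    L: float,
    t_end: float = 1000.0,
    with_feedback: bool = True,
    n_samples: int = 50,
) -> FeedbackSimulation:
    """Ligand response of the (optionally feedback-free) system.

    Equilibrates at L = 0, then holds the ligand at ``L`` for ``t_end``
    seconds; the readout is endpoint free [Gbetagamma]. ``with_feedback=False``
    zeroes the five feedback production rates for a like-for-like comparison.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    run_rates = rates if with_feedback else rates.without_feedback()
    x0 = equilibrate_feedback(run_rates).as_array()
    rhs = lambda t, x: _rhs_vec(x, run_rates, L)  # noqa: E731
    times = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), x0, method="BDF",
                    rtol=1e-10, atol=1e-22, t_eval=times)
    if not sol.success:
        raise RuntimeError(f"feedback simulation failed: {sol.message}")
    end = sol.y[:, -1]
    return FeedbackSimulation(
        times=sol.t,
        states=sol.y,
        endpoint=FeedbackState.from_array(end),
        readout=float(end[_IDX["bg"]]),
        receptor_mass=float(end[:8].sum()),
    )
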