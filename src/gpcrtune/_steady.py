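"""Steady-state refinement shared by the ODE models.

Integrating a stiff mass-action network to its basal state leaves a residual
drift set by the slowest rate constants; a damped Newton polish on the
right-hand side removes it. Because mass-action networks carry linear
conservation laws, the raw Jacobian of the rhs is singular: for each
conservation group one rhs row is replaced by the conservation residual,
pinning the solution to the totals of the starting point.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root


def integrate_to(
    rhs: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    t_end: float,
    rtol: float = 1e-10,
    atol: float = 1e-22,
) -> np.ndarray:
    """Endpoint of a stiff (BDF) integration of an autonomous rhs."""
    sol = solve_ivp(
        lambda t, x: rhs(x), (0.0, t_end), np.asarray(x0, dtype=float),
        method="BDF", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed (t_end={t_end}): {sol.message}")
    return sol.y[:, -1]


def refine_steady_state(
    rhs: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    conservation: Sequence[tuple[int, Sequence[int]]] = (),
    xtol: float = 1e-14,
) -> np.ndarray:
    """Polish ``x0`` toward rhs(x) = 0 subject to conservation sums.

    Parameters
    ----------
    rhs : callable
        Autonomous right-hand side, vector in, vector out.
    x0 : ndarray
        Starting point (typically the endpoint of a long integration); also
        defines the conservation targets.
    conservation : sequence of (row, members)
        For each conservation group, the rhs row to replace and the indices
        whose sum is conserved. The target is ``x0[members].sum()``.
    xtol : float
        Relative step tolerance of the hybrid Powell solver.

    Returns
    -------
    ndarray
        The refined state if the solver converged to a physical
        (non-negative, conservation-respecting) point, else ``x0`` unchanged.
    """
    x0 = np.asarray(x0, dtype=float)
    scale = max(float(np.max(np.abs(x0))), 1e-30)
    targets = [float(x0[list(members)].sum()) for _, members in conservation]

    def residual(z: np.ndarray) -> np.ndarray:
        x = z * scale
        r = rhs(x) / scale
        for (row, members), target in zip(conservation, targets):
            r[row] = (x[list(members)].sum() - target) / scale
        return r

    sol = root(residual, x0 / scale, method="hybr", options={"xtol": xtol})
    x = sol.x * scale
    if not sol.success:
        return x0
    if np.any(x < -1e-9 * scale):
        return x0
    np.clip(x, 0.0, None, out=x)
    # accept only if the polish did not break conservation
    for (_, members), target in zip(conservation, targets):
        drift = abs(x[list(members)].sum() - target)
        if drift > 1e-9 * max(abs(target), scale * 1e-12):
            return x0
    return x
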