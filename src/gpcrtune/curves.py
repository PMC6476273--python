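"""Shared dose-response curve container.

A :class:`ResponseCurve` is the common currency between the ODE simulators,
the 4PL fitting machinery and the consortium mixture operators: a sorted dose
grid (molar) paired with one endpoint response per dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ResponseCurve:
    """Endpoint responses on a strictly increasing dose grid.

    Parameters
    ----------
    doses : array-like of float
        Ligand concentrations in M, sorted strictly ascending. May include 0.
    responses : array-like of float
        One response per dose, in whatever output unit the producer uses
        (a model readout concentration, or fluorescence).
    label : str
        Free-text tag carried through plots and CSV output.
    """

    doses: np.ndarray
    responses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        responses = np.asarray(self.responses, dtype=float)
        if doses.ndim != 1 or responses.ndim != 1:
            raise ValueError("doses and responses must be 1-D")
        if doses.shape != responses.shape:
            raise ValueError(
                f"doses ({doses.size}) and responses ({responses.size}) differ in length"
            )
        if doses.size and doses[0] < 0:
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)

    def __len__(self) -> int:
        return self.doses.size

    def interpolate(self, dose_grid: np.ndarray) -> np.ndarray:
        """Resample onto ``dose_grid`` (log-linear in dose for positive doses).

        Dose 0 maps to the curve's own dose-0 response when present, otherwise
        to the response at the lowest tabulated dose. Queries outside the
        tabulated range clamp to the end values.
        """
        grid = np.asarray(dose_grid, dtype=float)
        pos = self.doses > 0
        if pos.sum() < 2:
            raise ValueError("need at least two positive doses to interpolate")
        logd = np.log10(self.doses[pos])
        resp = self.responses[pos]
        out = np.empty(grid.shape, dtype=float)
        positive_q = grid > 0
        out[positive_q] = np.interp(np.log10(grid[positive_q]), logd, resp)
        if np.any(~positive_q):
            zero_val = (
                self.responses[0] if self.doses[0] == 0 else resp[0]
            )
            out[~positive_q] = zero_val
        return out
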