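"""Melatonin-measurement arithmetic: diagnostic ions and quantitation.

Covers the three calculations used to benchmark a GPCR sensor consortium
against LC-MS: monoisotopic m/z of diagnostic ions (protonated molecule and
in-source neutral-loss fragments), linear standard-curve quantitation, and
inversion of a fitted 4PL to read a concentration off a sensor's fluorescence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy import stats

from .doseresponse import FourPL

__all__ = [
    "MolecularFormula",
    "StandardCurve",
    "QuantResult",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "fit_standard_curve",
    "invert_standard_curve",
    "sensor_quantify",
]

# Most-abundant-isotope masses (Da), CODATA/AME-style standard atomic data.
ISOTOPE_MASS = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972071174,
    "P": 30.973761998,
    "Na": 22.989769282,
    "K": 38.963706486,
    "Cl": 34.968852682,
    "F": 18.998403163,
}

PROTON_MASS = 1.007276467  # Da; [M+H]+ adds a proton, not a hydrogen atom

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map (counts are non-negative integers)."""

    counts: dict

    def __post_init__(self) -> None:
        for elem, n in self.counts.items():
            if elem not in ISOTOPE_MASS:
                raise ValueError(f"unknown element {elem!r}")
            if not (isinstance(n, int) and n >= 0):
                raise ValueError(f"count for {elem} must be a non-negative integer")

    @classmethod
    def from_string(cls, hill: str) -> "MolecularFormula":
        return parse_formula(hill)


def parse_formula(hill: str) -> MolecularFormula:
    """Parse a Hill-notation string such as ``"C13H16N2O2"``."""
    counts: dict = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(hill):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {hill!r} at position {pos}")
        pos = match.end()
        elem, num = match.group(1), match.group(2)
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(hill) or (hill and not counts):
        raise ValueError(f"cannot parse formula {hill!r}")
    return MolecularFormula(counts)


def _as_formula(f) -> MolecularFormula:
    return parse_formula(f) if isinstance(f, str) else f


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Sum of most-abundant-isotope masses, in Da. Empty formula -> 0."""
    f = _as_formula(f)
    return sum(ISOTOPE_MASS[elem] * n for elem, n in f.counts.items())


def ion_mz(
    f: MolecularFormula | str,
    adduct: str = "[M+H]+",
    neutral_loss: MolecularFormula | str | None = None,
    ndigits: int | None = 4,
) -> float:
    """m/z of a singly charged diagnostic ion.

    ``neutral_loss`` subtracts the monoisotopic mass of the lost fragment
    (for in-source fragments such as [M+H-C2H5NO]+). The default rounds
    half-even to 4 decimals, the precision of standard ion tables; pass
    ``ndigits=None`` for the unrounded value.
    """
    offsets = {
        "[M+H]+": PROTON_MASS,
        "[M+Na]+": ISOTOPE_MASS["Na"] - 0.000548580,  # Na+ = Na atom - e-
        "[M-H]-": -PROTON_MASS,
    }
    if adduct not in offsets:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(offsets)}"
        )
    mz = monoisotopic_mass(f) + offsets[adduct]
    if neutral_loss is not None:
        mz -= monoisotopic_mass(neutral_loss)
    if ndigits is None:
        return mz
    return float(Decimal(repr(mz)).quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_EVEN))


@dataclass(frozen=True)
class StandardCurve:
    """An OLS calibration line: signal = slope * concentration + intercept."""

    slope: float
    intercept: float
    valid_range: tuple  # (min, max) concentration of the calibration points, M
    signal_range: tuple  # (min, max) fitted signal over valid_range
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("degenerate standard curve: slope is zero")


@dataclass(frozen=True)
class QuantResult:
    """A back-calculated concentration plus an in-range flag."""

    concentration: float  # M; NaN when the signal is out of range
    in_range: bool


def fit_standard_curve(concentrations, signals) -> StandardCurve:
    """Ordinary least-squares calibration line through standard points."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need >= 3 matching (concentration, signal) points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate standards: all concentrations equal")
    fit = stats.linregress(x, y)
    lo, hi = float(x.min()), float(x.max())
    predicted = fit.slope * x + fit.intercept
    sig_lo = fit.slope * lo + fit.intercept
    sig_hi = fit.slope * hi + fit.intercept
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - predicted) ** 2)) / sst if sst > 0 else 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        valid_range=(lo, hi),
        signal_range=(min(sig_lo, sig_hi), max(sig_lo, sig_hi)),
        r_squared=r2,
    )


def invert_standard_curve(curve: StandardCurve, signal: float) -> QuantResult:
    """Concentration = (signal - intercept) / slope, flagged when the implied
    concentration falls outside the calibrated range."""
    conc = (float(signal) - curve.intercept) / curve.slope
    in_range = curve.valid_range[0] <= conc <= curve.valid_range[1]
    return QuantResult(concentration=conc, in_range=in_range)


def sensor_quantify(p: FourPL, fluorescence: float) -> QuantResult:
    """Invert a sensor's fitted 4PL to a ligand concentration.

    Only responses strictly inside the open asymptote interval (A, D) map to
    a finite dose; values at or beyond an asymptote come back flagged with a
    NaN concentration rather than raising.
    """
    y = float(fluorescence)
    lo, hi = min(p.A, p.D), max(p.A, p.D)
    if not (lo < y < hi):
        return QuantResult(concentration=math.nan, in_range=False)
    x = p.C * ((p.A - p.D) / (y - p.D) - 1.0) ** (1.0 / p.B)
    return QuantResult(concentration=float(x), in_range=True)
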