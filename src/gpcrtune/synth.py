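"""Seeded synthetic datasets with the statistical structure of the assays.

Every generator attaches its ground truth and is bit-reproducible under its
seed, so parameter-recovery tests are self-contained:

* plate-reader style dose-response tables (replicates with multiplicative
  lognormal noise around a known 4PL),
* flow-cytometry style per-cell fluorescence populations (10,000 lognormal
  cells summarised by their geometric mean, the convention for reporting
  population fluorescence),
* two-cell model 260-minute endpoints for ODE parameter recovery,
* OD600 growth series on a 24 h / 15 min plate-reader sampling grid.

Noise is multiplicative lognormal with median 1 (fluorescence readouts are
positive with roughly constant CV); cv = 0 reproduces the noise-free truth
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .doseresponse import FourPL, GrowthSeries, fourpl_eval
from .twocell import (
    DEFAULT_T_END,
    SensorVariant,
    TwoCellRateSet,
    twocell_dose_response,
)

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "FlowPopulation",
    "gen_dose_response",
    "gen_flow_population",
    "gen_twocell_dataset",
    "gen_od_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    ``cv`` is the coefficient of variation of the noise factor (sigma of the
    underlying normal is sqrt(ln(1 + cv^2)); the factor has median 1 so the
    geometric mean of repeated draws converges to the clean value).
    """

    cv: float = 0.1
    n_cells: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log1p(self.cv**2))

    def factors(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.cv == 0:
            return np.ones(shape)
        return rng.lognormal(mean=0.0, sigma=self.sigma, size=shape)


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset: long-format readouts plus the generating truth."""

    readouts: pd.DataFrame
    truth: object  # the generating FourPL or TwoCellRateSet
    seed: int
    design: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FlowPopulation:
    """Per-cell fluorescence draws and their geometric-mean summary."""

    values: np.ndarray
    geometric_mean: float
    arithmetic_mean: float
    truth_mean: float
    seed: int


def gen_dose_response(
    truth: FourPL,
    doses: Sequence[float],
    n_reps: int = 3,
    noise: NoiseModel = NoiseModel(),
) -> SyntheticDataset:
    """Triplicate-isolate style dose-response table around a known 4PL.

    Each replicate response is fourpl_eval(truth, dose) times an independent
    lognormal factor. Columns: ``dose_M``, ``replicate``, ``response``.
    """
    doses = np.asarray(doses, dtype=float)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(noise.seed)
    clean = fourpl_eval(truth, doses)
    rows = []
    for rep in range(n_reps):
        factors = noise.factors(rng, doses.shape)
        for d, v in zip(doses, clean * factors):
            rows.append({"dose_M": d, "replicate": rep, "response": v})
    return SyntheticDataset(
        readouts=pd.DataFrame(rows),
        truth=truth,
        seed=noise.seed,
        design={"doses": doses, "n_reps": n_reps, "cv": noise.cv},
    )


def gen_flow_population(
    mean_fluor: float, noise: NoiseModel = NoiseModel(cv=0.4)
) -> FlowPopulation:
    """A flow-cytometry sample: n_cells lognormal per-cell fluorescences.

    The population median (hence the expected geometric mean) is
    ``mean_fluor``; the sample geometric mean is the reported summary.
    """
    if mean_fluor <= 0:
        raise ValueError("mean_fluor must be > 0")
    rng = np.random.default_rng(noise.seed)
    values = mean_fluor * noise.factors(rng, noise.n_cells)
    return FlowPopulation(
        values=values,
        geometric_mean=float(np.exp(np.mean(np.log(values)))),
        arithmetic_mean=float(np.mean(values)),
        truth_mean=mean_fluor,
        seed=noise.seed,
    )


def gen_twocell_dataset(
    rates: TwoCellRateSet,
    variant: SensorVariant,
    doses: Sequence[float],
    noise: NoiseModel = NoiseModel(cv=0.0),
    t_end: float = DEFAULT_T_END,
) -> SyntheticDataset:
    """260-minute endpoint readings of the two-cell model, optionally noisy.

    Columns: ``dose_M``, ``endpoint_M``. The attached truth is the full rate
    set, so recovery tests can free any subset against it.
    """
    doses = np.asarray(doses, dtype=float)
    curve = twocell_dose_response(rates, variant, dose_grid=doses, t_end=t_end)
    rng = np.random.default_rng(noise.seed)
    readouts = curve.responses * noise.factors(rng, doses.shape)
    return SyntheticDataset(
        readouts=pd.DataFrame({"dose_M": doses, "endpoint_M": readouts}),
        truth=rates,
        seed=noise.seed,
        design={"variant": variant.name, "t_end": t_end, "cv": noise.cv},
    )


def gen_od_series(
    rate: float,
    od0: float,
    duration_h: float = 24.0,
    interval_min: float = 15.0,
    carrying_capacity: float | None = None,
) -> GrowthSeries:
    """An OD600 time series on the plate-reader sampling grid.

    Pure exponential by default (``OD(t) = od0 * exp(rate * t)``); with
    ``carrying_capacity`` K set, logistic growth saturating at K. 24 h at
    15-minute intervals gives 97 samples including t = 0.
    """
    if od0 <= 0:
        raise ValueError("od0 must be > 0")
    times = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    if carrying_capacity is None:
        od = od0 * np.exp(rate * times)
    else:
        K = carrying_capacity
        if K <= od0:
            raise ValueError("carrying_capacity must exceed od0")
        e = np.exp(rate * times)
        od = K * od0 * e / (K + od0 * (e - 1.0))
    return GrowthSeries(times=times, od600=od)
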