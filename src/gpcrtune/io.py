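"""Configuration files, CSV interchange and run manifests.

One flat key:value config dialect (JSON or YAML) serves every model: keys
must exactly match the target dataclass's field names and are validated with
close-match suggestions on typos. Curves travel as ``dose_M,response`` CSV
(optionally with ``replicate`` and ``label`` columns) at full float
precision; sweep summaries as ``factor,basal,emax,fold_change``. A
:class:`RunConfig` snapshots the fully resolved parameters of a run next to
its outputs so any result can be regenerated from its manifest.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import ResponseCurve

__all__ = [
    "RunConfig",
    "load_overrides",
    "apply_overrides",
    "load_config",
    "read_curve_csv",
    "write_curve_csv",
    "write_sweep_csv",
]

logger = logging.getLogger(__name__)


def load_overrides(path: str | Path) -> dict:
    """Parse a flat key:value override file (JSON or YAML by extension)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return {}
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return data


def apply_overrides(obj, overrides: dict):
    """Return ``obj`` (a frozen dataclass) with validated overrides applied.

    Unknown keys raise with a did-you-mean suggestion; non-numeric values
    for numeric fields raise TypeError.
    """
    valid = {f.name for f in dataclasses.fields(obj)}
    clean = {}
    for key, value in overrides.items():
        if key not in valid:
            hint = difflib.get_close_matches(key, sorted(valid), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(
                f"unknown parameter {key!r}{suggestion} "
                f"Valid keys: {sorted(valid)}"
            )
        if isinstance(value, str):
            # YAML 1.1 reads exponent forms like "7.0e8" as strings
            try:
                value = float(value)
            except ValueError:
                pass
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeError(f"parameter {key!r} must be a number, got {value!r}")
        clean[key] = float(value)
    return dataclasses.replace(obj, **clean)


def load_config(path: str | Path, *targets):
    """Build dataclass instances from one flat config file.

    ``targets`` are dataclass instances (e.g. a rate set and a totals
    object); each key in the file is routed to the target that owns a field
    of that name. An empty file returns the targets' defaults unchanged.
    """
    overrides = load_overrides(path)
    field_owner = {}
    for i, target in enumerate(targets):
        for f in dataclasses.fields(target):
            field_owner.setdefault(f.name, i)
    all_fields = sorted(field_owner)
    per_target: list[dict] = [{} for _ in targets]
    for key, value in overrides.items():
        if key not in field_owner:
            hint = difflib.get_close_matches(key, all_fields, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(
                f"unknown parameter {key!r}{suggestion} Valid keys: {all_fields}"
            )
        per_target[field_owner[key]][key] = value
    resolved = tuple(
        apply_overrides(t, o) for t, o in zip(targets, per_target)
    )
    return resolved[0] if len(resolved) == 1 else resolved


def write_curve_csv(curve: ResponseCurve, path: str | Path) -> None:
    """Write ``dose_M,response,label`` at full float precision."""
    df = pd.DataFrame(
        {"dose_M": curve.doses, "response": curve.responses,
         "label": [curve.label] * len(curve)}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_curve_csv(path: str | Path):
    """Read a curve CSV back.

    Returns a :class:`ResponseCurve` for plain ``dose_M,response`` tables;
    when a ``replicate`` column is present, returns the long-format DataFrame
    (grouped replicate structure) instead. Errors name the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("dose_M", "response"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    doses = pd.to_numeric(df["dose_M"], errors="coerce")
    bad = np.flatnonzero(doses.isna().to_numpy())
    if bad.size:
        raise ValueError(
            f"{path}: non-numeric dose in row {int(bad[0]) + 2} "
            f"(value {df['dose_M'].iloc[bad[0]]!r})"
        )
    responses = pd.to_numeric(df["response"], errors="coerce")
    bad = np.flatnonzero(responses.isna().to_numpy())
    if bad.size:
        raise ValueError(f"{path}: non-numeric response in row {int(bad[0]) + 2}")
    if "replicate" in df.columns:
        df["dose_M"] = doses
        df["response"] = responses
        return df
    label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else ""
    return ResponseCurve(doses=doses.to_numpy(), responses=responses.to_numpy(),
                         label=label)


def write_sweep_csv(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a sweep summary (``factor,basal,emax,fold_change`` or similar)."""
    summary.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """A run manifest: everything needed to reproduce one computation."""

    model: str
    parameters: dict = field(default_factory=dict)
    dose_grid: list = field(default_factory=list)
    t_end: float | None = None
    seed: int | None = None
    outputs: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def write_resolved(self, path: str | Path) -> None:
        """Dump the fully resolved manifest as JSON beside the outputs."""
        payload = dataclasses.asdict(self)
        payload["dose_grid"] = [float(d) for d in self.dose_grid]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        logger.info("resolved run config written to %s", path)

    @classmethod
    def from_dataclasses(cls, model: str, *objs, **kwargs) -> "RunConfig":
        params = {}
        for obj in objs:
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, (int, float)):
                    params[f.name] = float(v)
        return cls(model=model, parameters=params, **kwargs)
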