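"""File formats and run configuration.

CSV for observational data, JSON for model artifacts, YAML or JSON for run
configs. Times are hours since oviposition, temperatures °C, lengths mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stages import parse_stage
from .thermal import TemperatureSeries

OBS_COLUMNS = ["replicate", "temp_c", "time_h", "stage", "length_mm"]


class ObservationError(ValueError):
    """Invalid rearing-observation file; message carries the offending row."""


def read_observations(path) -> pd.DataFrame:
    """Read and validate a rearing-observation CSV.

    Requires columns ``replicate,temp_c,time_h,stage,length_mm`` (extra
    columns pass through). Row numbers in error messages are 1-based file
    rows including the header.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationError(f"missing required columns: {missing}")
    for col in ("replicate", "temp_c", "time_h", "length_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ObservationError(
                f"row {row}: non-numeric or missing value in column {col!r}"
            )
        df[col] = coerced
    for i, label in df["stage"].items():
        try:
            parse_stage(label)
        except ValueError as exc:
            raise ObservationError(f"row {int(i) + 2}: {exc}") from None
    nonpos = df.index[df["length_mm"] <= 0]
    if len(nonpos):
        raise ObservationError(
            f"row {int(nonpos[0]) + 2}: non-positive length_mm"
        )
    df["stage"] = df["stage"].str.strip().str.lower()
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    cols = OBS_COLUMNS + [c for c in df.columns if c not in OBS_COLUMNS]
    df.to_csv(path, index=False, columns=cols)


def read_temperature_csv(path) -> TemperatureSeries:
    """Read an hourly temperature record: columns ``timestamp`` (ISO-8601,
    strictly hourly) and ``temp_c``. Gaps must be filled beforehand."""
    df = pd.read_csv(path)
    for col in ("timestamp", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"temperature CSV needs column {col!r}")
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) > 1:
        deltas = ts.diff().dropna()
        if not (deltas == pd.Timedelta(hours=1)).all():
            raise ValueError("timestamps must be strictly consecutive hourly values")
    temps = pd.to_numeric(df["temp_c"], errors="raise").to_numpy(dtype=float)
    return TemperatureSeries(temps, start=ts.iloc[0])


def write_temperature_csv(series: TemperatureSeries, path) -> None:
    start = series.start
    if not isinstance(start, pd.Timestamp):
        start = pd.Timestamp("2000-01-01") + pd.Timedelta(hours=int(start))
    stamps = pd.date_range(start, periods=series.n_hours, freq="h")
    pd.DataFrame({"timestamp": stamps, "temp_c": series.temps_c}).to_csv(
        path, index=False
    )


@dataclass
class RunConfig:
    """Serializable run configuration; a run is reproducible from this + seed."""

    observations: str | None = None
    temperatures: str | None = None
    output_dir: str = "."
    base_temp_c: float | None = None
    clamp_negative: bool = True
    seed: int = 0
    level: float = 0.95
    design: dict = field(default_factory=dict)      # CohortDesign overrides
    model_options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "observations": self.observations,
            "temperatures": self.temperatures,
            "output_dir": self.output_dir,
            "base_temp_c": self.base_temp_c,
            "clamp_negative": self.clamp_negative,
            "seed": self.seed,
            "level": self.level,
            "design": self.design,
            "model_options": self.model_options,
        }


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run config (same schema either way)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def dump_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.reset_index().to_dict(orient="list")
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
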