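"""Developmental stages, minimum-time / minimum-ADH threshold tables, and the
stage x temperature ANOVA.

Stage timing follows the first-individual (minimum) criterion used in
forensic practice: the time to reach a stage is the earliest sampling time at
which any individual shows that stage (or any later one), not a 50 %
transition time.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import constants
from .thermal import ThermalParams


class Stage(enum.IntEnum):
    """Ordered developmental stages.

    Transition forms (larvae caught mid-moult, showing one extra posterior
    spiracular slit) are optional labels that collapse to their parent instar
    when disabled.
    """

    EGG = 0
    INSTAR1 = 1
    TRANSITION_1_2 = 2
    INSTAR2 = 3
    TRANSITION_2_3 = 4
    INSTAR3 = 5
    POSTFEEDING = 6
    PUPA = 7
    ADULT = 8

    @property
    def label(self) -> str:
        return self.name.lower()


_STAGE_BY_LABEL = {s.label: s for s in Stage}

PRIMARY_STAGES = (
    Stage.EGG, Stage.INSTAR1, Stage.INSTAR2, Stage.INSTAR3,
    Stage.POSTFEEDING, Stage.PUPA, Stage.ADULT,
)
FEEDING_STAGES = frozenset({
    Stage.INSTAR1, Stage.TRANSITION_1_2, Stage.INSTAR2,
    Stage.TRANSITION_2_3, Stage.INSTAR3,
})
_PARENT = {Stage.TRANSITION_1_2: Stage.INSTAR1, Stage.TRANSITION_2_3: Stage.INSTAR2}


def parse_stage(label: str) -> Stage:
    try:
        return _STAGE_BY_LABEL[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown stage label {label!r}") from None


def collapse_transitions(stage: Stage) -> Stage:
    """Map transition forms onto their parent instar."""
    return _PARENT.get(stage, stage)


@dataclass(frozen=True)
class StageThresholdTable:
    """Minimum ADH to reach each primary stage, with its base temperature.

    A threshold is meaningless without the base it was accumulated against,
    so the base temperature is embedded. ``transition_ranges`` hold the ADH
    windows of mid-moult forms; note the published instar2→3 window extends
    past the postfeeding minimum, so the monotonicity invariant applies to
    primary-stage minima only.
    """

    min_adh: dict[str, float]
    base_temp_c: float
    transition_ranges: dict[str, tuple[float, float]] | None = None
    min_time_h: pd.DataFrame | None = None  # optional per-(stage, temp) hours

    def __post_init__(self) -> None:
        order = [s.label for s in PRIMARY_STAGES if s.label in self.min_adh]
        vals = [self.min_adh[k] for k in order]
        if self.min_adh.get("egg", 0.0) != 0.0:
            raise ValueError("egg threshold must be 0 (clock starts at oviposition)")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"stage thresholds not strictly increasing: {vals}")

    @classmethod
    def default(cls) -> "StageThresholdTable":
        return cls(
            min_adh=dict(constants.STAGE_MIN_ADH),
            base_temp_c=constants.BASE_TEMP_C,
            transition_ranges=dict(constants.TRANSITION_ADH_RANGES),
        )

    def required_adh(self, stage: Stage) -> float:
        """Minimum ADH implied by the presence of ``stage``."""
        if stage in _PARENT and self.transition_ranges:
            return self.transition_ranges[stage.label][0]
        key = collapse_transitions(stage).label
        if key not in self.min_adh:
            raise KeyError(f"no threshold for stage {key!r}")
        return self.min_adh[key]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "min_adh": self.min_adh,
            "base_temp_c": self.base_temp_c,
            "transition_ranges": self.transition_ranges,
            "min_time_h": None if self.min_time_h is None
            else self.min_time_h.reset_index().to_dict(orient="list"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "StageThresholdTable":
        mt = d.get("min_time_h")
        frame = None
        if mt is not None:
            frame = pd.DataFrame(mt).set_index("stage")
            frame.columns = [float(c) for c in frame.columns]
        tr = d.get("transition_ranges")
        if tr is not None:
            tr = {k: tuple(v) for k, v in tr.items()}
        return cls(min_adh=dict(d["min_adh"]), base_temp_c=float(d["base_temp_c"]),
                   transition_ranges=tr, min_time_h=frame)

    @classmethod
    def from_json(cls, path) -> "StageThresholdTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def minimum_stage_times(
    observations: pd.DataFrame, collapse: bool = True
) -> pd.DataFrame:
    """Per-(stage, temperature) minimum hours, first-individual criterion.

    A stage counts as reached once that stage *or any later stage* is
    observed (sampling can miss a short stage entirely). Returns a DataFrame
    indexed by stage label with one column per temperature; NaN marks stages
    never observed at a temperature.
    """
    obs = observations.copy()
    ranks = obs["stage"].map(lambda s: int(parse_stage(s)))
    obs["_rank"] = ranks
    temps = sorted(obs["temp_c"].unique())
    stages = [s for s in PRIMARY_STAGES] if collapse else list(Stage)
    out = pd.DataFrame(index=[s.label for s in stages], columns=temps, dtype=float)
    for temp, grp in obs.groupby("temp_c"):
        for s in stages:
            hit = grp.loc[grp["_rank"] >= int(s), "time_h"]
            out.loc[s.label, temp] = hit.min() if len(hit) else np.nan
    out.index.name = "stage"
    return out


def build_threshold_table(
    min_times: pd.DataFrame, base_temp_c: float
) -> StageThresholdTable:
    """Convert per-(stage, temperature) minimum hours into minimum ADH.

    ``min_adh(stage) = min over temperatures of hours x (T - base)``, matching
    the convention of quoting a single minimum per stage. Raises when the
    resulting ladder is not strictly increasing (inconsistent staging).
    """
    temps = np.array([float(c) for c in min_times.columns])
    if np.any(temps <= base_temp_c):
        raise ValueError("base temperature must lie below all rearing temperatures")
    min_adh: dict[str, float] = {"egg": 0.0}
    for label, row in min_times.iterrows():
        if label in ("egg",):
            continue
        vals = row.to_numpy(dtype=float) * (temps - base_temp_c)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            min_adh[label] = float(vals.min())
    return StageThresholdTable(min_adh=min_adh, base_temp_c=base_temp_c,
                               min_time_h=min_times)


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Additive two-way decomposition without replication."""

    f_rows: float
    df_rows: int
    p_rows: float
    f_cols: float
    df_cols: int
    p_cols: float
    df_error: int
    ss_rows: float
    ss_cols: float
    ss_error: float
    ss_total: float
    zero_residual: bool = False


def two_way_anova_noreplication(table) -> TwoWayAnovaResult:
    """Two-way ANOVA without replication on a complete r x c matrix.

    Rows and columns are tested against the residual mean square with
    ``df_error = (r-1)(c-1)``. A zero residual (purely additive matrix) is
    reported as infinite F with ``zero_residual`` set.
    """
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete r x c matrix with r, c >= 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells: no replication available to absorb them")
    r, c = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = c * float(((row_means - grand) ** 2).sum())
    ss_cols = r * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    df_rows, df_cols = r - 1, c - 1
    df_error = df_rows * df_cols
    ms_error = ss_error / df_error
    if ms_error <= 1e-12 * max(ss_total, 1.0):
        f_r = np.inf if ss_rows > 0 else 0.0
        f_c = np.inf if ss_cols > 0 else 0.0
        return TwoWayAnovaResult(f_r, df_rows, 0.0 if ss_rows > 0 else 1.0,
                                 f_c, df_cols, 0.0 if ss_cols > 0 else 1.0,
                                 df_error, ss_rows, ss_cols, max(ss_error, 0.0),
                                 ss_total, zero_residual=True)
    f_rows = (ss_rows / df_rows) / ms_error
    f_cols = (ss_cols / df_cols) / ms_error
    p_rows = float(sps.f.sf(f_rows, df_rows, df_error))
    p_cols = float(sps.f.sf(f_cols, df_cols, df_error))
    return TwoWayAnovaResult(float(f_rows), df_rows, p_rows,
                             float(f_cols), df_cols, p_cols,
                             df_error, ss_rows, ss_cols, ss_error, ss_total)


def isomorphen_export(observations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy tables behind isomorphen / isomegalen diagrams.

    Returns ``(occupancy, lengths)``: stage occupancy fractions per
    (temperature, time) cell — summing to 1 within each cell — and body-length
    quantiles (q25/median/q75) plus the mean per cell.
    """
    occ = (
        observations.groupby(["temp_c", "time_h", "stage"], observed=True)
        .size().rename("n").reset_index()
    )
    totals = occ.groupby(["temp_c", "time_h"])["n"].transform("sum")
    occ["fraction"] = occ["n"] / totals
    lengths = (
        observations.groupby(["temp_c", "time_h"])["length_mm"]
        .agg(q25=lambda s: s.quantile(0.25), median="median",
             q75=lambda s: s.quantile(0.75), mean="mean", n="size")
        .reset_index()
    )
    return occ, lengths


def development_time_summary(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-temperature egg-to-adult development time (days) from observations.

    Destructive sampling yields interval-censored emergence, so the
    development time is estimated by classic stage-frequency analysis: at
    each sampling time the adult fraction among the sampled individuals
    estimates the probability that emergence has occurred, and the
    median emergence time is the linear-interpolation crossing of that
    fraction through 0.5. This is robust to the detection lag of the first
    emerged individual. Temperatures where adults never reach half the
    samples are dropped.
    """
    out = []
    for temp, grp in observations.groupby("temp_c"):
        frac = (
            grp.assign(_adult=grp["stage"].eq("adult"))
            .groupby("time_h")["_adult"].agg(["mean", "size"])
            .sort_index()
        )
        prev_t, prev_f = 0.0, 0.0
        crossing = None
        n_adults = int((grp["stage"] == "adult").sum())
        for ti, (fi, _) in frac.iterrows():
            if fi >= 0.5:
                crossing = prev_t + (0.5 - prev_f) / (fi - prev_f) * (ti - prev_t)
                break
            prev_t, prev_f = ti, fi
        if crossing is not None:
            out.append((float(temp), crossing / 24.0, n_adults))
    if not out:
        raise ValueError("no adult observations; cannot summarize development time")
    return pd.DataFrame(out, columns=["temp_c", "dev_days", "n_adults"])
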