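"""Minimum-postmortem-interval (PMI-min) estimation.

Scene evidence (the oldest developmental stage found, and/or the largest
feeding-larva body length) fixes a minimum ADH requirement; back-accumulating
that requirement over the scene's hourly temperature record gives the minimum
number of hours since oviposition. The ADH clock starts at egg laying —
any pre-oviposition delay is outside this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import LengthAdhModel, predict_adh
from .stages import Stage, StageThresholdTable, collapse_transitions
from .thermal import TemperatureSeries, ThermalParams


@dataclass(frozen=True)
class SceneEvidence:
    """Insect evidence collected at a scene.

    At least one of ``oldest_stage`` / ``max_length_mm`` must be present;
    length evidence is only meaningful for feeding larvae (stage <= instar3),
    where body length still tracks ADH.
    """

    oldest_stage: Stage | None = None
    max_length_mm: float | None = None
    collection_time: object = None

    def __post_init__(self) -> None:
        if self.oldest_stage is None and self.max_length_mm is None:
            raise ValueError("evidence needs a stage and/or a length")
        if self.max_length_mm is not None and self.max_length_mm <= 0:
            raise ValueError("length must be positive")
        if self.max_length_mm is not None and self.oldest_stage is not None:
            if collapse_transitions(self.oldest_stage) > Stage.INSTAR3:
                raise ValueError(
                    "length evidence is invalid for post-feeding/pupal stages; "
                    "use stage thresholds instead"
                )


@dataclass(frozen=True)
class AdhRequirement:
    point: float
    interval: tuple[float, float]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BackAccumulation:
    hours: float
    requirement_met: bool
    accumulated_total: float


@dataclass(frozen=True)
class PMIEstimate:
    required_adh: float
    required_adh_interval: tuple[float, float]
    pmi_min_h: float
    pmi_interval_h: tuple[float, float]
    level: float
    flags: tuple[str, ...] = ()


def required_adh(
    evidence: SceneEvidence,
    thresholds: StageThresholdTable,
    length_model: LengthAdhModel | None = None,
    level: float = 0.95,
) -> AdhRequirement:
    """Minimum ADH requirement implied by the evidence.

    Stage evidence gives the stage threshold with a degenerate interval;
    length evidence gives the length-model prediction with its prediction
    interval; when both are present the binding minimum is taken — the
    elementwise maximum of the two bounds (never an average: PMI-min is the
    shortest time *consistent with all* the evidence).
    """
    flags: list[str] = []
    parts: list[AdhRequirement] = []
    if evidence.oldest_stage is not None:
        v = thresholds.required_adh(evidence.oldest_stage)
        parts.append(AdhRequirement(v, (v, v)))
    if evidence.max_length_mm is not None:
        if length_model is None:
            raise ValueError("length evidence requires a fitted length model")
        pred = predict_adh(length_model, evidence.max_length_mm, level=level)
        if pred.extrapolated:
            flags.append("length outside calibration range (extrapolated)")
        parts.append(AdhRequirement(pred.point, (pred.lo, pred.hi)))
    point = max(p.point for p in parts)
    lo = max(p.interval[0] for p in parts)
    hi = max(p.interval[1] for p in parts)
    return AdhRequirement(point, (lo, hi), tuple(flags))


def back_accumulate(
    series: TemperatureSeries, requirement: float, params: ThermalParams
) -> BackAccumulation:
    """Smallest number of hours before the record's end whose accumulated ADH
    meets ``requirement``.

    Walks the hourly record backwards from the collection time; the crossing
    hour is resolved by linear interpolation. If the record is exhausted
    first, the flag is cleared and the record length is returned with the
    total actually accumulated (a lower bound on the PMI).
    """
    if series.n_hours < 1:
        raise ValueError("empty temperature series")
    if requirement <= 0:
        return BackAccumulation(0.0, True, 0.0)
    inc = np.asarray(params.excess(series.temps_c))[::-1]  # last hour first
    cum = np.cumsum(inc)
    total = float(cum[-1])
    idx = int(np.searchsorted(cum, requirement))
    if idx >= cum.size:
        # tolerate summation-order rounding at the record boundary
        if requirement - total <= 1e-9 * max(1.0, total):
            return BackAccumulation(float(series.n_hours), True, total)
        return BackAccumulation(float(series.n_hours), False, total)
    prev = cum[idx - 1] if idx > 0 else 0.0
    frac = (requirement - prev) / inc[idx]
    return BackAccumulation(float(idx + frac), True, total)


def estimate_pmi(
    evidence: SceneEvidence,
    series: TemperatureSeries,
    thresholds: StageThresholdTable | None = None,
    length_model: LengthAdhModel | None = None,
    level: float = 0.95,
    params: ThermalParams | None = None,
) -> PMIEstimate:
    """PMI-min from scene evidence and the scene temperature record.

    Back-accumulates the point requirement and both interval endpoints; the
    mapping is monotone (a higher ADH requirement never yields a shorter
    PMI). The interval mapping under variable temperatures is this package's
    construction: ADH prediction-interval endpoints are propagated through
    the same back-accumulation as the point estimate.
    """
    thresholds = thresholds or StageThresholdTable.default()
    params = params or ThermalParams(base_temp_c=thresholds.base_temp_c)
    req = required_adh(evidence, thresholds, length_model, level)
    flags = list(req.flags)
    point = back_accumulate(series, req.point, params)
    lo = back_accumulate(series, req.interval[0], params)
    hi = back_accumulate(series, req.interval[1], params)
    if not point.requirement_met or not hi.requirement_met:
        flags.append(
            "temperature record exhausted before the ADH requirement was met; "
            "PMI is a lower bound at the record length"
        )
    return PMIEstimate(
        required_adh=req.point,
        required_adh_interval=req.interval,
        pmi_min_h=point.hours,
        pmi_interval_h=(lo.hours, hi.hours),
        level=level,
        flags=tuple(flags),
    )
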