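"""Packaged reference values for *Lucilia sericata* thermal development.

These are published constants for a South Korean population reared at seven
constant temperatures (20–35 °C): stage-wise rate regressions and their
x-intercept base temperatures, mean egg-to-adult development times, minimum
accumulated-degree-hour (ADH) stage thresholds, the four-parameter sigmoid
rate model, and the body-length → ADH regression grid. They let the package
estimate a minimum postmortem interval without access to the original rearing
records.
"""

from __future__ import annotations

# Development rate is expressed as 1e4 / (development time in hours); any
# positive rescaling leaves the x-intercept base temperature unchanged.
RATE_SCALE = 1e4
RATE_SCALE_LABEL = "1e4 per hour"

#: Egg-to-adult developmental zero (°C), x-intercept of the rate regression.
BASE_TEMP_C = 9.0734

#: Stage-wise linear rate regressions (rate vs temperature, 20–28 °C):
#: slope, intercept, R², base temperature (x-intercept, °C), slope p-value.
STAGE_RATE_REGRESSIONS: dict[str, dict[str, float]] = {
    "egg": {"slope": 39.9305, "intercept": -479.1665, "r_squared": 0.8701,
            "base_temp_c": 12.0000, "p_value": 0.0207},
    "instar1": {"slope": 25.4630, "intercept": -164.0213, "r_squared": 0.5673,
                "base_temp_c": 6.4416, "p_value": 0.1416},
    "instar2": {"slope": 21.3656, "intercept": -147.9693, "r_squared": 0.6338,
                "base_temp_c": 6.9256, "p_value": 0.1071},
    "instar3": {"slope": 12.5778, "intercept": -92.7091, "r_squared": 0.6265,
                "base_temp_c": 7.3709, "p_value": 0.1106},
    "postfeeding": {"slope": 9.2416, "intercept": -65.3248, "r_squared": 0.3773,
                    "base_temp_c": 7.0686, "p_value": 0.2703},
    "pupa": {"slope": 4.4917, "intercept": -46.8452, "r_squared": 0.9152,
             "base_temp_c": 10.4293, "p_value": 0.0108},
    "egg_to_adult": {"slope": 1.9040, "intercept": -17.2758, "r_squared": 0.9907,
                     "base_temp_c": 9.0734, "p_value": 0.0004},
}

#: Mean egg-to-adult development time (days) at each rearing temperature (°C).
MEAN_DEV_TIME_DAYS: dict[float, float] = {
    20.0: 20.60, 22.0: 16.42, 24.0: 14.78, 26.0: 12.75,
    28.0: 11.70, 32.0: 10.90, 35.0: 10.70,
}

#: SDs and sample sizes of the development times above (documentation/reference).
DEV_TIME_SD_DAYS: dict[float, float] = {
    20.0: 1.53, 22.0: 1.54, 24.0: 0.61, 26.0: 0.96,
    28.0: 0.84, 32.0: 0.55, 35.0: 0.45,
}
DEV_TIME_N: dict[float, int] = {
    20.0: 499, 22.0: 357, 24.0: 361, 26.0: 332, 28.0: 360, 32.0: 390, 35.0: 374,
}

#: Temperatures used for the base-temperature fit. The response flattens above
#: 28 °C (sigmoid regime), so 32/35 °C are excluded from the linear fit.
BASE_FIT_TEMP_RANGE: tuple[float, float] = (20.0, 28.0)

#: Egg-to-adult thermal constant, accumulated degree days (mean, SD).
THERMAL_CONSTANT_ADD: tuple[float, float] = (232.81, 23.0)

#: Minimum ADH (°H above 9.0734 °C, clock starting at oviposition) to reach
#: each developmental stage; egg presence sets no thermal minimum.
STAGE_MIN_ADH: dict[str, float] = {
    "egg": 0.0,
    "instar1": 203.16,
    "instar2": 524.64,
    "instar3": 812.64,
    "postfeeding": 1551.60,
    "pupa": 2492.04,
    # Adult emergence from the thermal constant: 232.81 ADD x 24 h.
    "adult": 5587.44,
}

#: ADH ranges of larvae caught mid-moult (one extra posterior spiracular slit).
#: The second range as published extends past the postfeeding minimum 1551.60.
TRANSITION_ADH_RANGES: dict[str, tuple[float, float]] = {
    "transition_1_2": (454.3, 622.3),
    "transition_2_3": (812.6, 1612.4),
}

#: Upper end of the feeding larval calibration domain for length models (°H).
FEEDING_MAX_ADH = 1551.60

#: Four-parameter sigmoid rate model F(x) = y0 + a/(1 + exp(-(x - x0)/b))
#: fitted to egg-to-adult rates (rate scale 1e4/h); x0 is the optimum
#: development temperature.
SIGMOID_PARAMS: dict[str, float] = {"a": 28.56, "b": 3.28, "x0": 22.31, "y0": 11.14}
SIGMOID_X0_CI95 = 1.21  # °C half-width
SIGMOID_R2_ADJ = 0.93
SIGMOID_MSE = 3.10

#: Best-fitting length model: Log10(ADH) = b0 + b1 * Log10(length_mm),
#: feeding larvae only (ADH <= 1551.60).
LENGTH_MODEL_COEFFS: tuple[float, float] = (2.295, 0.327)
LENGTH_MODEL_SE = 0.083      # standard error of estimation on the Log10 scale
LENGTH_MODEL_N = 973
LENGTH_MODEL_R2_ADJ = 0.911
#: Body-length calibration range (mm) implied by the feeding larval stages.
LENGTH_MODEL_RANGE_MM: tuple[float, float] = (1.0, 16.0)

#: Body length by stage, mm (mean, SD).
STAGE_LENGTH_MM: dict[str, tuple[float, float]] = {
    "egg": (1.17, 0.13),
    "instar1": (2.45, 0.65),
    "instar2": (6.29, 1.54),
    "instar3": (13.16, 2.40),
    "postfeeding": (12.12, 1.99),
    "pupa": (7.73, 0.63),
}

#: Full rearing design: 25 eggs x 10 bottles x 7 temperatures x 5 replicates.
DESIGN_TOTAL_EGGS = 8750

PROVENANCE = (
    "Packaged constants are published reference values for a South Korean "
    "Lucilia sericata population reared at 20-35 degC; base temperature "
    "9.0734 degC, thermal constant 232.81 ADD."
)
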