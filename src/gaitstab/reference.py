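"""Published reference values from an IMU-versus-optical validation experiment.

These are the printed group-level results of a two-system overground walking
study (N = 10 healthy adults; conditions Normal, Eyes Closed, Wide and Tandem;
an inertial motion-capture suit compared against fixed optical motion
capture).  They serve two purposes here: the synthetic generator's condition
presets are anchored to the optical column so that simulated studies live on
a realistic scale, and the report helpers below reproduce the study's own
summary arithmetic (row means of the ICC grid, limits-of-agreement width
ratios, percent speed changes) as fast cross-checks of the reporting code.

All values are dimensionless (lengths divided by leg length L, speeds by
sqrt(g*L)) except where noted.  ``MEAN_LEG_LENGTH`` is in metres.
"""

from __future__ import annotations

import math

MEAN_LEG_LENGTH = 0.92  # m, group mean standing trochanter height
GRAVITY = 9.81  # m/s^2

CONDITIONS = ("normal", "eyes_closed", "wide", "tandem")

#: Group mean (s.d.) of each measure per system and condition.
SUMMARY_TABLE: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "speed": {
        "imu": {"normal": (0.357, 0.062), "eyes_closed": (0.341, 0.070),
                "wide": (0.346, 0.064), "tandem": (0.316, 0.071)},
        "optical": {"normal": (0.354, 0.060), "eyes_closed": (0.338, 0.069),
                    "wide": (0.341, 0.064), "tandem": (0.313, 0.071)},
    },
    "ml_mos": {
        "imu": {"normal": (0.004, 0.026), "eyes_closed": (0.005, 0.025),
                "wide": (0.066, 0.029), "tandem": (-0.048, 0.036)},
        "optical": {"normal": (0.012, 0.023), "eyes_closed": (0.013, 0.022),
                    "wide": (0.071, 0.047), "tandem": (-0.035, 0.017)},
    },
    "ap_mos": {
        "imu": {"normal": (0.163, 0.068), "eyes_closed": (0.170, 0.071),
                "wide": (0.149, 0.059), "tandem": (0.214, 0.085)},
        "optical": {"normal": (0.111, 0.050), "eyes_closed": (0.117, 0.055),
                    "wide": (0.097, 0.048), "tandem": (0.163, 0.069)},
    },
    "ml_lyapunov": {
        "imu": {"normal": (2.389, 0.147), "eyes_closed": (2.455, 0.131),
                "wide": (2.752, 0.216), "tandem": (2.209, 0.138)},
        "optical": {"normal": (1.969, 0.207), "eyes_closed": (2.042, 0.242),
                    "wide": (2.202, 0.229), "tandem": (1.818, 0.099)},
    },
    "ap_lyapunov": {
        "imu": {"normal": (2.918, 0.175), "eyes_closed": (3.096, 0.198),
                "wide": (3.131, 0.174), "tandem": (2.897, 0.207)},
        "optical": {"normal": (2.474, 0.213), "eyes_closed": (2.692, 0.309),
                    "wide": (2.674, 0.259), "tandem": (2.448, 0.268)},
    },
    "step_width_rms": {
        "imu": {"normal": (0.029, 0.007), "eyes_closed": (0.035, 0.007),
                "wide": (0.033, 0.008), "tandem": (0.024, 0.009)},
        "optical": {"normal": (0.027, 0.007), "eyes_closed": (0.032, 0.008),
                    "wide": (0.031, 0.008), "tandem": (0.022, 0.007)},
    },
    "step_length_rms": {
        "imu": {"normal": (0.031, 0.006), "eyes_closed": (0.038, 0.007),
                "wide": (0.040, 0.008), "tandem": (0.032, 0.008)},
        "optical": {"normal": (0.028, 0.004), "eyes_closed": (0.035, 0.008),
                    "wide": (0.036, 0.007), "tandem": (0.029, 0.005)},
    },
    "step_width": {
        "imu": {"normal": (0.125, 0.065), "eyes_closed": (0.140, 0.057),
                "wide": (0.376, 0.092), "tandem": (-0.051, 0.079)},
        "optical": {"normal": (0.158, 0.061), "eyes_closed": (0.172, 0.055),
                    "wide": (0.399, 0.132), "tandem": (0.004, 0.042)},
    },
    "step_length": {
        "imu": {"normal": (0.719, 0.037), "eyes_closed": (0.688, 0.052),
                "wide": (0.719, 0.055), "tandem": (0.703, 0.064)},
        "optical": {"normal": (0.711, 0.042), "eyes_closed": (0.682, 0.056),
                    "wide": (0.708, 0.055), "tandem": (0.694, 0.067)},
    },
}

#: Published ICC(A,1) of IMU against optical, per condition and pooled.
ICC_TABLE: dict[str, dict[str, float]] = {
    "ml_mos": {"normal": 0.16, "eyes_closed": 0.30, "wide": 0.46,
               "tandem": 0.34, "overall": 0.74},
    "ap_mos": {"normal": 0.65, "eyes_closed": 0.72, "wide": 0.66,
               "tandem": 0.81, "overall": 0.74},
    "step_width": {"normal": 0.51, "eyes_closed": 0.50, "wide": 0.83,
                   "tandem": 0.42, "overall": 0.91},
    "step_length": {"normal": 0.88, "eyes_closed": 0.94, "wide": 0.93,
                    "tandem": 0.95, "overall": 0.93},
}

#: Published Bland-Altman bias (optical minus IMU) and 95% LoA width.
BLAND_ALTMAN_TABLE: dict[str, dict[str, float]] = {
    "ml_mos": {"bias": 0.008, "loa_width": 0.14},
    "ap_mos": {"bias": -0.054, "loa_width": 0.13},
    "step_width": {"bias": 0.035, "loa_width": 0.25},
    "step_length": {"bias": -0.008, "loa_width": 0.086},
}


def speed_scale(leg_length: float = MEAN_LEG_LENGTH,
                gravity: float = GRAVITY) -> float:
    """Velocity normalisation constant sqrt(g*L) in m/s."""
    return math.sqrt(gravity * leg_length)


def loa_width_ratio(measure_a: str, measure_b: str) -> float:
    """Ratio of published 95% LoA widths of two measures (a over b)."""
    return (BLAND_ALTMAN_TABLE[measure_a]["loa_width"]
            / BLAND_ALTMAN_TABLE[measure_b]["loa_width"])


def mean_condition_icc(measure: str, exclude: tuple[str, ...] = ()) -> float:
    """Mean of the published per-condition ICCs for one measure.

    ``exclude`` drops conditions from the mean (the study quotes the step
    width row mean excluding the Wide condition, where reliability was far
    better than elsewhere).  The pooled "overall" entry is never included.
    """
    vals = [v for cond, v in ICC_TABLE[measure].items()
            if cond != "overall" and cond not in exclude]
    return sum(vals) / len(vals)


def percent_speed_reduction(condition: str = "tandem",
                            system: str = "optical") -> float:
    """Percent reduction of mean walking speed relative to Normal."""
    normal = SUMMARY_TABLE["speed"][system]["normal"][0]
    other = SUMMARY_TABLE["speed"][system][condition][0]
    return 100.0 * (normal - other) / normal
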