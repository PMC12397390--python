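"""Reference in-vivo cohort metadata and published class-level summaries.

The package's simulator and acceptance checks are calibrated against a
20-animal reference cohort (5 vehicle-injected sham controls, 15
6-OHDA-lesioned): per-animal apomorphine-induced rotation rates quantify
the dopaminergic deficit, and class means of the segmental statistics
anchor the simulator's effect sizes. Two animals are excluded from the
accelerometry cohort (one sensor failure, one insufficient lesioning —
the latter also excluded from rotation statistics), so the accelerometry
cohort has D_all = 18 members while the rotation comparison uses 5 + 14
values.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

# animal_id, condition, sensor_id, rotation rpm, in rotation cohort, in accelerometry cohort
_COHORT_ROWS = [
    (1, "sham", "S3", -0.01, True, True),
    (2, "sham", "S4", -0.14, True, True),
    (3, "sham", "S1", 0.99, True, True),
    (4, "sham", "S2", 0.27, True, True),
    (5, "sham", "S5", -0.32, True, True),
    (6, "pd", "S6", 9.00, True, True),
    (7, "pd", "S7", 5.71, True, True),
    (8, "pd", "S8", 7.56, True, True),
    (9, "pd", "S5", 5.48, True, True),
    (10, "pd", "S6", 7.08, True, True),
    (11, "pd", "S1", 9.40, True, False),   # sensor failure during acquisition
    (12, "pd", "S2", 6.58, True, True),
    (13, "pd", "S3", -0.16, False, False),  # insufficient lesioning
    (14, "pd", "S4", 7.76, True, True),
    (15, "pd", "S1", 7.58, True, True),
    (16, "pd", "S2", 7.69, True, True),
    (17, "pd", "S3", 7.55, True, True),
    (18, "pd", "S4", 6.03, True, True),
    (19, "pd", "S6", 7.21, True, True),
    (20, "pd", "S8", 5.82, True, True),
]


def cohort_table() -> pd.DataFrame:
    """Reference cohort metadata as a DataFrame."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=["animal_id", "condition", "sensor_id", "rotation_rpm",
                 "in_rotation_cohort", "in_accel_cohort"],
    )


def rotation_groups() -> tuple[np.ndarray, np.ndarray]:
    """(sham, 6-OHDA) rotation rates of the rotation-validation cohort."""
    df = cohort_table()
    df = df[df["in_rotation_cohort"]]
    sham = df.loc[df["condition"] == "sham", "rotation_rpm"].to_numpy()
    pd_ = df.loc[df["condition"] == "pd", "rotation_rpm"].to_numpy()
    return sham, pd_


# Published class means of the per-animal segment-mean statistics (raw,
# un-normalized scale): simulator calibration anchors.
CLASS_MEANS = {
    "mean_mu": {"sham": 9.822, "pd": 9.818},      # m/s²
    "mean_var": {"sham": 0.279, "pd": 0.163},     # m²/s⁴
    "mean_skew": {"sham": 0.569, "pd": 0.342},
    "mean_kurt": {"sham": 50.258, "pd": 50.798},
}

# Raw p-values of the published test batteries (inputs for the literal
# Holm-Bonferroni recomputation): ascending order MWU, BWS, KS.
VARIANCE_BATTERY_P = [0.013, 0.018, 0.019]
SKEWNESS_BATTERY_P = [0.019, 0.032, 0.061]


def percent_decrease(sham: float, pd_: float) -> float:
    """Percent decrease from the sham to the lesioned class mean."""
    return (sham - pd_) / sham * 100.0


def round_half_up(x, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed tables; Python's
    built-in round is banker's and turns 7.175 into 7.17)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def rotation_means() -> tuple[Fraction, Fraction]:
    """Class means of the rotation rates in exact rational arithmetic.

    The table entries are exact decimals; the lesioned mean is 2009/280 =
    7.175 exactly, a value binary floats cannot represent, so the means are
    kept rational until the final printed-precision rounding."""
    sham, pd_ = rotation_groups()
    f_sham = sum(Fraction(repr(float(v))) for v in sham) / len(sham)
    f_pd = sum(Fraction(repr(float(v))) for v in pd_) / len(pd_)
    return f_sham, f_pd
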