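"""Magnitude, segmentation, segmental moments and per-dataset aggregates.

The analysis reduces each 3-axis trace to the per-sample Euclidean
magnitude (orientation-free), splits it into non-overlapping one-minute
segments (S = 1500 samples at 25 Hz; a 12 h trace gives N = 720 segments)
and characterises every segment by its first four moments:

    μ   = (1/S) Σ m_s
    σ²  = 1/(S−1) Σ (m_s − μ)²
    γ   = [(1/S) Σ (m_s − μ)³] / (σ²)^(3/2)
    κ   = [(1/S) Σ (m_s − μ)⁴] / (σ²)²          (plain, not excess)

Note the deliberate estimator mix: the third/fourth central moments use a
1/S numerator while the denominator is built from the *unbiased* (1/(S−1))
variance. This is not the textbook biased or bias-corrected skewness/
kurtosis — it is kept verbatim because the reference summary values
downstream depend on it.

g-normalization divides each statistic by the matching power of
g = 9.81 m/s² (μ/g, σ²/g², |γ|/g³, κ/g⁴). For γ and κ, which are already
dimensionless, this normalization is dimensionally inconsistent; both raw
and normalized values are therefore carried, and all group comparisons use
the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .io import G, AccelerationRecording, StructuralError

DEFAULT_SEGMENT_LENGTH = 1500  # samples = one minute at 25 Hz


@dataclass
class MagnitudeSeries:
    """Per-sample acceleration magnitude m_i = √(x²+y²+z²), in m/s²."""

    values: np.ndarray
    animal_id: int
    sampling_rate: float = 25.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size

    @property
    def normalized(self) -> np.ndarray:
        """Dimensionless magnitudes m̃ = m/g (≈1 for a resting animal)."""
        return self.values / G


@dataclass
class SegmentStatistics:
    """First four moments of every segment of one dataset.

    ``mu, var, skew, kurt`` are arrays of length N (segments). Constant
    (zero-variance) segments get σ² = 0 and NaN skewness/kurtosis, recorded
    in ``degenerate`` and excluded from downstream means.
    """

    mu: np.ndarray
    var: np.ndarray
    skew: np.ndarray
    kurt: np.ndarray
    segment_length: int
    animal_id: int
    degenerate: np.ndarray = field(default=None)  # bool mask per segment

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = ~np.isfinite(self.skew)
        n = self.mu.size
        if not (self.var.size == self.skew.size == self.kurt.size == n):
            raise StructuralError("moment arrays must share the segment count")

    @property
    def n_segments(self) -> int:
        return self.mu.size

    @property
    def n_degenerate(self) -> int:
        return int(np.count_nonzero(self.degenerate))

    def normalized(self, g: float = G) -> "SegmentStatistics":
        return normalize_moments(self, g)


@dataclass
class DatasetSummary:
    """Per-animal means of the segmental statistics plus the overall variance.

    ``mean_skew`` averages |γ| over non-degenerate segments (absolute
    values, matching the skewness feature used for group testing);
    ``overall_var`` is the variance of the full magnitude series (1/(I−1)
    convention), the input to the outlier rule.
    """

    animal_id: int
    condition: str
    mean_mu: float
    mean_var: float
    mean_skew: float
    mean_kurt: float
    overall_var: float
    n_segments: int
    n_degenerate: int
    rotation_rpm: float | None = None


def compute_magnitude(rec: AccelerationRecording) -> MagnitudeSeries:
    """Per-sample Euclidean norm of the 3-axis acceleration vector."""
    values = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    return MagnitudeSeries(values=values, animal_id=rec.animal_id, sampling_rate=rec.sampling_rate)


def segment_series(m: MagnitudeSeries | np.ndarray, segment_length: int = DEFAULT_SEGMENT_LENGTH) -> np.ndarray:
    """Split a magnitude series into N = ⌊I/S⌋ consecutive segments.

    Returns an (N, S) view-like array; a trailing remainder shorter than S
    is dropped. Raises if the series is shorter than one segment.
    """
    values = m.values if isinstance(m, MagnitudeSeries) else np.asarray(m, dtype=float)
    if segment_length < 2:
        raise StructuralError("segment_length must be ≥ 2")
    n_seg = values.size // segment_length
    if n_seg == 0:
        raise StructuralError(
            f"series of length {values.size} is shorter than one segment ({segment_length})"
        )
    return values[: n_seg * segment_length].reshape(n_seg, segment_length)


def segment_moments(segments: np.ndarray, animal_id: int = 0) -> SegmentStatistics:
    """First four moments per segment (rows of an (N, S) array).

    Accepts a single 1-D segment as well. Zero-variance segments yield
    σ² = 0 with NaN γ, κ and are flagged degenerate.
    """
    seg = np.atleast_2d(np.asarray(segments, dtype=float))
    n, s = seg.shape
    if s < 2:
        raise StructuralError("segments must contain at least 2 samples")
    mu = seg.mean(axis=1)
    dev = seg - mu[:, None]
    var = (dev**2).sum(axis=1) / (s - 1)
    m3 = (dev**3).sum(axis=1) / s
    m4 = (dev**4).sum(axis=1) / s
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = m3 / np.sqrt(var) ** 3
        kurt = m4 / var**2
    degenerate = var == 0
    skew[degenerate] = np.nan
    kurt[degenerate] = np.nan
    return SegmentStatistics(
        mu=mu, var=var, skew=skew, kurt=kurt,
        segment_length=s, animal_id=animal_id, degenerate=degenerate,
    )


def normalize_moments(stats: SegmentStatistics, g: float = G) -> SegmentStatistics:
    """g-normalize segmental moments: μ/g, σ²/g², |γ|/g³, κ/g⁴.

    Applied literally, order-matched powers of g including for the already
    dimensionless γ and κ; skewness enters as its absolute value.
    """
    if not g > 0:
        raise StructuralError("g must be > 0")
    return SegmentStatistics(
        mu=stats.mu / g,
        var=stats.var / g**2,
        skew=np.abs(stats.skew) / g**3,
        kurt=stats.kurt / g**4,
        segment_length=stats.segment_length,
        animal_id=stats.animal_id,
        degenerate=stats.degenerate.copy(),
    )


def dataset_summary(
    stats: SegmentStatistics,
    m: MagnitudeSeries,
    condition: str = "sham",
    rotation_rpm: float | None = None,
) -> DatasetSummary:
    """Per-animal aggregate: segment-mean statistics and overall variance.

    Means are arithmetic over all N segments; degenerate segments are
    excluded from the skewness/kurtosis means (their count is reported).
    The overall variance uses the full untrimmed-by-segmentation series
    with the 1/(I−1) convention.
    """
    if stats.n_segments == 0:
        raise StructuralError("no segments to summarize")
    ok = ~stats.degenerate
    return DatasetSummary(
        animal_id=stats.animal_id,
        condition=condition,
        mean_mu=float(stats.mu.mean()),
        mean_var=float(stats.var.mean()),
        mean_skew=float(np.abs(stats.skew[ok]).mean()) if ok.any() else float("nan"),
        mean_kurt=float(stats.kurt[ok].mean()) if ok.any() else float("nan"),
        overall_var=float(np.var(m.values, ddof=1)),
        n_segments=stats.n_segments,
        n_degenerate=stats.n_degenerate,
        rotation_rpm=rotation_rpm,
    )


def summarize_recording(
    rec: AccelerationRecording,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> tuple[MagnitudeSeries, SegmentStatistics, DatasetSummary]:
    """Convenience: magnitude → segments → moments → summary for one animal."""
    m = compute_magnitude(rec)
    stats = segment_moments(segment_series(m, segment_length), animal_id=rec.animal_id)
    summary = dataset_summary(stats, m, condition=rec.condition, rotation_rpm=rec.rotation_rpm)
    return m, stats, summary


def directional_transforms(rec: AccelerationRecording) -> dict[str, np.ndarray]:
    """Per-axis series, cumulative integrals and spherical angles.

    Velocity and position are cumulative trapezoidal integrals with
    Δt = 1/f_s (initial value 0). Spherical convention: θ = polar angle
    from +z in [0, π], φ = atan2(y, x) in (−π, π]; zero-magnitude samples
    give NaN angles.
    """
    dt = 1.0 / rec.sampling_rate
    out: dict[str, np.ndarray] = {}
    for name, axis in (("x", rec.x), ("y", rec.y), ("z", rec.z)):
        out[name] = axis
        v = cumulative_trapezoid(axis, dx=dt, initial=0.0)
        out[f"v{name}"] = v
        out[f"p{name}"] = cumulative_trapezoid(v, dx=dt, initial=0.0)
    r = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(rec.z / r, -1.0, 1.0))
        phi = np.arctan2(rec.y, rec.x)
    zero = r == 0
    theta[zero] = np.nan
    phi[zero] = np.nan
    out["theta"] = theta
    out["phi"] = phi
    return out
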