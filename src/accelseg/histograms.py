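"""Log-binned histograms of magnitudes and pooled segmental statistics.

Logarithmic bin spacing amplifies differences in the right tail of the
distributions — where the two classes differ most (sham animals produce
more high-acceleration samples). Values are pooled per class across all
segments of all animals; non-positive values (possible for |skewness| at
exactly 0) cannot be log-binned and are excluded with a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_N_BINS = 100


@dataclass
class LogHistogram:
    """Per-class counts over shared, geometrically spaced bin edges.

    Bins are right-open except the last (closed), the numpy convention.
    ``excluded`` counts non-positive or out-of-range values per class.
    """

    edges: np.ndarray
    counts: dict[str, np.ndarray]
    variable: str = ""
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def relative(self) -> dict[str, np.ndarray]:
        """Relative frequencies per class (sum to 1 where nonempty)."""
        out = {}
        for cls, c in self.counts.items():
            total = c.sum()
            out[cls] = c / total if total else c.astype(float)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_left": self.edges[:-1], "bin_right": self.edges[1:]})
        for cls, c in self.counts.items():
            df[f"count_{cls}"] = c
        return df


def log_histogram(
    values_by_class: dict[str, np.ndarray],
    n_bins: int = DEFAULT_N_BINS,
    value_range: tuple[float, float] | None = None,
    variable: str = "",
) -> LogHistogram:
    """Histogram positive values per class over shared logarithmic bins.

    ``value_range`` defaults to (min positive value, max value) across all
    classes. Doubling ``n_bins`` refines each bin exactly in two, so a
    coarse histogram is recoverable by summing adjacent fine bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be ≥ 1")
    cleaned = {
        cls: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
        for cls, v in values_by_class.items()
    }
    if value_range is None:
        positive = [v[v > 0] for v in cleaned.values()]
        pooled = np.concatenate(positive) if positive else np.array([])
        if pooled.size == 0:
            raise ValueError("no positive values to bin")
        lo, hi = float(pooled.min()), float(pooled.max())
        if lo == hi:
            hi = lo * (1 + 1e-9)
    else:
        lo, hi = value_range
    if not (lo > 0 and hi > lo):
        raise ValueError("range must satisfy 0 < lo < hi")

    edges = np.geomspace(lo, hi, n_bins + 1)
    counts: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for cls, v in cleaned.items():
        in_range = v[(v > 0) & (v >= lo) & (v <= hi)]
        excluded[cls] = int(v.size - in_range.size)
        counts[cls], _ = np.histogram(in_range, bins=edges)
    return LogHistogram(edges=edges, counts=counts, variable=variable, excluded=excluded)
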