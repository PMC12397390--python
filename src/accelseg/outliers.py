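"""Outlier screening: PCA latent projection and the MAD-median rule.

Two complementary views flag anomalous datasets before group testing:

* a 2-D principal-component projection of the cohort magnitude matrix
  (diagnostic — anomalous animals separate visibly from the compact bulk);
* the MAD-median rule on the per-dataset overall variance σ²_d, applied
  separately within each condition class:

      |σ²_d − median(σ²)| / (MAD(σ²)/0.6745) > K,   K = √χ²₀.₉₇₅,₁ ≈ 2.24

  where MAD is the median absolute deviation from the median and 0.6745
  makes MAD/0.6745 a consistent estimator of the standard deviation under
  normality.

Automated exclusion uses the MAD rule alone; the latent projection is
reported for inspection (visual confirmation cannot be automated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .io import DatasetMatrix, StructuralError

MAD_CONSISTENCY = 0.6745


def mad_threshold(quantile: float = 0.975) -> float:
    """K = √(χ² quantile, 1 df); ≈ 2.24 at the default 0.975 quantile."""
    return float(np.sqrt(chi2.ppf(quantile, df=1)))


@dataclass
class LatentRepresentation:
    """First principal components of the cohort magnitude matrix.

    ``coordinates`` holds the scores T = (M − column means)·V, one row per
    dataset; singular values are those of the column-centered matrix.
    """

    coordinates: np.ndarray  # D × n_components
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    animal_ids: list[int]
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        n = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, columns=[f"pc{i+1}" for i in range(n)])
        df.insert(0, "animal_id", self.animal_ids)
        df.insert(1, "condition", self.labels)
        return df


@dataclass
class OutlierReport:
    """Per-dataset MAD-median scores, threshold and flags.

    ``degenerate_mad`` marks classes where MAD = 0 (all-equal variances);
    there no finite score exists and nothing is flagged in that class.
    """

    animal_ids: list[int]
    labels: list[str]
    scores: np.ndarray
    threshold: float
    flagged: np.ndarray
    degenerate_mad: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_ids,
                "condition": self.labels,
                "score": self.scores,
                "flagged": self.flagged,
            }
        )

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flagged))


def pca_latent(matrix: DatasetMatrix, n_components: int = 2) -> LatentRepresentation:
    """Project the cohort matrix onto its first principal components.

    Columns (sample positions) are mean-centered before the singular value
    decomposition; the scores are the first ``n_components`` columns of UΣ.
    """
    D, I = matrix.values.shape
    if D < 2:
        raise StructuralError("PCA needs at least 2 datasets")
    if n_components > min(D, I):
        raise StructuralError(f"n_components={n_components} exceeds min(D, I)={min(D, I)}")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(matrix.values)
    return LatentRepresentation(
        coordinates=coords,
        singular_values=pca.singular_values_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        animal_ids=list(matrix.animal_ids),
        labels=list(matrix.labels),
    )


def mad_median_scores(
    overall_variances: np.ndarray | list[float],
    animal_ids: list[int],
    labels: list[str],
    quantile: float = 0.975,
) -> OutlierReport:
    """MAD-median rule scores, computed separately within each class.

    A dataset is flagged when its score exceeds K = √χ²(quantile, 1 df).
    If a class's MAD is zero the rule is degenerate there: scores are set
    to 0, nothing is flagged, and the class is listed in
    ``degenerate_mad`` rather than dividing by zero silently.
    """
    values = np.asarray(overall_variances, dtype=float)
    if values.size != len(animal_ids) or values.size != len(labels):
        raise StructuralError("variances, ids and labels must align")
    K = mad_threshold(quantile)
    scores = np.zeros_like(values)
    degenerate: dict[str, bool] = {}
    labels_arr = np.asarray(labels)
    for cls in dict.fromkeys(labels):  # preserve order
        idx = labels_arr == cls
        if np.count_nonzero(idx) < 3:
            raise StructuralError(f"class {cls!r} needs ≥ 3 datasets for the MAD rule")
        v = values[idx]
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            degenerate[cls] = True
            scores[idx] = 0.0
        else:
            degenerate[cls] = False
            scores[idx] = np.abs(v - med) / (mad / MAD_CONSISTENCY)
    flagged = scores > K
    return OutlierReport(
        animal_ids=list(animal_ids),
        labels=list(labels),
        scores=scores,
        threshold=K,
        flagged=flagged,
        degenerate_mad=degenerate,
    )


def exclude_outliers(items: list, report: OutlierReport) -> tuple[list, pd.DataFrame]:
    """Drop flagged datasets from a per-animal list (summaries, recordings…).

    ``items`` must align with the report rows by ``animal_id`` attribute or
    dict key. Returns the reduced list and an exclusion log (animal_id,
    condition, score) for the flagged datasets.
    """
    flagged_ids = {
        aid for aid, fl in zip(report.animal_ids, report.flagged) if fl
    }

    def _aid(obj):
        return obj["animal_id"] if isinstance(obj, dict) else obj.animal_id

    kept = [obj for obj in items if _aid(obj) not in flagged_ids]
    log = report.to_frame()
    log = log[log["flagged"]].drop(columns="flagged").reset_index(drop=True)
    return kept, log
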