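"""Discrimination and calibration metrics.

AUROC is the probability that a randomly sampled outcome patient receives a
higher predicted risk than a randomly sampled non-outcome patient; tied
predictions count one half.  Calibration-in-the-large is the observed event
rate minus the mean predicted risk (0 means mean-level agreement), and the
calibration gradient is the slope of observed event fractions on mean
predicted risks across equal-count prediction quantile bins (1 means the
spread of the predictions matches the spread of the observed risk; values
well above 1 indicate systematically too-small predictions, the overfitting
signature).

Predictions are not required to lie in [0, 1]: the unnormalised
AUROC-weighted fusion can push combined risks outside the unit interval and
is deliberately evaluated as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError

__all__ = [
    "ScoredPredictions",
    "CalibrationSummary",
    "auroc",
    "auroc_pairwise_oracle",
    "calibration_in_the_large",
    "calibration_gradient",
    "auroc_difference",
]


@dataclass(frozen=True)
class ScoredPredictions:
    """Paired risk predictions and binary ground-truth labels."""

    predictions: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.predictions, dtype=float)
        y = np.asarray(self.labels)
        if p.shape != y.shape or p.ndim != 1:
            raise ValueError("predictions and labels must be 1-d arrays of equal length")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary")
        object.__setattr__(self, "predictions", p)
        object.__setattr__(self, "labels", np.asarray(y, dtype=np.int8))

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CalibrationSummary:
    citl: float
    gradient: float
    n_bins: int

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _check_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise UndefinedMetricError("AUROC undefined: labels contain a single class")


def auroc(sp: ScoredPredictions) -> float:
    """Rank-based (Mann–Whitney) AUROC with half-credit for ties."""
    y = sp.labels
    _check_both_classes(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(sp.predictions)  # average ranks handle ties at 0.5/pair
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auroc_pairwise_oracle(sp: ScoredPredictions) -> float:
    """Literal pairwise AUROC: mean over all (outcome, non-outcome) pairs.

    Quadratic-cost reference used to validate :func:`auroc`; guarded to
    modest sizes.
    """
    if sp.n > 10_000:
        raise ValueError("pairwise oracle guarded to n <= 10,000")
    y = sp.labels
    _check_both_classes(y)
    pos = sp.predictions[y == 1]
    neg = sp.predictions[y == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def calibration_in_the_large(sp: ScoredPredictions) -> float:
    """Observed event rate minus mean predicted risk."""
    if sp.n == 0:
        raise UndefinedMetricError("calibration undefined on empty input")
    return float(sp.labels.mean() - sp.predictions.mean())


def calibration_gradient(sp: ScoredPredictions, n_bins: int = 100) -> float:
    """OLS slope of observed event fraction on mean prediction over quantile bins.

    Patients are sorted by prediction and split into ``n_bins`` equal-count
    bins (fewer automatically when n is small: at most n // 2, at least 2).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if sp.n < 4:
        raise UndefinedMetricError("calibration gradient needs at least 4 patients")
    bins = max(2, min(n_bins, sp.n // 2))
    order = np.argsort(sp.predictions, kind="mergesort")
    mean_pred = np.array([sp.predictions[idx].mean() for idx in np.array_split(order, bins)])
    obs_frac = np.array([sp.labels[idx].mean() for idx in np.array_split(order, bins)])
    if np.ptp(mean_pred) == 0:
        raise UndefinedMetricError("calibration gradient undefined: binned predictions constant")
    slope, _ = np.polyfit(mean_pred, obs_frac, 1)
    return float(slope)


def calibration_summary(sp: ScoredPredictions, n_bins: int = 100) -> CalibrationSummary:
    bins = max(2, min(n_bins, sp.n // 2))
    return CalibrationSummary(
        citl=calibration_in_the_large(sp),
        gradient=calibration_gradient(sp, n_bins=n_bins),
        n_bins=bins,
    )


def auroc_difference(external_auroc: float, internal_auroc: float) -> float:
    """External-validation AUROC minus the internal-benchmark AUROC.

    Values near 0 indicate the model transported without discrimination loss;
    negative values quantify the loss relative to a model developed inside
    the validation database itself.
    """
    for v in (external_auroc, internal_auroc):
        if not 0.0 <= v <= 1.0:
            raise ValueError("AUROC values must lie in [0, 1]")
    return float(external_auroc - internal_auroc)
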