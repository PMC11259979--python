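"""The four benchmarked missing-data handling strategies.

* ``uniform`` — leave the data untouched and marginalise missing entries in
  the likelihood with a uniform density 1/z_max (the model-based approach;
  a pass-through here, consumed by the likelihood as ``missing_mode``).
* ``deletion`` — drop every subject with any missing biomarker.
* ``mean`` — impute each missing cell with the column mean over observed
  subjects.
* ``knn`` — impute with the mean of the biomarker over the K nearest
  neighbours, using either summary-statistic features (per-subject mean,
  range, standard deviation of observed values) or the raw Z-scored rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import DataMatrix

logger = logging.getLogger(__name__)

__all__ = ["StrategySpec", "apply_strategy", "knn_impute"]

STRATEGY_KINDS = ("uniform", "deletion", "mean", "knn")


@dataclass(frozen=True)
class StrategySpec:
    """Which strategy to use, with the KNN knobs where relevant."""

    kind: str
    knn_k: int = 5
    knn_features: str = "summary_stats"

    def __post_init__(self):
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"kind must be one of {STRATEGY_KINDS}")
        if self.kind == "knn":
            if self.knn_k < 1:
                raise ValueError("knn_k must be >= 1")
            if self.knn_features not in ("summary_stats", "zscored"):
                raise ValueError("knn_features must be 'summary_stats' or 'zscored'")

    @property
    def missing_mode(self) -> str:
        """Likelihood missing mode to use downstream of this strategy."""
        return "uniform" if self.kind == "uniform" else "none"

    def label(self) -> str:
        if self.kind == "knn":
            variant = "feature matrix" if self.knn_features == "summary_stats" else "Z-scored"
            return f"knn ({variant})"
        return self.kind


def apply_strategy(data: DataMatrix, spec: StrategySpec):
    """Transform ``data`` per the strategy; returns (data, kept_row_indices).

    ``kept_row_indices`` indexes the rows of the input that survive (only
    deletion drops rows).  All strategies except ``uniform`` return a matrix
    with an all-true mask.
    """
    J = data.n_subjects
    all_rows = np.arange(J)
    if spec.kind == "uniform":
        return data, all_rows
    if spec.kind == "deletion":
        keep = np.nonzero(data.mask.all(axis=1))[0]
        if keep.size == 0:
            raise ValueError("deletion removed every subject")
        return data.subset(keep), keep
    if spec.kind == "mean":
        observed_any = data.mask.any(axis=0)
        if not observed_any.all():
            bad = int(np.nonzero(~observed_any)[0][0])
            raise ValueError(f"biomarker column {bad} has no observed values")
        col_mean = np.nanmean(data.values, axis=0)
        filled = np.where(data.mask, data.values, col_mean[None, :])
        return DataMatrix(values=filled, subject_ids=data.subject_ids), all_rows
    return knn_impute(data, spec.knn_k, spec.knn_features), all_rows


def _summary_features(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-subject [mean, range, sd] of the observed values (3 features)."""
    feats = np.full((values.shape[0], 3), np.nan)
    for j in range(values.shape[0]):
        obs = values[j, mask[j]]
        if obs.size == 0:
            continue
        feats[j] = (obs.mean(), obs.max() - obs.min(), obs.std())
    return feats


def knn_impute(data: DataMatrix, k: int, features: str = "summary_stats") -> DataMatrix:
    """K-nearest-neighbour imputation, cell by cell against the ORIGINAL matrix.

    For each missing cell (j, i), other subjects with biomarker i observed
    are ranked by Euclidean distance between feature vectors and the cell is
    imputed as the mean of biomarker i over the k nearest.  All lookups read
    the pre-imputation matrix, so the iteration order over missing cells
    cannot influence the result.

    Feature variants: ``summary_stats`` (the 3-vector mean/range/sd of each
    subject's observed values) or ``zscored`` (the raw Z-score rows, with
    distances over pairwise-complete coordinates rescaled by
    sqrt(total / shared) so pairs with different overlap stay comparable).
    Distance ties keep the lower subject index first; with fewer than k
    eligible neighbours all of them are used and a warning is logged.
    """
    if features not in ("summary_stats", "zscored"):
        raise ValueError("features must be 'summary_stats' or 'zscored'")
    values, mask = data.values, data.mask
    J, I = values.shape
    observed_any = mask.any(axis=0)
    if not observed_any.all():
        bad = int(np.nonzero(~observed_any)[0][0])
        raise ValueError(f"biomarker column {bad} has no observed values")
    filled = np.where(mask, values, 0.0).copy()

    if features == "summary_stats":
        feats = _summary_features(values, mask)

        def distances(j):
            d = np.sqrt(((feats - feats[j]) ** 2).sum(axis=1))
            d[np.isnan(feats).any(axis=1) | np.isnan(feats[j]).any()] = np.inf
            return d
    else:
        def distances(j):
            shared = mask & mask[j]
            n_shared = shared.sum(axis=1)
            diff = np.where(shared, values - values[j], 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.sqrt((diff ** 2).sum(axis=1) * (I / n_shared))
            d[n_shared == 0] = np.inf
            return d

    out = filled.copy()
    for j, i in zip(*np.nonzero(~mask)):
        eligible = np.nonzero(mask[:, i] & (np.arange(J) != j))[0]
        if eligible.size == 0:
            raise ValueError(f"no subject observes biomarker {i}; cannot impute")
        d = distances(j)[eligible]
        finite = np.isfinite(d)
        if not finite.any():
            raise ValueError(f"no comparable neighbour for subject {j}, biomarker {i}")
        eligible, d = eligible[finite], d[finite]
        if eligible.size < k:
            logger.warning("only %d eligible neighbours (< k=%d) for subject %d, "
                           "biomarker %d", eligible.size, k, j, i)
            chosen = eligible
        else:
            order = np.argsort(d, kind="stable")  # ties keep lower index
            chosen = eligible[order[:k]]
        out[j, i] = values[chosen, i].mean()
    return DataMatrix(values=out, subject_ids=data.subject_ids)
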