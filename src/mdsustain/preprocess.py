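"""Control-referenced covariate correction and Z-scoring of raw biomarkers.

A linear regression of each raw biomarker on the covariates (e.g. age, sex,
education, total intracranial volume) is estimated in the control group only;
covariates without a significant association are dropped and the model
refitted.  The model is then propagated to all subjects: residuals are
standardized against the control residual distribution, and biomarkers that
decrease with disease progression are sign-flipped so that every Z-score
increases with abnormality.  Event levels and the per-biomarker ceiling are
derived from the resulting Z-score distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import BiomarkerConfig, DataMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateModel",
    "fit_covariate_model",
    "correct_and_zscore",
    "derive_event_config",
]


@dataclass
class CovariateModel:
    """Per-biomarker regression coefficients and control residual moments."""

    biomarkers: tuple
    covariate_names: tuple
    intercept: dict        # biomarker -> float
    coefficients: dict     # biomarker -> {covariate: coef} (retained only)
    control_mean: dict     # biomarker -> mean of control residuals
    control_sd: dict       # biomarker -> SD of control residuals (ddof=1)
    direction: dict        # biomarker -> +1 (increases with disease) or -1

    def __post_init__(self):
        for b in self.biomarkers:
            if self.control_sd[b] <= 0:
                raise ValueError(f"control SD must be positive for {b!r}")
            if self.direction[b] not in (+1, -1):
                raise ValueError(f"direction must be +1 or -1 for {b!r}")


def _fit_ols(y: np.ndarray, X: pd.DataFrame, retained, biomarker: str):
    design = sm.add_constant(X[retained], has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"singular design for biomarker {biomarker!r}; "
                         f"collinear covariates among {retained}")
    return sm.OLS(y, design).fit()


def _ols_with_selection(y: np.ndarray, X: pd.DataFrame, alpha: float,
                        biomarker: str, iterate: bool):
    """OLS with one-pass (or iterated) backward elimination at level alpha."""
    retained = list(X.columns)
    fit = _fit_ols(y, X, retained, biomarker)
    while retained:
        drop = [c for c in retained if fit.pvalues[c] >= alpha]
        if not drop:
            break
        retained = [c for c in retained if c not in drop]
        fit = _fit_ols(y, X, retained, biomarker)
        if not iterate:
            break
    return fit, retained


def fit_covariate_model(raw: pd.DataFrame, covariates: pd.DataFrame,
                        control_flag, directions: dict = None,
                        alpha: float = 0.05,
                        iterate_elimination: bool = False) -> CovariateModel:
    """Fit per-biomarker OLS corrections in the control population.

    Covariates whose coefficient has two-sided p >= ``alpha`` are dropped and
    the model refitted on the retained set (single pass by default).  The
    control residual mean and SD define the Z-scoring reference, so controls
    score mean 0 / SD 1 by construction.  ``directions`` maps biomarker name
    to +1 (increases with disease, default) or -1 (decreases; sign-flipped).
    """
    control_flag = np.asarray(control_flag, dtype=bool)
    if control_flag.shape[0] != raw.shape[0]:
        raise ValueError("control_flag length must match raw rows")
    directions = directions or {}
    biomarkers = tuple(raw.columns)
    cov_names = tuple(covariates.columns)
    intercept, coefs, cmean, csd, direc = {}, {}, {}, {}, {}
    cov_ok = ~covariates.isna().any(axis=1).to_numpy()
    for b in biomarkers:
        y_all = raw[b].to_numpy(dtype=float)
        rows = control_flag & cov_ok & np.isfinite(y_all)
        if rows.sum() < 2 + len(cov_names):
            raise ValueError(f"too few complete control subjects for {b!r}")
        fit, retained = _ols_with_selection(
            y_all[rows], covariates.loc[rows], alpha, b, iterate_elimination)
        intercept[b] = float(fit.params["const"])
        coefs[b] = {c: float(fit.params[c]) for c in retained}
        resid = fit.resid
        cmean[b] = float(np.mean(resid))
        csd[b] = float(np.std(resid, ddof=1))
        direc[b] = int(directions.get(b, +1))
    return CovariateModel(biomarkers=biomarkers, covariate_names=cov_names,
                          intercept=intercept, coefficients=coefs,
                          control_mean=cmean, control_sd=csd, direction=direc)


def correct_and_zscore(raw: pd.DataFrame, covariates: pd.DataFrame,
                       model: CovariateModel) -> DataMatrix:
    """Propagate the control model to all subjects and Z-score.

    z = direction * (residual - control mean) / control SD.  Missing raw
    cells stay missing; a subject with a missing covariate that a biomarker's
    model retains gets a missing Z-score for that biomarker (logged).
    """
    J = raw.shape[0]
    values = np.full((J, len(model.biomarkers)), np.nan)
    for col, b in enumerate(model.biomarkers):
        if b not in raw.columns:
            raise ValueError(f"biomarker {b!r} absent from raw table")
        y = raw[b].to_numpy(dtype=float)
        retained = list(model.coefficients[b])
        cov = covariates[retained].to_numpy(dtype=float) if retained else np.empty((J, 0))
        cov_ok = ~np.isnan(cov).any(axis=1)
        pred = model.intercept[b] + (
            cov @ np.asarray([model.coefficients[b][c] for c in retained])
            if retained else 0.0)
        usable = np.isfinite(y) & cov_ok
        n_dropped = int((np.isfinite(y) & ~cov_ok).sum())
        if n_dropped:
            logger.warning("%d subjects lose biomarker %r to missing covariates",
                           n_dropped, b)
        resid = y[usable] - (pred[usable] if retained else model.intercept[b])
        values[usable, col] = model.direction[b] * (
            (resid - model.control_mean[b]) / model.control_sd[b])
    ids = tuple(str(i) for i in raw.index)
    return DataMatrix(values=values, subject_ids=ids)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def derive_event_config(zscored: DataMatrix,
                        candidate_levels=(1.0, 2.0, 3.0, 5.0),
                        min_observed: int = 20,
                        sigma: float = 1.0,
                        biomarker_names=None) -> BiomarkerConfig:
    """Per-biomarker event levels and ceiling from the Z-score distribution.

    The ceiling z_max is the rounded (half away from zero) 95th percentile of
    the observed Z-scores (linear-interpolation empirical quantile); the
    event levels are the candidate levels strictly below z_max.  Biomarkers
    whose ceiling does not exceed the smallest candidate level carry no
    event and are excluded with a warning.
    """
    if biomarker_names is None:
        biomarker_names = [f"bm{i}" for i in range(zscored.n_biomarkers)]
    names, levels_out, zmax_out = [], [], []
    for i in range(zscored.n_biomarkers):
        obs = zscored.values[zscored.mask[:, i], i]
        if obs.size < min_observed:
            raise ValueError(f"biomarker column {i} has fewer than "
                             f"{min_observed} observed values")
        z_max = _round_half_away(float(np.percentile(obs, 95)))
        levels = tuple(z for z in candidate_levels if z < z_max)
        if not levels:
            logger.warning("biomarker column %d uninformative (z_max=%s <= "
                           "smallest candidate level); excluded", i, z_max)
            continue
        names.append(str(biomarker_names[i]))
        levels_out.append(levels)
        zmax_out.append(float(z_max))
    if not names:
        raise ValueError("no informative biomarkers left")
    return BiomarkerConfig(names=tuple(names), event_levels=tuple(levels_out),
                           z_max=tuple(zmax_out),
                           sigma=tuple(sigma for _ in names))
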