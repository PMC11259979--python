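"""Synthetic ground-truth generator for the subtype/stage benchmark.

The default settings reproduce the benchmark design used to validate the
missing-data likelihood: 500 subjects, 10 biomarkers with event levels
(1, 2, 3) and ceiling z_max = 5, three subtypes with a random monotonic event
ordering each and mixture fractions (4/9, 3/9, 2/9), unit observation noise
with no between-biomarker covariance, stages drawn uniformly, and missing
cells deleted completely at random (150 cells = 3% or 2000 cells = 40% of
the 5000 datapoints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import random_sequence
from .model import BiomarkerConfig, DataMatrix, SubtypeModel

__all__ = [
    "SimulationTruth",
    "subtype_fractions",
    "simulate_model",
    "simulate_subjects",
    "inject_missingness",
]


@dataclass
class SimulationTruth:
    """Generating model and per-subject ground truth labels."""

    model: SubtypeModel
    subject_subtype: np.ndarray  # 0-based subtype index, length J
    subject_stage: np.ndarray    # stage in 0..N, length J
    complete_data: np.ndarray    # J x I matrix before any masking


def subtype_fractions(C: int) -> np.ndarray:
    """Mixture fractions f_c = (2 + (C - c)) / (2C + sum_c (C - c)), c = 1..C.

    Gives (4/9, 3/9, 2/9) at C = 3 and sums to 1 for any C.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    c = np.arange(1, C + 1)
    num = 2.0 + (C - c)
    return num / num.sum()


def simulate_model(C: int = 3, I: int = 10, levels=(1.0, 2.0, 3.0),
                   z_max: float = 5.0, rng: np.random.Generator = None,
                   sigma: float = 1.0) -> SubtypeModel:
    """Random generating model: an independent uniform-random valid ordering
    per subtype, benchmark mixture fractions, and identity noise structure."""
    if rng is None:
        rng = np.random.default_rng()
    if C < 1 or I < 1:
        raise ValueError("C and I must be >= 1")
    config = BiomarkerConfig(
        names=tuple(f"bm{i}" for i in range(I)),
        event_levels=tuple(tuple(levels) for _ in range(I)),
        z_max=tuple(float(z_max) for _ in range(I)),
        sigma=tuple(float(sigma) for _ in range(I)),
    )
    sequences = tuple(random_sequence(config, rng) for _ in range(C))
    return SubtypeModel(sequences=sequences, fractions=subtype_fractions(C),
                        config=config)


def simulate_subjects(model: SubtypeModel, J: int = 500,
                      rng: np.random.Generator = None,
                      continuous_t: bool = False):
    """Draw subjects from the model; returns (DataMatrix, SimulationTruth).

    Subtype c is drawn with probability f_c and the stage uniformly on
    {0..N}.  Each observation is the trajectory value at the subject's
    timepoint plus Normal(0, sigma_i) noise.  By default the timepoint is the
    stage-representative midpoint k + 0.5 (the same convention as the
    likelihood quadrature, so stage 0 subjects sit just above the Z = 0
    anchor); with ``continuous_t`` the timepoint is instead uniform within
    the stage interval [k, k+1].
    """
    if rng is None:
        rng = np.random.default_rng()
    if J < 1:
        raise ValueError("J must be >= 1")
    cfg = model.config
    N = cfg.n_events
    subtype = rng.choice(model.n_subtypes, size=J, p=model.fractions)
    stage = rng.integers(0, N + 1, size=J)
    offset = rng.uniform(0.0, 1.0, size=J) if continuous_t else np.full(J, 0.5)
    t = stage + offset
    values = np.empty((J, cfg.n_biomarkers))
    sigma = np.asarray(cfg.sigma)
    from .model import trajectory_value

    for c in range(model.n_subtypes):
        rows = np.nonzero(subtype == c)[0]
        if rows.size == 0:
            continue
        for i in range(cfg.n_biomarkers):
            values[rows, i] = trajectory_value(model.sequences[c], cfg, i, t[rows])
    values = values + rng.normal(0.0, 1.0, size=values.shape) * sigma[None, :]
    data = DataMatrix(values=values,
                      subject_ids=tuple(f"sim{j:05d}" for j in range(J)))
    truth = SimulationTruth(model=model, subject_subtype=subtype,
                            subject_stage=stage, complete_data=values.copy())
    return data, truth


def inject_missingness(data: DataMatrix, n_missing: int,
                       rng: np.random.Generator = None) -> DataMatrix:
    """Delete exactly ``n_missing`` distinct cells uniformly at random (MCAR)."""
    if rng is None:
        rng = np.random.default_rng()
    J, I = data.values.shape
    if not (0 <= n_missing <= J * I):
        raise ValueError(f"n_missing must lie in [0, {J * I}]")
    cells = rng.choice(J * I, size=n_missing, replace=False)
    mask = data.mask.copy().ravel()
    mask[cells] = False
    mask = mask.reshape(J, I)
    values = data.values.copy()
    values[~mask] = np.nan
    return DataMatrix(values=values, mask=mask, subject_ids=data.subject_ids)
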