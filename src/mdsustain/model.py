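"""Piecewise-linear Z-score progression model and missing-data-aware likelihood.

The model describes disease progression as an ordered sequence of N Z-score
events.  Each event is a biomarker reaching a new Z-score threshold; each
biomarker's expected trajectory g_i(t) is piecewise linear on an arbitrary
timeline t in [0, N+1], anchored at (0, 0) and (N+1, z_max_i), passing
through (p, z) for each of its events at sequence position p.

A subject at stage k (k = 0..N) has reached exactly the first k events of
their subtype's sequence.  Observed values are modelled as Gaussian around
g_i(t) with per-biomarker noise sigma_i; a missing value contributes a
constant uniform density 1 / z_max_i, which cancels from subtype and stage
posteriors and therefore leaves the estimated progression pattern untouched
while still letting the observed biomarkers inform the assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "BiomarkerConfig",
    "EventSequence",
    "SubtypeModel",
    "DataMatrix",
    "SubjectPosterior",
    "trajectory_value",
    "observation_density",
    "stage_likelihoods",
    "stage_log_likelihoods",
    "total_log_likelihood",
    "subject_posteriors",
    "credible_set",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class BiomarkerConfig:
    """Per-biomarker event levels, Z-score ceiling and observation noise.

    Parameters
    ----------
    names
        Biomarker identifiers, one per biomarker (column order of the data).
    event_levels
        For each biomarker, a strictly increasing tuple of Z-score thresholds
        (the biomarker's events).  All levels must lie in (0, z_max).
    z_max
        Per-biomarker trajectory ceiling: the Z-score each trajectory ends at,
        and the range of the uniform density used for missing values.
    sigma
        Per-biomarker Gaussian observation noise, in Z units.  Defaults to 1
        for every biomarker (data are control-referenced Z-scores).
    """

    names: tuple
    event_levels: tuple
    z_max: tuple
    sigma: tuple = None

    def __post_init__(self):
        names = tuple(str(n) for n in self.names)
        levels = tuple(tuple(float(z) for z in lv) for lv in self.event_levels)
        z_max = tuple(float(z) for z in self.z_max)
        sigma = self.sigma
        if sigma is None:
            sigma = tuple(1.0 for _ in names)
        sigma = tuple(float(s) for s in sigma)
        if not (len(names) == len(levels) == len(z_max) == len(sigma)):
            raise ValueError("names, event_levels, z_max and sigma must have equal length")
        if len(names) == 0:
            raise ValueError("at least one biomarker required")
        if len(set(names)) != len(names):
            raise ValueError("duplicate biomarker names")
        for name, lv, zm, sg in zip(names, levels, z_max, sigma):
            if zm <= 0:
                raise ValueError(f"z_max must be positive for biomarker {name!r}")
            if sg <= 0:
                raise ValueError(f"sigma must be positive for biomarker {name!r}")
            if len(lv) == 0:
                raise ValueError(f"biomarker {name!r} needs at least one event level")
            if any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError(f"event levels must be strictly increasing for {name!r}")
            if lv[0] <= 0 or lv[-1] >= zm:
                raise ValueError(f"event levels must lie in (0, z_max) for {name!r}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "event_levels", levels)
        object.__setattr__(self, "z_max", z_max)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_biomarkers(self) -> int:
        return len(self.names)

    @property
    def n_events(self) -> int:
        """Total event count N = sum of per-biomarker level counts."""
        return sum(len(lv) for lv in self.event_levels)

    def event_list(self):
        """All (biomarker index, level index) pairs in config order."""
        return [
            (i, r)
            for i in range(self.n_biomarkers)
            for r in range(len(self.event_levels[i]))
        ]

    def event_labels(self):
        return [
            f"{self.names[i]}:z={self.event_levels[i][r]:g}"
            for i, r in self.event_list()
        ]


@dataclass(frozen=True)
class EventSequence:
    """One subtype's strict ordering of all N Z-score events.

    ``events`` is a length-N tuple of (biomarker index, level index) pairs;
    the event at tuple index p-1 occurs at timeline position p.  Within any
    biomarker, events must appear in increasing level order so that the
    trajectory is monotone.
    """

    events: tuple
    config: BiomarkerConfig

    def __post_init__(self):
        events = tuple((int(i), int(r)) for i, r in self.events)
        object.__setattr__(self, "events", events)
        expected = set(self.config.event_list())
        if set(events) != expected or len(events) != len(expected):
            raise ValueError("sequence must contain each (biomarker, level) event exactly once")
        seen_level: dict = {}
        for i, r in events:
            prev = seen_level.get(i, -1)
            if r != prev + 1:
                raise ValueError("within-biomarker events must appear in increasing level order")
            seen_level[i] = r
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    def positions_by_biomarker(self):
        """For each biomarker, the 1-based sequence positions of its events."""
        pos = [[] for _ in range(self.config.n_biomarkers)]
        for p, (i, _r) in enumerate(self.events, start=1):
            pos[i].append(p)
        return [np.asarray(p, dtype=float) for p in pos]

    def event_positions(self) -> dict:
        """Mapping (biomarker, level index) -> 1-based position."""
        return {ev: p for p, ev in enumerate(self.events, start=1)}


@dataclass(frozen=True)
class SubtypeModel:
    """Mixture of C event sequences with mixing fractions and a stage prior."""

    sequences: tuple
    fractions: np.ndarray
    config: BiomarkerConfig
    stage_prior: np.ndarray = None

    def __post_init__(self):
        sequences = tuple(self.sequences)
        if len(sequences) == 0:
            raise ValueError("at least one sequence required")
        for s in sequences:
            if s.config is not self.config and s.config != self.config:
                raise ValueError("all sequences must share the model's config")
        fractions = np.asarray(self.fractions, dtype=float)
        if fractions.shape != (len(sequences),):
            raise ValueError("fractions length must equal number of sequences")
        if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        n_stages = self.config.n_events + 1
        prior = self.stage_prior
        if prior is None:
            prior = np.full(n_stages, 1.0 / n_stages)
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (n_stages,):
            raise ValueError("stage_prior must have length N+1")
        if np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError("stage_prior must be nonnegative and sum to 1")
        object.__setattr__(self, "sequences", sequences)
        object.__setattr__(self, "fractions", fractions)
        object.__setattr__(self, "stage_prior", prior)

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    @property
    def n_stages(self) -> int:
        return self.config.n_events + 1

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "biomarkers": list(cfg.names),
            "event_levels": [list(lv) for lv in cfg.event_levels],
            "z_max": list(cfg.z_max),
            "sigma": list(cfg.sigma),
            "sequences": [[[i, r] for i, r in s.events] for s in self.sequences],
            "fractions": [float(f) for f in self.fractions],
            "stage_prior": [float(p) for p in self.stage_prior],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        cfg = BiomarkerConfig(
            names=tuple(d["biomarkers"]),
            event_levels=tuple(tuple(lv) for lv in d["event_levels"]),
            z_max=tuple(d["z_max"]),
            sigma=tuple(d["sigma"]),
        )
        seqs = tuple(
            EventSequence(tuple((i, r) for i, r in s), cfg) for s in d["sequences"]
        )
        return cls(
            sequences=seqs,
            fractions=np.asarray(d["fractions"], dtype=float),
            config=cfg,
            stage_prior=np.asarray(d["stage_prior"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "SubtypeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DataMatrix:
    """Subjects-by-biomarkers Z-score matrix with an explicit missingness mask.

    ``values`` holds NaN wherever ``mask`` is False; entries where the mask is
    True must be finite.
    """

    values: np.ndarray
    mask: np.ndarray = None
    subject_ids: tuple = None

    def __post_init__(self):
        values = np.array(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x biomarkers)")
        mask = self.mask
        if mask is None:
            mask = np.isfinite(values)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape must match values")
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("values must be finite wherever observed")
        values = values.copy()
        values[~mask] = np.nan
        ids = self.subject_ids
        if ids is None:
            ids = tuple(f"S{j}" for j in range(values.shape[0]))
        ids = tuple(str(s) for s in ids)
        if len(ids) != values.shape[0]:
            raise ValueError("subject_ids length must equal number of rows")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject IDs")
        self.values = values
        self.mask = mask
        self.subject_ids = ids

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return self.values.shape[1]

    def subset(self, rows) -> "DataMatrix":
        rows = np.asarray(rows)
        return DataMatrix(
            values=self.values[rows],
            mask=self.mask[rows],
            subject_ids=tuple(np.asarray(self.subject_ids, dtype=object)[rows]),
        )


@dataclass
class SubjectPosterior:
    """Per-subject joint posterior over (subtype, stage) with ML assignments.

    ``prob`` has shape (J, C, N+1) and each subject's table sums to 1.
    ``ml_subtype`` / ``ml_stage`` are the arg-max assignments (lowest index on
    ties); subjects whose ML stage is 0 show no detectable abnormality and are
    flagged "normal appearing" (not subtypable).
    """

    prob: np.ndarray
    ml_subtype: np.ndarray
    ml_stage: np.ndarray
    subject_ids: tuple

    @property
    def normal_appearing(self) -> np.ndarray:
        return self.ml_stage == 0

    def subtype_marginals(self) -> np.ndarray:
        return self.prob.sum(axis=2)

    def credible_sets(self, mass: float = 0.95):
        return [credible_set(self.prob[j], mass) for j in range(self.prob.shape[0])]


# ---------------------------------------------------------------------------
# Trajectories and densities


def _trajectory_knots(sequence: EventSequence, biomarker: int):
    cfg = sequence.config
    n1 = cfg.n_events + 1
    pos = []
    for p, (i, r) in enumerate(sequence.events, start=1):
        if i == biomarker:
            pos.append((p, cfg.event_levels[i][r]))
    t = np.array([0.0] + [p for p, _ in pos] + [float(n1)])
    z = np.array([0.0] + [z for _, z in pos] + [cfg.z_max[biomarker]])
    return t, z


def trajectory_value(sequence: EventSequence, config: BiomarkerConfig,
                     biomarker: int, t) -> np.ndarray:
    """Expected Z-score g_i(t) of ``biomarker`` at timeline coordinate t.

    Linear interpolation through (0, 0), each of the biomarker's events at
    its sequence position, and (N+1, z_max).  Nondecreasing in t.
    """
    if sequence.config != config:
        raise ValueError("sequence and config disagree")
    if not (0 <= biomarker < config.n_biomarkers):
        raise LookupError(f"unknown biomarker index {biomarker}")
    t_arr = np.asarray(t, dtype=float)
    n1 = config.n_events + 1
    if np.any(t_arr < 0) or np.any(t_arr > n1):
        raise ValueError(f"t must lie in [0, {n1}]")
    knots_t, knots_z = _trajectory_knots(sequence, biomarker)
    out = np.interp(t_arr, knots_t, knots_z)
    return out if out.ndim else float(out)


def _stage_means(sequence: EventSequence, quad_points: int = 1) -> np.ndarray:
    """g_i at each stage's representative timepoint(s).

    Midpoint rule by default: one point t = k + 0.5 per unit-width stage
    interval [k, k+1].  Returns array (I, N+1) for quad_points == 1, else
    (I, N+1, quad_points) at the interior midpoints of equal sub-intervals.
    """
    cfg = sequence.config
    n_stages = cfg.n_events + 1
    k = np.arange(n_stages, dtype=float)
    if quad_points == 1:
        t = k + 0.5
    else:
        offs = (np.arange(quad_points) + 0.5) / quad_points
        t = (k[:, None] + offs[None, :]).ravel()
    mu = np.empty((cfg.n_biomarkers, t.size))
    for i in range(cfg.n_biomarkers):
        knots_t, knots_z = _trajectory_knots(sequence, i)
        mu[i] = np.interp(t, knots_t, knots_z)
    if quad_points > 1:
        mu = mu.reshape(cfg.n_biomarkers, n_stages, quad_points)
    return mu


def observation_density(x, biomarker: int, t, sequence: EventSequence,
                        config: BiomarkerConfig, missing_mode: str = "uniform"):
    """Density of one observation at timeline coordinate t.

    Observed value: Normal(g_i(t), sigma_i).  Missing value (NaN/None) under
    ``missing_mode='uniform'``: the constant 1 / z_max_i, independent of t and
    of the sequence.  Under ``missing_mode='none'`` a missing value is a
    contract violation (the caller promised complete data).
    """
    if missing_mode not in ("uniform", "none"):
        raise ValueError("missing_mode must be 'uniform' or 'none'")
    missing = x is None or (np.isscalar(x) and np.isnan(x))
    if missing:
        if missing_mode != "uniform":
            raise ValueError("missing value encountered with missing_mode='none'")
        return 1.0 / config.z_max[biomarker]
    g = trajectory_value(sequence, config, biomarker, t)
    s = config.sigma[biomarker]
    return np.exp(-0.5 * ((x - g) / s) ** 2) / (s * np.sqrt(2.0 * np.pi))


def stage_log_likelihoods(data: DataMatrix, sequence: EventSequence,
                          config: BiomarkerConfig, missing_mode: str = "uniform",
                          quad_points: int = 1) -> np.ndarray:
    """Log of the per-stage data likelihood, one row per subject.

    Entry (j, k) is the log of the stage-k integral of the product over
    biomarkers of the observation densities, approximated by the midpoint
    rule over t in [k, k+1] (interval width 1); the stage prior is NOT
    included.  With ``quad_points`` > 1 the integral uses that many equally
    spaced midpoints per stage.
    """
    if missing_mode not in ("uniform", "none"):
        raise ValueError("missing_mode must be 'uniform' or 'none'")
    if data.n_biomarkers != config.n_biomarkers:
        raise ValueError("data column count must equal config biomarker count")
    if missing_mode == "none" and not data.mask.all():
        raise ValueError("missing values present with missing_mode='none'")
    values = np.where(data.mask, data.values, 0.0)
    sigma = np.asarray(config.sigma)
    mu = _stage_means(sequence, quad_points)  # (I, K) or (I, K, Q)
    n_stages = config.n_events + 1
    if data.n_subjects == 0:
        return np.empty((0, n_stages))
    if quad_points == 1:
        # expand the Gaussian log-density so the stage dimension factors into
        # two small matrix products: sum_i -((x - mu)/sigma)^2/2 - log(sigma
        # sqrt(2pi)) = const_j + (x/sigma^2) . mu - (1/sigma^2) . mu^2 / 2
        xs = values * data.mask / (sigma * sigma)[None, :]
        ms = data.mask / (sigma * sigma)[None, :]
        const = (-0.5 * values * xs
                 - data.mask * (np.log(sigma) + _LOG_SQRT_2PI)[None, :]).sum(axis=1)
        out = const[:, None] + xs @ mu - 0.5 * (ms @ (mu * mu))
    else:
        z = (values[:, :, None, None] - mu[None]) / sigma[None, :, None, None]
        log_pdf = -0.5 * z * z - np.log(sigma)[None, :, None, None] - _LOG_SQRT_2PI
        log_pdf = np.where(data.mask[:, :, None, None], log_pdf, 0.0)
        per_point = log_pdf.sum(axis=1)  # (J, K, Q)
        out = logsumexp(per_point, axis=2) - np.log(quad_points)
    if missing_mode == "uniform":
        miss_const = -np.log(np.asarray(config.z_max))  # log 1/z_max per biomarker
        out = out + ((~data.mask) * miss_const[None, :]).sum(axis=1)[:, None]
    return out


def stage_likelihoods(data: DataMatrix, sequence: EventSequence,
                      config: BiomarkerConfig, missing_mode: str = "uniform",
                      quad_points: int = 1) -> np.ndarray:
    """Natural-scale stage likelihood matrix P(x_j | sequence, stage k)."""
    return np.exp(stage_log_likelihoods(data, sequence, config, missing_mode,
                                        quad_points))


def _log_joint(data: DataMatrix, model: SubtypeModel, missing_mode: str,
               quad_points: int = 1) -> np.ndarray:
    """log [ f_c * prior_k * P(x_j | seq_c, k) ] with shape (J, C, K)."""
    log_prior = np.log(np.where(model.stage_prior > 0, model.stage_prior, 1.0))
    log_prior = np.where(model.stage_prior > 0, log_prior, -np.inf)
    with np.errstate(divide="ignore"):
        log_f = np.log(model.fractions)
    parts = [
        stage_log_likelihoods(data, seq, model.config, missing_mode, quad_points)
        for seq in model.sequences
    ]
    stacked = np.stack(parts, axis=1)  # (J, C, K)
    return stacked + log_f[None, :, None] + log_prior[None, None, :]


def total_log_likelihood(data: DataMatrix, model: SubtypeModel,
                         missing_mode: str = "uniform",
                         quad_points: int = 1) -> float:
    """Total log-likelihood: sum over subjects of the log mixture marginal."""
    lj = _log_joint(data, model, missing_mode, quad_points)
    return float(logsumexp(lj.reshape(data.n_subjects, -1), axis=1).sum())


def subject_posteriors(data: DataMatrix, model: SubtypeModel,
                       missing_mode: str = "uniform",
                       quad_points: int = 1) -> SubjectPosterior:
    """Joint posterior over (subtype, stage) per subject, plus ML assignments.

    Computed in log space; each subject's (C, N+1) table is normalized to sum
    to 1.  Arg-max ties break to the lowest index, so results are
    deterministic.  The ML stage is the stage of the joint arg-max cell.
    """
    lj = _log_joint(data, model, missing_mode, quad_points)
    J = data.n_subjects
    flat = lj.reshape(J, -1)
    log_norm = logsumexp(flat, axis=1)
    prob = np.exp(lj - log_norm[:, None, None])
    flat_idx = np.argmax(flat, axis=1)  # lowest index on ties (np.argmax)
    n_stages = model.n_stages
    ml_subtype = flat_idx // n_stages
    ml_stage = flat_idx % n_stages
    return SubjectPosterior(prob=prob, ml_subtype=ml_subtype, ml_stage=ml_stage,
                            subject_ids=data.subject_ids)


def credible_set(prob_table: np.ndarray, mass: float = 0.95):
    """Smallest set of (subtype, stage) cells reaching cumulative ``mass``.

    Cells are taken in decreasing probability order; ties are broken by flat
    (subtype-major) cell index via a stable sort, so the result is
    deterministic and of minimal size (e.g. a uniform posterior over 20 cells
    at mass 0.95 yields exactly 19 cells).
    Returns a list of (subtype, stage) index pairs.
    """
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must lie in (0, 1]")
    p = np.asarray(prob_table, dtype=float)
    flat = p.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    # first index where cumulative mass reached (tolerate fp rounding at mass=1)
    reached = np.nonzero(csum >= mass - 1e-12)[0]
    stop = reached[0] if reached.size else flat.size - 1
    if mass >= 1.0:
        keep = order[flat[order] > 0]
    else:
        keep = order[:stop + 1]
    n_stages = p.shape[1]
    return [(int(ix // n_stages), int(ix % n_stages)) for ix in keep]
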