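"""Model estimation: greedy sequence optimization, EM, hierarchical splitting
and Metropolis-Hastings uncertainty estimation.

The fitting strategy follows the event-based-model family: maximum-likelihood
event orderings are found by hill climbing with random restarts, subtype
mixtures are estimated by EM over subject responsibilities, the number of
subtypes grows hierarchically by splitting clusters of the previous solution,
and positional uncertainty in the sequences is characterised by MCMC over
event permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .model import (
    BiomarkerConfig,
    DataMatrix,
    EventSequence,
    SubtypeModel,
    stage_log_likelihoods,
    subject_posteriors,
    total_log_likelihood,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitOptions",
    "FitResult",
    "random_sequence",
    "optimize_sequence",
    "fit_em",
    "fit_hierarchical",
    "mcmc_uncertainty",
]


@dataclass(frozen=True)
class FitOptions:
    """Hyper-parameters of the fitting pipeline.

    Parameters
    ----------
    n_startpoints
        Random restarts of the greedy sequence search.
    n_em_iter_max
        Cap on EM iterations.
    em_tol
        Stop EM when the log-likelihood improves by less than this (nats).
    n_mcmc
        Metropolis-Hastings iterations for uncertainty estimation.
    n_split_trials
        Random bipartitions tried when splitting a cluster.
    seed
        Seed of the single generator all randomness flows from (used when no
        explicit generator is passed).
    """

    n_startpoints: int = 25
    n_em_iter_max: int = 100
    em_tol: float = 1e-6
    n_mcmc: int = 100_000
    n_split_trials: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_startpoints, self.n_em_iter_max, self.n_mcmc,
               self.n_split_trials) < 1:
            raise ValueError("all counts must be >= 1")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")


@dataclass
class FitResult:
    """Maximum-likelihood model plus MCMC uncertainty summaries."""

    model: SubtypeModel
    log_likelihood: float
    seq_samples: np.ndarray = None      # (S, C, N) event index per position
    frac_samples: np.ndarray = None     # (S, C)
    ll_samples: np.ndarray = None       # (S,)
    positional_variance: list = None    # per subtype (N, N): event x position

    @property
    def n_subtypes(self) -> int:
        return self.model.n_subtypes


# ---------------------------------------------------------------------------
# Sequence search


def random_sequence(config: BiomarkerConfig, rng: np.random.Generator) -> EventSequence:
    """Uniform-random key per event, with within-biomarker level order restored."""
    events = config.event_list()
    n = len(events)
    order = rng.permutation(n)
    # slot each biomarker's events into its assigned positions in level order
    placed = [None] * n
    per_bm_positions: dict = {}
    for pos, idx in enumerate(order):
        per_bm_positions.setdefault(events[idx][0], []).append(pos)
    for i, positions in per_bm_positions.items():
        levels = [ev for ev in events if ev[0] == i]
        for pos, ev in zip(sorted(positions), levels):
            placed[pos] = ev
    return EventSequence(tuple(placed), config)


class _SeqObjective:
    """Cached weighted log-likelihood of an event ordering.

    Precomputes the data-side terms of the Gaussian log-density expansion
    (see :func:`mdsustain.model.stage_log_likelihoods`) so that evaluating a
    candidate sequence costs only the trajectory means and two small matrix
    products.  Used by the hill climber, which evaluates thousands of
    candidate orderings per fit.
    """

    def __init__(self, data: DataMatrix, config: BiomarkerConfig,
                 missing_mode: str):
        if missing_mode == "none" and not data.mask.all():
            raise ValueError("missing values present with missing_mode='none'")
        sigma = np.asarray(config.sigma)
        values = np.where(data.mask, data.values, 0.0)
        self.config = config
        self.xs = values * data.mask / (sigma * sigma)[None, :]
        self.ms = data.mask / (sigma * sigma)[None, :]
        log_sqrt_2pi = 0.5 * np.log(2.0 * np.pi)
        self.const = (-0.5 * values * self.xs
                      - data.mask * (np.log(sigma) + log_sqrt_2pi)[None, :]).sum(axis=1)
        if missing_mode == "uniform":
            miss_const = -np.log(np.asarray(config.z_max))
            self.const = self.const + ((~data.mask) * miss_const[None, :]).sum(axis=1)
        n_stages = config.n_events + 1
        self.t_mid = np.arange(n_stages) + 0.5
        self.log_prior = np.full(n_stages, -np.log(n_stages))
        self._n1 = float(n_stages)

    def _mu(self, events) -> np.ndarray:
        cfg = self.config
        I = cfg.n_biomarkers
        pos = [[0.0] for _ in range(I)]
        lev = [[0.0] for _ in range(I)]
        for p, (i, r) in enumerate(events, start=1):
            pos[i].append(float(p))
            lev[i].append(cfg.event_levels[i][r])
        mu = np.empty((I, self.t_mid.size))
        for i in range(I):
            pos[i].append(self._n1)
            lev[i].append(cfg.z_max[i])
            mu[i] = np.interp(self.t_mid, pos[i], lev[i])
        return mu

    def stage_loglik(self, events) -> np.ndarray:
        mu = self._mu(events)
        return self.const[:, None] + self.xs @ mu - 0.5 * (self.ms @ (mu * mu))

    def stage_marginal(self, events) -> np.ndarray:
        """Per-subject log P(x_j | sequence) under the uniform stage prior."""
        sll = self.stage_loglik(events)
        mx = sll.max(axis=1)
        # hand-rolled log-sum-exp: this sits in the hill climber's hot loop
        return (mx + np.log(np.exp(sll - mx[:, None]).sum(axis=1))
                + self.log_prior[0])

    def weighted(self, events, weights) -> float:
        return float(np.dot(weights, self.stage_marginal(events)))


def _weighted_seq_loglik(data: DataMatrix, weights, sequence: EventSequence,
                         log_prior, missing_mode: str) -> float:
    sll = stage_log_likelihoods(data, sequence, sequence.config, missing_mode)
    marg = logsumexp(sll + log_prior[None, :], axis=1)
    return float(np.dot(weights, marg))


def _valid_insertions(events: list, ev) -> range:
    """Insertion indices into ``events`` keeping biomarker ``ev`` monotone."""
    i, r = ev
    lo, hi = 0, len(events)
    for idx, (bi, br) in enumerate(events):
        if bi == i:
            if br < r:
                lo = idx + 1
            elif br > r:
                hi = min(hi, idx)
                break
    return range(lo, hi + 1)


def _hill_climb(objective: _SeqObjective, weights, sequence: EventSequence,
                rng: np.random.Generator):
    """Remove-and-reinsert ascent: per event, try every valid reinsertion and
    keep the best, looping until a full pass makes no improvement."""
    cfg = sequence.config
    events = list(sequence.events)
    current_ll = objective.weighted(events, weights)
    n = len(events)
    improved = True
    while improved:
        improved = False
        for ev_idx in rng.permutation(n):
            ev = events[ev_idx]
            rest = events[:ev_idx] + events[ev_idx + 1:]
            best_ll, best_events = current_ll, None
            for q in _valid_insertions(rest, ev):
                if q == ev_idx:
                    continue  # identity move
                cand = rest[:q] + [ev] + rest[q:]
                ll = objective.weighted(cand, weights)
                if ll > best_ll + 1e-12:
                    best_ll, best_events = ll, cand
            if best_events is not None:
                events = best_events
                current_ll = best_ll
                improved = True
    return EventSequence(tuple(events), cfg), current_ll


def optimize_sequence(data: DataMatrix, weights, config: BiomarkerConfig,
                      opts: FitOptions = FitOptions(),
                      rng: np.random.Generator = None,
                      missing_mode: str = "uniform",
                      init: EventSequence = None) -> EventSequence:
    """Best event ordering found by greedy ascent from random start points.

    ``weights`` are per-subject responsibilities (nonnegative); the objective
    is the weighted sum of per-subject log stage-marginals under a uniform
    stage prior.  When ``init`` is given it is used as an extra start point.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    objective = _SeqObjective(data, config, missing_mode)
    starts = [random_sequence(config, rng) for _ in range(opts.n_startpoints)]
    if init is not None:
        starts.append(init)
    best_seq, best_ll = None, -np.inf
    for s in starts:
        seq, ll = _hill_climb(objective, weights, s, rng)
        if ll > best_ll:
            best_seq, best_ll = seq, ll
    return best_seq


# ---------------------------------------------------------------------------
# EM over subtype memberships


def _responsibilities(data: DataMatrix, model: SubtypeModel, missing_mode: str,
                      objective: _SeqObjective = None):
    """Posterior subtype memberships r_jc and the total log-likelihood."""
    with np.errstate(divide="ignore"):
        log_f = np.log(model.fractions)
        log_prior = np.where(model.stage_prior > 0,
                             np.log(np.maximum(model.stage_prior, 1e-300)),
                             -np.inf)
    if objective is None:
        slls = [stage_log_likelihoods(data, seq, model.config, missing_mode)
                for seq in model.sequences]
    else:
        slls = [objective.stage_loglik(list(seq.events)) for seq in model.sequences]
    per_c = np.stack([
        logsumexp(sll + log_prior[None, :], axis=1) for sll in slls
    ], axis=1)  # (J, C)
    joint = per_c + log_f[None, :]
    norm = logsumexp(joint, axis=1)
    return np.exp(joint - norm[:, None]), float(norm.sum())


def fit_em(data: DataMatrix, C: int, init_model: SubtypeModel,
           opts: FitOptions = FitOptions(), rng: np.random.Generator = None,
           missing_mode: str = "uniform"):
    """EM refinement of a C-subtype model.

    Alternates (a) responsibilities, (b) fraction update, (c) per-subtype
    sequence re-optimization by hill climbing from the current sequence with
    responsibility weights.  The log-likelihood trace is nondecreasing up to
    numerical tolerance.  Returns (model, log_likelihood, trace).
    """
    if init_model.n_subtypes != C:
        raise ValueError("init_model must have C sequences")
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    model = init_model
    objective = _SeqObjective(data, model.config, missing_mode)
    trace = []
    prev_ll = -np.inf
    for _ in range(opts.n_em_iter_max):
        resp, ll = _responsibilities(data, model, missing_mode, objective)
        trace.append(ll)
        if ll - prev_ll < opts.em_tol and trace[:-1]:
            break
        prev_ll = ll
        fractions = resp.mean(axis=0)
        sequences = []
        for c in range(C):
            w = resp[:, c]
            if w.sum() < 1e-8:
                logger.warning("empty cluster %d re-seeded with a random sequence", c)
                sequences.append(random_sequence(model.config, rng))
                fractions[c] = 1.0 / data.n_subjects
                continue
            seq, _ = _hill_climb(objective, w, model.sequences[c], rng)
            sequences.append(seq)
        fractions = np.maximum(fractions, 0)
        fractions = fractions / fractions.sum()
        model = SubtypeModel(sequences=tuple(sequences), fractions=fractions,
                             config=model.config, stage_prior=model.stage_prior)
    final_ll = total_log_likelihood(data, model, missing_mode)
    trace.append(final_ll)
    return model, final_ll, np.asarray(trace)


# ---------------------------------------------------------------------------
# Hierarchical model building


def fit_hierarchical(data: DataMatrix, C_max: int,
                     opts: FitOptions = FitOptions(),
                     rng: np.random.Generator = None,
                     missing_mode: str = "uniform",
                     config: BiomarkerConfig = None,
                     run_mcmc: bool = False) -> list:
    """Fit models with C = 1..C_max subtypes by hierarchical cluster splitting.

    C = 1 is fitted directly by multi-start greedy search.  Each larger C is
    initialized by splitting, in turn, every cluster of the (C-1) solution:
    ``n_split_trials`` random bipartitions of the cluster's ML-assigned
    subjects (plus the trivial duplicate split, which guarantees the C-model
    likelihood never falls below the (C-1) one) each seed an internal
    2-subtype fit, the best split initializes a full EM refit over all
    subjects, and the best refit over clusters is kept.

    Returns a list of :class:`FitResult`, one per C.  MCMC uncertainty is run
    per model only when ``run_mcmc`` is set.
    """
    if C_max < 1:
        raise ValueError("C_max must be >= 1")
    if config is None:
        raise ValueError("config is required")
    if rng is None:
        rng = np.random.default_rng(opts.seed)

    results = []
    seq1 = optimize_sequence(data, np.ones(data.n_subjects), config, opts, rng,
                             missing_mode)
    model = SubtypeModel(sequences=(seq1,), fractions=np.array([1.0]),
                         config=config)
    ll = total_log_likelihood(data, model, missing_mode)
    results.append(_finalize(data, model, ll, opts, rng, missing_mode, run_mcmc))

    split_opts = replace(opts, n_startpoints=1,
                         n_em_iter_max=min(opts.n_em_iter_max, 30))

    def _with_cluster_split(prev, c, s_a, s_b, fa, fb):
        seqs = list(prev.sequences)
        fracs = list(prev.fractions)
        fc = fracs.pop(c)
        seqs.pop(c)
        seqs.extend([s_a, s_b])
        fracs.extend([fc * fa, fc * fb])
        fr = np.maximum(np.asarray(fracs), 1e-12)
        return SubtypeModel(sequences=tuple(seqs), fractions=fr / fr.sum(),
                            config=config)

    for C in range(2, C_max + 1):
        prev = results[-1].model
        prev_ll = results[-1].log_likelihood
        assign = subject_posteriors(data, prev, missing_mode).ml_subtype
        best_model, best_ll = None, -np.inf
        for c in range(prev.n_subtypes):
            members = np.nonzero(assign == c)[0]
            if members.size < 2:
                continue
            # best bipartition of this cluster by the inner 2-subtype fit
            sub = data.subset(members)
            best_split, best_split_ll = None, -np.inf
            for _ in range(opts.n_split_trials):
                half = rng.random(members.size) < 0.5
                if half.all() or not half.any():
                    flip = rng.integers(members.size)
                    half[flip] = not half[flip]
                s_a = optimize_sequence(sub.subset(np.nonzero(half)[0]),
                                        np.ones(int(half.sum())), config,
                                        split_opts, rng, missing_mode)
                s_b = optimize_sequence(sub.subset(np.nonzero(~half)[0]),
                                        np.ones(int((~half).sum())), config,
                                        split_opts, rng, missing_mode)
                init = SubtypeModel(sequences=(s_a, s_b),
                                    fractions=np.array([0.5, 0.5]),
                                    config=config)
                m2, ll2, _ = fit_em(sub, 2, init, split_opts, rng, missing_mode)
                if ll2 > best_split_ll:
                    best_split, best_split_ll = m2, ll2
            if best_split is None:
                continue
            init_model = _with_cluster_split(
                prev, c, best_split.sequences[0], best_split.sequences[1],
                best_split.fractions[0], best_split.fractions[1])
            m, ll, _ = fit_em(data, C, init_model, opts, rng, missing_mode)
            if ll > best_ll:
                best_model, best_ll = m, ll
        if best_model is None and prev.n_subtypes < C:
            warnings.warn(f"could not split any cluster at C={C}; stopping early")
            break
        if best_ll < prev_ll:
            # duplicating the largest cluster reproduces the previous model's
            # likelihood exactly, keeping the per-C likelihood nondecreasing
            c = int(np.argmax(prev.fractions))
            best_model = _with_cluster_split(prev, c, prev.sequences[c],
                                             prev.sequences[c], 0.5, 0.5)
            best_ll = total_log_likelihood(data, best_model, missing_mode)
        results.append(_finalize(data, best_model, best_ll, opts, rng,
                                 missing_mode, run_mcmc))
    return results


def _finalize(data, model, ll, opts, rng, missing_mode, run_mcmc):
    if not run_mcmc:
        return FitResult(model=model, log_likelihood=ll)
    seqs, fracs, lls, pv = mcmc_uncertainty(data, model, opts, rng, missing_mode)
    return FitResult(model=model, log_likelihood=ll, seq_samples=seqs,
                     frac_samples=fracs, ll_samples=lls, positional_variance=pv)


# ---------------------------------------------------------------------------
# MCMC uncertainty


def mcmc_uncertainty(data: DataMatrix, model: SubtypeModel,
                     opts: FitOptions = FitOptions(),
                     rng: np.random.Generator = None,
                     missing_mode: str = "uniform"):
    """Metropolis-Hastings over event orderings and mixture fractions.

    Each iteration proposes moving one randomly chosen event of one randomly
    chosen subtype to a random valid position, jointly with a Gaussian
    perturbation of the fractions (sd 0.01, clipped at 0 and renormalized),
    and accepts with probability min(1, L_new / L_old) on the total data
    likelihood.

    Returns ``(seq_samples, frac_samples, ll_samples, positional_variance)``
    where ``seq_samples[s, c]`` lists the event index (config order) at each
    position, and ``positional_variance[c][e, p]`` is the fraction of samples
    placing event ``e`` at position ``p + 1``.
    """
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    if opts.n_mcmc < 1:
        raise ValueError("n_mcmc must be >= 1")
    C = model.n_subtypes
    N = model.config.n_events
    objective = _SeqObjective(data, model.config, missing_mode)
    with np.errstate(divide="ignore"):
        log_prior = np.where(model.stage_prior > 0,
                             np.log(np.maximum(model.stage_prior, 1e-300)),
                             -np.inf)

    def stage_marginal(events):
        # log P(x_j | sequence) marginalised over the stage prior, (J,)
        x = objective.stage_loglik(events) + log_prior[None, :]
        mx = x.max(axis=1)
        return mx + np.log(np.exp(x - mx[:, None]).sum(axis=1))

    def total_ll(marg_cols, fracs):
        with np.errstate(divide="ignore"):
            log_f = np.log(fracs)
        return float(logsumexp(np.stack(marg_cols, axis=1) + log_f[None, :],
                               axis=1).sum())

    cur_seqs = [list(s.events) for s in model.sequences]
    cur_fracs = np.asarray(model.fractions, dtype=float)
    cur_marg = [stage_marginal(e) for e in cur_seqs]
    cur_ll = total_ll(cur_marg, cur_fracs)

    seq_samples = np.empty((opts.n_mcmc, C, N), dtype=np.int16)
    frac_samples = np.empty((opts.n_mcmc, C))
    ll_samples = np.empty(opts.n_mcmc)
    lookup = {ev: n for n, ev in enumerate(model.config.event_list())}
    cur_idx = [np.asarray([lookup[e] for e in ev], dtype=np.int16)
               for ev in cur_seqs]

    for it in range(opts.n_mcmc):
        c = int(rng.integers(C))
        ev_idx = int(rng.integers(N))
        events = cur_seqs[c]
        ev = events[ev_idx]
        rest = events[:ev_idx] + events[ev_idx + 1:]
        choices = list(_valid_insertions(rest, ev))
        q = choices[int(rng.integers(len(choices)))]
        prop_events = rest[:q] + [ev] + rest[q:]

        prop_fracs = cur_fracs + rng.normal(0.0, 0.01, size=C)
        prop_fracs = np.maximum(prop_fracs, 0.0)
        total = prop_fracs.sum()
        prop_fracs = cur_fracs.copy() if total <= 0 else prop_fracs / total

        prop_marg_c = stage_marginal(prop_events)
        marg_cols = cur_marg[:c] + [prop_marg_c] + cur_marg[c + 1:]
        prop_ll = total_ll(marg_cols, prop_fracs)
        if np.log(rng.random()) < prop_ll - cur_ll:
            cur_seqs[c] = prop_events
            cur_marg[c] = prop_marg_c
            cur_fracs, cur_ll = prop_fracs, prop_ll
            cur_idx[c] = np.asarray([lookup[e] for e in prop_events],
                                    dtype=np.int16)
        for cc in range(C):
            seq_samples[it, cc] = cur_idx[cc]
        frac_samples[it] = cur_fracs
        ll_samples[it] = cur_ll

    positional_variance = []
    for cc in range(C):
        pv = np.zeros((N, N))
        for p in range(N):
            counts = np.bincount(seq_samples[:, cc, p], minlength=N)
            pv[:, p] += counts
        positional_variance.append(pv / opts.n_mcmc)
    return seq_samples, frac_samples, ll_samples, positional_variance
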