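"""Evaluation metrics and the missing-data strategy benchmark.

Sequence recovery is scored with a normalized Kendall similarity (1 = same
ordering, 0 = fully reversed), subtyping with percent-correct after optimal
cluster matching, and staging with the mean and SD across individuals of the
absolute difference between estimated and true stage.  The benchmark harness
re-runs the full simulate / corrupt / handle-missingness / fit / score loop
for each strategy and missingness level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .fitting import FitOptions, fit_hierarchical
from .model import DataMatrix, EventSequence, SubjectPosterior, SubtypeModel, subject_posteriors
from .simulate import inject_missingness, simulate_model, simulate_subjects
from .strategies import StrategySpec, apply_strategy

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "sequence_similarity",
    "match_clusters",
    "subtype_accuracy",
    "staging_error",
    "evaluate_fit",
    "longitudinal_consistency",
    "modality_ablation",
    "run_benchmark",
    "summarize_benchmark",
]


@dataclass
class EvaluationReport:
    """Scores of one fitted model against simulation ground truth."""

    kendall_similarity: np.ndarray   # per matched true cluster
    subtype_accuracy: float          # percent
    staging_error_mean: float        # stages (pooled)
    staging_error_sd: float
    staging_by_subtype: dict         # true subtype -> (mean, sd)
    cluster_matching: np.ndarray     # est cluster -> true cluster

    @property
    def kendall_mean(self) -> float:
        return float(np.mean(self.kendall_similarity))


def sequence_similarity(est: EventSequence, truth: EventSequence) -> float:
    """Normalized Kendall similarity: 1 - discordant pairs / (N choose 2).

    1 means identical orderings, 0 a fully reversed ordering.
    """
    pos_est = est.event_positions()
    pos_true = truth.event_positions()
    if set(pos_est) != set(pos_true):
        raise ValueError("sequences must be over the same event set")
    events = list(pos_true)
    a = np.asarray([pos_est[e] for e in events])
    b = np.asarray([pos_true[e] for e in events])
    n = len(events)
    if n < 2:
        return 1.0
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    discordant = int(np.sum((da * db < 0)) // 2)
    return 1.0 - discordant / (n * (n - 1) / 2)


def match_clusters(est_assign, true_assign, C: int) -> np.ndarray:
    """Bijection est -> true maximizing total agreement (Hungarian algorithm).

    Returns an array ``perm`` with ``perm[est_label] = true_label``.
    """
    est = np.asarray(est_assign)
    true = np.asarray(true_assign)
    if est.shape != true.shape:
        raise ValueError("label vectors must cover the same subjects")
    if est.size and (est.max() >= C or true.max() >= C):
        raise ValueError("labels exceed C")
    confusion = np.zeros((C, C))
    np.add.at(confusion, (est, true), 1.0)
    rows, cols = linear_sum_assignment(-confusion)
    perm = np.empty(C, dtype=int)
    perm[rows] = cols
    return perm


def subtype_accuracy(est_assign, true_assign, matching,
                     exclude: np.ndarray = None) -> float:
    """Percent of scored subjects whose matched estimated subtype is correct.

    ``exclude`` marks subjects left out of scoring (by default none); in the
    pipeline the "normal appearing" ML-stage-0 subjects are excluded, since
    subjects with no detectable abnormality are not subtypable.
    """
    est = np.asarray(est_assign)
    true = np.asarray(true_assign)
    keep = np.ones(est.shape[0], dtype=bool) if exclude is None else ~np.asarray(exclude)
    if keep.sum() == 0:
        raise ValueError("no scored subjects; accuracy undefined")
    mapped = np.asarray(matching)[est[keep]]
    return 100.0 * float(np.mean(mapped == true[keep]))


def staging_error(est_stage, true_stage, true_subtype=None):
    """Mean and sample SD across individuals of |estimated - true| stage.

    Returns ``(mean, sd)`` pooled, or with ``true_subtype`` a dict mapping
    subtype -> (mean, sd) plus the pooled pair under key ``"pooled"``.
    """
    est = np.asarray(est_stage, dtype=float)
    true = np.asarray(true_stage, dtype=float)
    if est.shape != true.shape or est.size == 0:
        raise ValueError("stage vectors must be equal-length and nonempty")
    err = np.abs(est - true)

    def _ms(e):
        return float(e.mean()), float(e.std(ddof=1)) if e.size > 1 else 0.0

    if true_subtype is None:
        return _ms(err)
    out = {"pooled": _ms(err)}
    for c in np.unique(np.asarray(true_subtype)):
        out[int(c)] = _ms(err[np.asarray(true_subtype) == c])
    return out


def evaluate_fit(model: SubtypeModel, data: DataMatrix, truth,
                 kept_rows=None, missing_mode: str = "uniform",
                 exclude_stage0: bool = True) -> EvaluationReport:
    """Score a fitted model against simulation truth.

    ``kept_rows`` maps the rows of ``data`` back to rows of the original
    simulated cohort (needed after subject deletion).
    """
    if kept_rows is None:
        kept_rows = np.arange(data.n_subjects)
    kept_rows = np.asarray(kept_rows)
    post = subject_posteriors(data, model, missing_mode)
    true_sub = np.asarray(truth.subject_subtype)[kept_rows]
    true_stage = np.asarray(truth.subject_stage)[kept_rows]
    C = truth.model.n_subtypes
    if model.n_subtypes != C:
        raise ValueError("fitted and true models must have the same subtype count")
    perm = match_clusters(post.ml_subtype, true_sub, C)
    kendall = np.empty(C)
    for c_est in range(C):
        kendall[perm[c_est]] = sequence_similarity(
            model.sequences[c_est], truth.model.sequences[perm[c_est]])
    exclude = post.normal_appearing if exclude_stage0 else None
    acc = subtype_accuracy(post.ml_subtype, true_sub, perm, exclude=exclude)
    by_sub = staging_error(post.ml_stage, true_stage, true_subtype=true_sub)
    pooled = by_sub.pop("pooled")
    return EvaluationReport(
        kendall_similarity=kendall,
        subtype_accuracy=acc,
        staging_error_mean=pooled[0],
        staging_error_sd=pooled[1],
        staging_by_subtype=by_sub,
        cluster_matching=perm,
    )


def longitudinal_consistency(baseline: SubjectPosterior, followups,
                             mass: float = 0.95, prob_bins=(0.5, 0.75, 1.0)):
    """Consistency of assignments across visits.

    A follow-up is subtype-consistent if it keeps the baseline ML subtype or
    the baseline was "normal appearing" (stage 0, not subtypable);
    stage-consistent if the ML stage did not regress; credible-interval
    consistent if the two visits' ``mass`` credible sets intersect.  Returns
    percentages over all (subject, follow-up) pairs, plus the subtype
    percentages stratified by the baseline ML-subtype probability.
    """
    if isinstance(followups, SubjectPosterior):
        followups = [followups]
    base_sets = baseline.credible_sets(mass)
    n_pairs = 0
    ok_subtype = ok_stage = ok_ci = 0
    base_prob = baseline.subtype_marginals()[
        np.arange(baseline.prob.shape[0]), baseline.ml_subtype]
    bin_tot = np.zeros(len(prob_bins))
    bin_ok = np.zeros(len(prob_bins))
    for fu in followups:
        if fu.subject_ids != baseline.subject_ids:
            raise ValueError("follow-up subjects must match baseline")
        fu_sets = fu.credible_sets(mass)
        for j in range(baseline.prob.shape[0]):
            n_pairs += 1
            sub_ok = (baseline.normal_appearing[j]
                      or fu.ml_subtype[j] == baseline.ml_subtype[j])
            ok_subtype += sub_ok
            ok_stage += fu.ml_stage[j] >= baseline.ml_stage[j]
            ok_ci += bool(set(base_sets[j]) & set(fu_sets[j]))
            b = np.searchsorted(np.asarray(prob_bins), base_prob[j], side="left")
            b = min(b, len(prob_bins) - 1)
            bin_tot[b] += 1
            bin_ok[b] += sub_ok
    if n_pairs == 0:
        raise ValueError("no follow-up pairs")
    with np.errstate(invalid="ignore"):
        by_bin = np.where(bin_tot > 0, 100.0 * bin_ok / np.maximum(bin_tot, 1), np.nan)
    return {
        "subtype_consistent_pct": 100.0 * ok_subtype / n_pairs,
        "stage_consistent_pct": 100.0 * ok_stage / n_pairs,
        "ci_overlap_pct": 100.0 * ok_ci / n_pairs,
        "subtype_consistent_by_prob_bin": dict(zip(prob_bins, by_bin)),
    }


def modality_ablation(data: DataMatrix, model: SubtypeModel,
                      modality_groups: dict, mass: float = 0.95) -> pd.DataFrame:
    """Stability of assignments when one modality is treated as missing.

    ``modality_groups`` maps biomarker name -> modality label.  For each
    modality its biomarkers are masked, subjects re-assigned under the
    uniform missing model, and the rows report the percentage keeping their
    full-data ML subtype, the mean absolute stage shift, and the percentage
    whose full-data ML (subtype, stage) lies in the ablated credible set.
    """
    names = list(model.config.names)
    unknown = set(modality_groups) - set(names)
    if unknown:
        raise ValueError(f"unknown biomarkers in modality grouping: {sorted(unknown)}")
    full = subject_posteriors(data, model, "uniform")
    rows = []
    for modality in sorted(set(modality_groups.values())):
        cols = [names.index(n) for n, m in modality_groups.items() if m == modality]
        mask = data.mask.copy()
        mask[:, cols] = False
        ablated_data = DataMatrix(values=np.where(mask, data.values, np.nan),
                                  mask=mask, subject_ids=data.subject_ids)
        abl = subject_posteriors(ablated_data, model, "uniform")
        sets = abl.credible_sets(mass)
        covered = np.fromiter(
            ((int(full.ml_subtype[j]), int(full.ml_stage[j])) in set(sets[j])
             for j in range(data.n_subjects)), dtype=bool)
        rows.append({
            "modality": modality,
            "n_biomarkers_masked": len(cols),
            "subtype_agreement_pct": 100.0 * float(np.mean(abl.ml_subtype == full.ml_subtype)),
            "mean_abs_stage_shift": float(np.mean(np.abs(
                abl.ml_stage.astype(float) - full.ml_stage.astype(float)))),
            "credible_set_coverage_pct": 100.0 * float(covered.mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benchmark harness


def run_benchmark(strategies, missing_counts, reps: int = 1,
                  opts: FitOptions = FitOptions(),
                  rng: np.random.Generator = None,
                  J: int = 500, I: int = 10, C: int = 3,
                  levels=(1.0, 2.0, 3.0), z_max: float = 5.0,
                  include_full_data: bool = True) -> pd.DataFrame:
    """Benchmark missing-data strategies on the synthetic design.

    For each repetition a fresh ground-truth model and cohort are simulated;
    for each missingness count the same corrupted matrix is handed to every
    strategy, a C-subtype model is fitted hierarchically, and the three
    metrics are scored against the truth.  A "full data" row per repetition
    records the no-missing-data ceiling.  Cells where a strategy is
    infeasible (deletion leaving fewer subjects than subtypes) are recorded
    as failed rather than aborting the run.
    """
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    records = []
    for rep in range(reps):
        model_true = simulate_model(C=C, I=I, levels=levels, z_max=z_max, rng=rng)
        data_full, truth = simulate_subjects(model_true, J=J, rng=rng)
        conditions = []
        if include_full_data:
            conditions.append(("full data", 0, data_full))
        for n_missing in missing_counts:
            corrupted = inject_missingness(data_full, n_missing, rng)
            for spec in strategies:
                conditions.append((spec, n_missing, corrupted))
        for spec, n_missing, dat in conditions:
            label = spec if isinstance(spec, str) else spec.label()
            frac = n_missing / (J * I)
            base = {"strategy": label, "missing_fraction": frac, "rep": rep}
            try:
                if isinstance(spec, str):  # full data: no strategy applied
                    prepared, kept, mode = dat, np.arange(J), "none"
                else:
                    prepared, kept = apply_strategy(dat, spec)
                    mode = spec.missing_mode
                if prepared.n_subjects < C:
                    raise ValueError("fewer subjects than subtypes after strategy")
                fit_rng = np.random.default_rng(rng.integers(2**31))
                fits = fit_hierarchical(prepared, C, opts, fit_rng,
                                        missing_mode=mode,
                                        config=model_true.config)
                rep_eval = evaluate_fit(fits[-1].model, prepared, truth,
                                        kept_rows=kept, missing_mode=mode)
                records.append({**base, "failed": False,
                                "kendall_mean": rep_eval.kendall_mean,
                                "subtype_accuracy_pct": rep_eval.subtype_accuracy,
                                "staging_mae": rep_eval.staging_error_mean,
                                "staging_sd": rep_eval.staging_error_sd,
                                "n_subjects_fitted": prepared.n_subjects})
            except ValueError as exc:
                logger.warning("benchmark cell failed (%s, %.0f%%): %s",
                               label, 100 * frac, exc)
                records.append({**base, "failed": True, "kendall_mean": np.nan,
                                "subtype_accuracy_pct": np.nan,
                                "staging_mae": np.nan, "staging_sd": np.nan,
                                "n_subjects_fitted": 0})
    return pd.DataFrame.from_records(records)


def summarize_benchmark(report: pd.DataFrame) -> pd.DataFrame:
    """Mean over repetitions with dispersion, one row per strategy x level."""
    ok = report[~report["failed"]]
    grouped = ok.groupby(["strategy", "missing_fraction"]).agg(
        kendall_mean=("kendall_mean", "mean"),
        subtype_accuracy_pct=("subtype_accuracy_pct", "mean"),
        subtype_accuracy_sd=("subtype_accuracy_pct", "std"),
        staging_mae=("staging_mae", "mean"),
        staging_sd=("staging_sd", "mean"),
        n_reps=("rep", "count"),
    ).reset_index()
    return grouped
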