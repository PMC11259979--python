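"""Miniature version of the missing-data strategy benchmark.

Simulates cohorts from the synthetic design (random subtype orderings,
uniform stages, unit noise), deletes cells completely at random, hands the
corrupted matrix to each strategy, refits the subtype model and scores it
against the generating truth.  At full scale (500 subjects x 10 biomarkers,
3 subtypes) this is the package's headline experiment; here it is scaled to
run in about a minute.
"""

import numpy as np

from mdsustain import FitOptions, StrategySpec, run_benchmark, summarize_benchmark

strategies = [
    StrategySpec("uniform"),
    StrategySpec("mean"),
    StrategySpec("knn", knn_k=5, knn_features="summary_stats"),
    StrategySpec("deletion"),
]
opts = FitOptions(n_startpoints=3, n_split_trials=3, em_tol=1e-3)
# 15 and 200 of the 500 cells: the 3% and 40% conditions of the full design
report = run_benchmark(strategies, missing_counts=[15, 200], reps=2,
                       opts=opts, rng=np.random.default_rng(0),
                       J=100, I=5, C=2)

summary = summarize_benchmark(report)
cols = ["strategy", "missing_fraction", "kendall_mean",
        "subtype_accuracy_pct", "staging_mae"]
print(summary[cols].round(3).to_string(index=False))
print("\nkendall_mean: 1 = orderings recovered exactly; "
      "subtype_accuracy_pct: % of subjects assigned to their true subtype;")
print("staging_mae: mean |estimated - true| stage. As missingness grows the "
      "uniform strategy keeps the best sequence recovery (kendall_mean); at "
      "this miniature scale the subject-level scores are noisy, so the "
      "full-scale benchmark is the one to trust for those.")
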