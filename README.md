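# mdsustain

Subtype and Stage Inference (SuStaIn) for cross-sectional biomarker data,
with missing values handled inside the likelihood instead of by deletion or
imputation.

Progressive diseases are heterogeneous: different patient subgroups
accumulate biomarker abnormality in different orders. Given one Z-score
snapshot per subject, `mdsustain` jointly recovers

* **subtypes** — clusters defined by an ordering of *Z-score events*
  (biomarker *i* reaching Z = 1, then 2, then 3 …), and
* **stages** — how far along their subtype's ordering each subject is,

together with per-subject posterior probabilities, credible sets, and MCMC
uncertainty over the event orderings ("positional variance diagrams"). It
is aimed at researchers modelling neurodegenerative or other progressive
conditions from multimodal cohorts (imaging, CSF, cognitive scores) where
some measurements are missing for many subjects.

## Model

Each biomarker follows a piecewise-linear trajectory g_i(t) on a
pseudo-time axis t ∈ [0, N+1], rising from 0 through its event levels
Z_i1 < … < Z_iR at their sequence positions to a ceiling z_max. With C
subtypes (mixture fractions f_c), stage prior P(k) and Gaussian observation
noise σ_i, the data likelihood is

    P(X|M) = Π_j  Σ_c f_c  Σ_k P(k) ∫ₖᵏ⁺¹ Π_i P(x_ij | t) dt,
    P(x_ij | t) = N(x_ij ; g_i(t), σ_i)        if x_ij observed
                = 1 / z_max_i                  if x_ij missing.

The uniform density for a missing value is constant in t and c, so missing
entries cancel from every posterior: they neither distort the estimated
orderings nor block subtyping and staging of incomplete subjects. Fitting
is greedy sequence search with random restarts inside EM over subtype
memberships, model size grows by hierarchical cluster splitting, and
uncertainty comes from Metropolis–Hastings over event permutations. See
`docs/methods.md` for the full account.

The package also ships the surrounding study apparatus: a synthetic-cohort
generator, the competing missing-data strategies (complete-case deletion,
column-mean imputation, two KNN imputation variants), evaluation metrics
(normalized Kendall similarity of orderings, subtyping accuracy after
optimal cluster matching, absolute staging error), longitudinal-consistency
and modality-ablation analyses, and a control-referenced covariate
correction / Z-scoring pipeline for raw biomarker tables.

## Worked example

`examples/simulate_and_fit.py` simulates 300 subjects from two subtypes
(5 biomarkers, events at Z = 1 and 2, noise σ = 0.75) and refits from
scratch:

```
simulated 300 subjects x 5 biomarkers, N = 10 events per sequence
C = 1: log-likelihood = -2608.9
C = 2: log-likelihood = -2236.0
(the C = 2 model should fit clearly better: the data contain 2 subtypes)

recovered mixture fractions: [0.535 0.465] (truth: [0.6 0.4])
Kendall similarity of recovered orderings to truth, per matched cluster: [1. 1.] (1 = identical)
subjects subtyped correctly: 93.7%
staging error: 0.62 +/- 0.71 stages
```

The likelihood jump from C = 1 to C = 2 identifies the number of subtypes;
both event orderings are recovered exactly (Kendall similarity 1); 93.7% of
subjects land in their true subtype and their stage is off by 0.62 of a
stage on average.

The other examples each exercise one capability end to end:
`assign_with_missing_data.py` (posteriors, credible sets and the
"normal appearing" stage-0 rule on incomplete records),
`missing_data_strategies.py` (what each strategy does to a corrupted
matrix), `benchmark_strategies.py` (a miniature strategy benchmark), and
`preprocess_raw_biomarkers.py` (raw measurements → control-referenced
Z-scores → event configuration).

A thin CLI wraps the same functions for shell pipelines:

```bash
mdsustain simulate --subjects 500 --biomarkers 10 --subtypes 3 \
    --missing-n 150 --seed 1 --out data.csv --truth truth.json
mdsustain fit --data data.csv --cmax 3 --seed 1 --out-dir fit/
mdsustain assign --data data.csv --model fit/model_C3.json --out assignments.csv
```

Every run writes a manifest (config, seed, versions, input checksums), and
fixed seeds give byte-identical outputs.

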