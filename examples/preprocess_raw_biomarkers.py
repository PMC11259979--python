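"""Turn raw biomarker measurements into model-ready Z-scores.

A linear model of each biomarker on the covariates is fitted in controls
only, nonsignificant covariates are dropped, and every subject's residual is
standardized against the control distribution.  Biomarkers that decrease
with disease (here: a brain volume) are sign-flipped so abnormality is
always positive.  Event levels and the per-biomarker ceiling are then read
off the resulting Z-score distribution.
"""

import numpy as np
import pandas as pd

from mdsustain import correct_and_zscore, derive_event_config, fit_covariate_model

rng = np.random.default_rng(0)
n_controls, n_patients = 100, 150
n = n_controls + n_patients
age = rng.uniform(55, 90, n)
sex = rng.integers(0, 2, n)
control = np.zeros(n, dtype=bool)
control[:n_controls] = True

# a volume that shrinks with age and (strongly) with disease, plus a
# cognitive score that worsens (increases) with disease only
volume = 120.0 - 0.8 * age + rng.normal(0, 6, n)
volume[~control] -= np.abs(rng.normal(25, 12, n_patients))
cognition = 10.0 + rng.normal(0, 3, n)
cognition[~control] += np.abs(rng.normal(9, 5, n_patients))

raw = pd.DataFrame({"volume": volume, "cognition": cognition})
covariates = pd.DataFrame({"age": age, "sex": sex})

model = fit_covariate_model(raw, covariates, control,
                            directions={"volume": -1, "cognition": +1})
for b in model.biomarkers:
    print(f"{b}: retained covariates {sorted(model.coefficients[b])}, "
          f"control SD {model.control_sd[b]:.2f}")

z = correct_and_zscore(raw, covariates, model)
zc = z.values[control]
print(f"\ncontrol Z-scores: mean {zc.mean(axis=0).round(6)}, "
      f"SD {zc.std(axis=0, ddof=1).round(6)}  (0 and 1 by construction)")
print(f"patient mean Z-scores: {z.values[~control].mean(axis=0).round(2)} "
      f"(positive = abnormal, for both directions)")

config = derive_event_config(z, candidate_levels=(1.0, 2.0, 3.0, 5.0),
                             biomarker_names=list(raw.columns))
for name, levels, zmax in zip(config.names, config.event_levels, config.z_max):
    print(f"{name}: z_max = {zmax:g} (rounded 95th percentile), "
          f"event levels = {levels}")
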