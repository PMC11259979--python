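import numpy as np
import pytest

from mdsustain import BiomarkerConfig, DataMatrix, EventSequence, SubtypeModel


@pytest.fixture
def tiny_config():
    """Two biomarkers, one event level each: N = 2, two valid orderings."""
    return BiomarkerConfig(names=("a", "b"), event_levels=((2.0,), (2.0,)),
                           z_max=(5.0, 5.0))


@pytest.fixture
def forced_config():
    """One biomarker with levels (1, 2, 3): a single valid ordering."""
    return BiomarkerConfig(names=("a",), event_levels=((1.0, 2.0, 3.0),),
                           z_max=(5.0,))


@pytest.fixture
def forced_sequence(forced_config):
    return EventSequence(((0, 0), (0, 1), (0, 2)), forced_config)


@pytest.fixture
def bench_config():
    """Benchmark-style config: I biomarkers, levels (1,2,3), z_max 5."""
    I = 3
    return BiomarkerConfig(names=tuple(f"bm{i}" for i in range(I)),
                           event_levels=tuple((1.0, 2.0, 3.0) for _ in range(I)),
                           z_max=tuple(5.0 for _ in range(I)))


def brute_force_log_likelihood(data: DataMatrix, model: SubtypeModel) -> float:
    """Independent naive oracle for the mixture log-likelihood.

    Triple loop over subjects, subtypes and stages with midpoint evaluation of
    each stage integral, using scipy's normal pdf on the natural scale; missing
    entries contribute 1 / z_max.  Only usable on tiny instances.
    """
    from scipy.stats import norm

    from mdsustain.model import trajectory_value

    cfg = model.config
    N = cfg.n_events
    total = 0.0
    for j in range(data.n_subjects):
        subject_lik = 0.0
        for c, seq in enumerate(model.sequences):
            for k in range(N + 1):
                t = k + 0.5
                lik = model.stage_prior[k]
                for i in range(cfg.n_biomarkers):
                    if data.mask[j, i]:
                        g = trajectory_value(seq, cfg, i, t)
                        lik *= norm.pdf(data.values[j, i], loc=g,
                                        scale=cfg.sigma[i])
                    else:
                        lik *= 1.0 / cfg.z_max[i]
            # midpoint rule: integral over [k, k+1] is the midpoint value
                subject_lik += model.fractions[c] * lik
        total += np.log(subject_lik)
    return total


def all_valid_sequences(config: BiomarkerConfig):
    """Exhaustive enumeration of valid event orderings (tiny configs only)."""
    from itertools import permutations

    events = config.event_list()
    out = []
    for perm in permutations(events):
        seen = {}
        ok = True
        for i, r in perm:
            if r != seen.get(i, -1) + 1:
                ok = False
                break
            seen[i] = r
        if ok:
            out.append(EventSequence(tuple(perm), config))
    return out
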