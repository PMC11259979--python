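"""Model core: trajectories, densities, stage likelihoods, posteriors."""

import numpy as np
import pytest

from mdsustain import (
    BiomarkerConfig,
    DataMatrix,
    EventSequence,
    SubtypeModel,
    credible_set,
    observation_density,
    stage_likelihoods,
    stage_log_likelihoods,
    subject_posteriors,
    total_log_likelihood,
    trajectory_value,
)
from mdsustain.simulate import simulate_model, simulate_subjects

from conftest import all_valid_sequences, brute_force_log_likelihood


class TestTrajectory:
    def test_anchors(self, forced_sequence, forced_config):
        N1 = forced_config.n_events + 1
        assert trajectory_value(forced_sequence, forced_config, 0, 0.0) == 0.0
        assert trajectory_value(forced_sequence, forced_config, 0, N1) == 5.0

    def test_hand_interpolation_between_events(self, forced_sequence, forced_config):
        # levels (1,2,3) at positions (1,2,3): between (1,1) and (2,2) -> 1.5
        assert trajectory_value(forced_sequence, forced_config, 0, 1.5) == pytest.approx(1.5)

    def test_monotone_and_continuous_on_dense_grid(self):
        rng = np.random.default_rng(42)
        model = simulate_model(C=2, I=4, rng=rng)
        t = np.linspace(0, model.config.n_events + 1, 2000)
        for seq in model.sequences:
            for i in range(model.config.n_biomarkers):
                g = trajectory_value(seq, model.config, i, t)
                assert np.all(np.diff(g) >= -1e-12)
                assert np.max(np.abs(np.diff(g))) < 0.1  # no jumps on fine grid

    def test_out_of_range_t_rejected(self, forced_sequence, forced_config):
        with pytest.raises(ValueError):
            trajectory_value(forced_sequence, forced_config, 0, -0.1)
        with pytest.raises(LookupError):
            trajectory_value(forced_sequence, forced_config, 5, 1.0)


class TestObservationDensity:
    def test_on_trajectory_standard_normal_peak(self, forced_sequence, forced_config):
        g = trajectory_value(forced_sequence, forced_config, 0, 1.5)
        d = observation_density(g, 0, 1.5, forced_sequence, forced_config)
        assert d == pytest.approx(1.0 / np.sqrt(2 * np.pi))

    @pytest.mark.parametrize("z_max,expect", [(5.0, 0.2), (2.0, 0.5)])
    def test_missing_uniform_density(self, z_max, expect):
        cfg = BiomarkerConfig(names=("a",), event_levels=((1.0,),), z_max=(z_max,))
        seq = EventSequence(((0, 0),), cfg)
        for t in (0.0, 0.7, 1.9):
            assert observation_density(np.nan, 0, t, seq, cfg, "uniform") == expect

    def test_missing_under_mode_none_rejected(self, forced_sequence, forced_config):
        with pytest.raises(ValueError):
            observation_density(np.nan, 0, 1.0, forced_sequence, forced_config, "none")


class TestStageLikelihoods:
    def test_all_missing_subject_constant_product(self):
        I = 10
        cfg = BiomarkerConfig(names=tuple(f"b{i}" for i in range(I)),
                              event_levels=tuple(((1.0,)) for _ in range(I)),
                              z_max=tuple(5.0 for _ in range(I)))
        from mdsustain.fitting import random_sequence
        seq = random_sequence(cfg, np.random.default_rng(0))
        data = DataMatrix(values=np.full((1, I), np.nan))
        lik = stage_likelihoods(data, seq, cfg, "uniform")
        assert lik.shape == (1, cfg.n_events + 1)
        assert np.allclose(lik, 0.2 ** 10)

    def test_empty_input(self, forced_sequence, forced_config):
        data = DataMatrix(values=np.empty((0, 1)))
        out = stage_likelihoods(data, forced_sequence, forced_config)
        assert out.shape == (0, 4)

    def test_far_off_trajectory_tiny(self, forced_sequence, forced_config):
        data = DataMatrix(values=np.array([[15.0]]))  # >= 10 sigma off everywhere
        lik = stage_likelihoods(data, forced_sequence, forced_config)
        assert np.all(lik < 1e-20)

    def test_dimension_mismatch(self, forced_sequence, forced_config):
        data = DataMatrix(values=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            stage_likelihoods(data, forced_sequence, forced_config)

    def test_multipoint_quadrature_matches_numerical_integration(
            self, forced_sequence, forced_config):
        from scipy.integrate import quad
        from scipy.stats import norm
        from mdsustain.model import trajectory_value

        data = DataMatrix(values=np.array([[1.2], [2.8]]))
        out = stage_log_likelihoods(data, forced_sequence, forced_config,
                                    quad_points=64)
        for j, x in enumerate((1.2, 2.8)):
            for k in range(4):
                ref, _ = quad(
                    lambda t: norm.pdf(
                        x, trajectory_value(forced_sequence, forced_config, 0, t), 1.0),
                    k, k + 1)
                assert out[j, k] == pytest.approx(np.log(ref), abs=1e-3)


class TestTotalLogLikelihood:
    def test_all_missing_collapses_to_uniform_constants(self):
        I = 4
        cfg = BiomarkerConfig(names=tuple(f"b{i}" for i in range(I)),
                              event_levels=tuple(((1.0, 2.0)) for _ in range(I)),
                              z_max=tuple(5.0 for _ in range(I)))
        from mdsustain.fitting import random_sequence
        seq = random_sequence(cfg, np.random.default_rng(1))
        model = SubtypeModel(sequences=(seq,), fractions=np.array([1.0]), config=cfg)
        data = DataMatrix(values=np.full((1, I), np.nan))
        assert total_log_likelihood(data, model) == pytest.approx(I * np.log(0.2))

    def test_duplicating_subjects_doubles_loglik(self, tiny_config):
        seqs = all_valid_sequences(tiny_config)
        model = SubtypeModel(sequences=tuple(seqs), fractions=np.array([0.6, 0.4]),
                             config=tiny_config)
        values = np.array([[0.5, 1.0], [np.nan, 2.0], [3.0, 0.1]])
        one = DataMatrix(values=values)
        two = DataMatrix(values=np.vstack([values, values]))
        assert total_log_likelihood(two, model) == pytest.approx(
            2 * total_log_likelihood(one, model))

    def test_matches_brute_force_oracle(self, bench_config):
        # N = 9 events, J = 8, with missingness: exhaustive naive summation
        rng = np.random.default_rng(3)
        from mdsustain.fitting import random_sequence
        seqs = tuple(random_sequence(bench_config, rng) for _ in range(2))
        model = SubtypeModel(sequences=seqs, fractions=np.array([0.7, 0.3]),
                             config=bench_config)
        values = rng.normal(1.0, 2.0, size=(8, 3))
        values[rng.random(values.shape) < 0.25] = np.nan
        data = DataMatrix(values=values)
        assert total_log_likelihood(data, model) == pytest.approx(
            brute_force_log_likelihood(data, model), abs=1e-10)

    def test_missing_entries_are_posterior_inert(self, tiny_config):
        # masking biomarker b equals dividing its density factor out: the
        # posterior from the masked data must match the posterior computed
        # from the observed column alone
        seqs = all_valid_sequences(tiny_config)
        model = SubtypeModel(sequences=tuple(seqs), fractions=np.array([0.5, 0.5]),
                             config=tiny_config)
        full = DataMatrix(values=np.array([[1.4, np.nan]]))
        post = subject_posteriors(full, model)
        # oracle: joint prob computed by hand from the observed column only
        from scipy.stats import norm
        from mdsustain.model import trajectory_value
        joint = np.zeros((2, 3))
        for c, seq in enumerate(seqs):
            for k in range(3):
                g = trajectory_value(seq, tiny_config, 0, k + 0.5)
                joint[c, k] = 0.5 * (1 / 3) * norm.pdf(1.4, g, 1.0)
        joint /= joint.sum()
        assert np.allclose(post.prob[0], joint, atol=1e-12)

    def test_fully_missing_data_cannot_identify_orderings(self, bench_config):
        from mdsustain.fitting import random_sequence
        rng = np.random.default_rng(5)
        data = DataMatrix(values=np.full((6, 3), np.nan))
        lls = []
        for _ in range(4):
            seqs = tuple(random_sequence(bench_config, rng) for _ in range(2))
            model = SubtypeModel(sequences=seqs, fractions=np.array([0.5, 0.5]),
                                 config=bench_config)
            lls.append(total_log_likelihood(data, model))
        assert np.ptp(lls) < 1e-9


class TestSubjectPosteriors:
    def test_all_missing_posterior_equals_prior(self, tiny_config):
        seqs = all_valid_sequences(tiny_config)
        fractions = np.array([0.7, 0.3])
        model = SubtypeModel(sequences=tuple(seqs), fractions=fractions,
                             config=tiny_config)
        data = DataMatrix(values=np.full((2, 2), np.nan))
        post = subject_posteriors(data, model)
        expected = fractions[:, None] / 3.0
        for j in range(2):
            assert np.allclose(post.prob[j], expected, atol=1e-12)

    def test_rows_normalized(self, bench_config):
        rng = np.random.default_rng(11)
        model = simulate_model(C=3, I=5, rng=rng)
        data, _ = simulate_subjects(model, 40, rng=rng)
        from mdsustain.simulate import inject_missingness
        data = inject_missingness(data, 30, rng)
        post = subject_posteriors(data, model)
        assert np.allclose(post.prob.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_noiseless_subject_recovers_subtype(self):
        rng = np.random.default_rng(21)
        model = simulate_model(C=2, I=5, levels=(1.0, 2.0), rng=rng, sigma=0.1)
        data, truth = simulate_subjects(model, 60, rng=rng)
        post = subject_posteriors(data, model)
        staged = truth.subject_stage > 3  # early stages carry little signal
        agree = post.ml_subtype[staged] == truth.subject_subtype[staged]
        assert agree.mean() > 0.95


class TestCredibleSet:
    def test_degenerate_posterior(self):
        p = np.zeros((2, 3))
        p[1, 2] = 1.0
        assert credible_set(p, 0.95) == [(1, 2)]

    def test_uniform_20_cells_needs_19(self):
        p = np.full((4, 5), 1 / 20)
        assert len(credible_set(p, 0.95)) == 19

    def test_full_mass_takes_all_nonzero(self):
        p = np.array([[0.5, 0.5, 0.0]])
        assert sorted(credible_set(p, 1.0)) == [(0, 0), (0, 1)]

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            credible_set(np.array([[1.0]]), 0.0)


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, bench_config):
        from mdsustain.fitting import random_sequence
        rng = np.random.default_rng(2)
        seqs = tuple(random_sequence(bench_config, rng) for _ in range(2))
        model = SubtypeModel(sequences=seqs, fractions=np.array([0.25, 0.75]),
                             config=bench_config)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SubtypeModel.from_json(path)
        assert back.to_dict() == model.to_dict()
        assert np.array_equal(back.fractions, model.fractions)
        assert all(a.events == b.events
                   for a, b in zip(back.sequences, model.sequences))


class TestInvariantValidation:
    def test_nonincreasing_levels_rejected(self):
        with pytest.raises(ValueError):
            BiomarkerConfig(names=("a",), event_levels=((2.0, 1.0),), z_max=(5.0,))

    def test_level_above_zmax_rejected(self):
        with pytest.raises(ValueError):
            BiomarkerConfig(names=("a",), event_levels=((6.0,),), z_max=(5.0,))

    def test_sequence_must_cover_all_events(self, tiny_config):
        with pytest.raises(ValueError):
            EventSequence(((0, 0), (0, 0)), tiny_config)

    def test_sequence_level_order_enforced(self, forced_config):
        with pytest.raises(ValueError):
            EventSequence(((0, 1), (0, 0), (0, 2)), forced_config)

    def test_fractions_must_normalize(self, tiny_config):
        seqs = all_valid_sequences(tiny_config)
        with pytest.raises(ValueError):
            SubtypeModel(sequences=tuple(seqs), fractions=np.array([0.5, 0.4]),
                         config=tiny_config)

    def test_observed_values_must_be_finite(self):
        with pytest.raises(ValueError):
            DataMatrix(values=np.array([[np.inf]]),
                       mask=np.array([[True]]))
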