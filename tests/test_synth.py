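"""Synthetic cohort generator: planted structure and determinism."""
import numpy as np
import pandas as pd
import pytest

from dynfnc import (
    CohortConfig,
    simulate_cognition,
    simulate_state_sequence,
    simulate_timecourses,
    simulate_voxel_dataset,
)
from dynfnc.errors import ArgumentError, ConfigError
from dynfnc.synth import default_state_correlations, nearest_correlation


def _single_state_config(cov, T=20_000, **kw):
    cov = np.asarray(cov, dtype=float)
    defaults = dict(
        n_subjects=1,
        n_components=cov.shape[0],
        n_timepoints=T,
        n_states=1,
        stay_prob=1.0,
        state_covariances=[cov],
        treatment_effects=[],
        prediction_couplings=[],
        noise_sd=0.0,
        subject_sd=0.0,
        seed=5,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestStateSequence:
    def test_absorbing_chain_is_constant(self):
        seq = simulate_state_sequence(6, 2, stay_prob=1.0, seed=0)
        assert len(seq) == 6
        assert len(set(seq)) == 1

    def test_empirical_transition_matrix_matches_chain(self):
        # Monte-Carlo count oracle: empirical row-normalized transition
        # frequencies of a long chain approach the generating matrix
        seq = simulate_state_sequence(50_000, 3, stay_prob=0.9, seed=42)
        counts = np.zeros((3, 3))
        np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
        empirical = counts / counts.sum(axis=1, keepdims=True)
        expected = np.full((3, 3), 0.05)
        np.fill_diagonal(expected, 0.9)
        assert np.abs(empirical - expected).max() < 0.01

    def test_long_run_occupancy_is_uniform(self):
        seq = simulate_state_sequence(100_000, 4, stay_prob=0.9, seed=7)
        occupancy = np.bincount(seq, minlength=4) / len(seq)
        assert np.abs(occupancy - 0.25).max() < 0.02

    @pytest.mark.parametrize("bad", [dict(n_steps=0), dict(n_states=0)])
    def test_nonpositive_sizes_rejected(self, bad):
        kwargs = dict(n_steps=10, n_states=2, stay_prob=0.5, seed=0)
        kwargs.update(bad)
        with pytest.raises(ArgumentError):
            simulate_state_sequence(**kwargs)


class TestTimecourses:
    def test_independent_components_under_identity_covariance(self):
        config = _single_state_config(np.eye(3))
        tcs, _ = simulate_timecourses(config)
        r = np.corrcoef(next(iter(tcs)).data)
        off = r[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 0.02

    def test_planted_pair_correlation_recovered(self):
        # sampling error bound from Fisher-z variance 1/(T-3): 4 SD ~ 0.014
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        tcs, _ = simulate_timecourses(_single_state_config(cov))
        x = next(iter(tcs)).data
        assert np.corrcoef(x)[0, 1] == pytest.approx(0.6, abs=0.02)

    def test_treatment_effect_shifts_post_session_correlation(self):
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        config = _single_state_config(cov, treatment_effects=[((0, 1), 0.3)])
        tcs, _ = simulate_timecourses(config)
        z = {tc.session: np.arctanh(np.corrcoef(tc.data)[0, 1]) for tc in tcs}
        expected = np.arctanh(0.6) - np.arctanh(0.3)
        assert z["post"] - z["pre"] == pytest.approx(expected, abs=0.05)

    def test_effect_outside_unit_interval_names_the_pair(self):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        with pytest.raises(ConfigError, match="IC01-IC02"):
            config = _single_state_config(cov, T=10, treatment_effects=[((0, 1), 0.5)])
            simulate_timecourses(config)

    def test_same_seed_bit_identical(self):
        a, _ = simulate_timecourses(CohortConfig(n_subjects=2, n_timepoints=50, seed=9))
        b, _ = simulate_timecourses(CohortConfig(n_subjects=2, n_timepoints=50, seed=9))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.data, tb.data)

    def test_adding_a_subject_preserves_existing_ones(self):
        a, _ = simulate_timecourses(CohortConfig(n_subjects=2, n_timepoints=50, seed=9))
        b, _ = simulate_timecourses(CohortConfig(n_subjects=3, n_timepoints=50, seed=9))
        np.testing.assert_array_equal(
            a.get("001", "pre").data, b.get("001", "pre").data
        )

    def test_ground_truth_sequences_cover_sessions(self, small_cohort):
        config, tcs, truth = small_cohort
        assert set(truth.state_sequences) == {
            (tc.subject, tc.session) for tc in tcs
        }
        for seq in truth.state_sequences.values():
            assert len(seq) == config.n_timepoints
            assert seq.min() >= 0 and seq.max() < config.n_states

    def test_sample_covariance_converges_with_length(self):
        cov = default_state_correlations(1, 4, 0.6)[0]
        errs = []
        for T in (500, 5_000, 50_000):
            tcs, _ = simulate_timecourses(_single_state_config(cov, T=T))
            sample = np.cov(next(iter(tcs)).data)
            errs.append(np.linalg.norm(sample - cov))
        assert errs[0] > errs[1] > errs[2]


class TestNearestCorrelation:
    def test_projects_to_unit_diagonal_psd(self, rng):
        m = rng.standard_normal((6, 6))
        m = (m + m.T) / 2
        out = nearest_correlation(m)
        assert np.allclose(np.diag(out), 1.0)
        assert np.linalg.eigvalsh(out).min() > 0

    def test_valid_matrix_unchanged(self):
        r = default_state_correlations(1, 5)[0]
        np.testing.assert_allclose(nearest_correlation(r), r, atol=1e-10)


class TestCognition:
    def _features(self, n, rng, names=("f0", "f1", "f2")):
        return pd.DataFrame(
            rng.standard_normal((n, len(names))),
            columns=list(names),
            index=[f"{i + 1:03d}" for i in range(n)],
        )

    def test_null_couplings_leave_delta_uncorrelated(self, rng):
        config = CohortConfig(
            n_subjects=200, prediction_couplings=[], labels=None, seed=1
        )
        feats = self._features(200, rng)
        table, _ = simulate_cognition(config, feats, seed=3, noise_sd=1.0)
        for c in feats.columns:
            r = np.corrcoef(feats[c], table["memory_delta"])[0, 1]
            assert abs(r) < 0.15  # null bound ~ 2/sqrt(n)

    def test_noiseless_unit_coupling_is_identity(self, rng):
        config = CohortConfig(n_subjects=20, prediction_couplings=[((0, 1), 1.0)], seed=1)
        feats = self._features(20, rng, names=[config.pair_name((0, 1)), "other"])
        table, truth = simulate_cognition(config, feats, seed=3, noise_sd=0.0)
        np.testing.assert_allclose(
            table["memory_delta"], feats[config.pair_name((0, 1))]
        )
        np.testing.assert_allclose(table["memory_delta"], truth.true_deltas)

    def test_post_minus_pre_equals_delta(self, rng):
        config = CohortConfig(n_subjects=15, seed=2)
        feats = self._features(15, rng, names=["rFPN-lFPN", "aDMN-pDMN"])
        table, _ = simulate_cognition(config, feats, seed=4)
        np.testing.assert_allclose(
            table["memory_post"] - table["memory_pre"], table["memory_delta"]
        )

    def test_same_seed_identical_tables(self, rng):
        config = CohortConfig(n_subjects=10, seed=2)
        feats = self._features(10, rng, names=["rFPN-lFPN", "aDMN-pDMN"])
        t1, _ = simulate_cognition(config, feats, seed=11)
        t2, _ = simulate_cognition(config, feats, seed=11)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_feature_in_coupling_rejected(self, rng):
        config = CohortConfig(n_subjects=5, seed=2)
        feats = self._features(5, rng)
        with pytest.raises(ConfigError, match="unknown feature"):
            simulate_cognition(config, feats, seed=0)


class TestVoxelDataset:
    def test_orthonormal_maps_invert_exactly(self, rng):
        maps = np.linalg.qr(rng.standard_normal((100, 5)))[0].T  # 5 orthonormal maps
        config = _single_state_config(np.eye(5), T=50)
        tcs, _ = simulate_timecourses(config)
        ds = simulate_voxel_dataset(maps, tcs, noise_sd=0.0, seed=1)
        recovered = maps @ ds.data[0]
        np.testing.assert_allclose(recovered, next(iter(tcs)).data, atol=1e-10)

    def test_duplicated_map_rejected(self, rng):
        maps = rng.standard_normal((3, 50))
        maps[2] = maps[0]
        config = _single_state_config(np.eye(3), T=20)
        tcs, _ = simulate_timecourses(config)
        with pytest.raises(ConfigError, match="rank"):
            simulate_voxel_dataset(maps, tcs, noise_sd=0.0, seed=1)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(stay_prob=0.0),
            dict(stay_prob=1.5),
            dict(n_states=0),
            dict(treatment_effects=[((0, 99), 0.1)]),
            dict(noise_sd=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            CohortConfig(**kw)

    def test_default_states_are_spd_and_distinct(self):
        mats = default_state_correlations()
        for m in mats:
            assert np.linalg.eigvalsh(m).min() > 0
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                assert not np.allclose(mats[i], mats[j])

    def test_coupling_pairs_are_state_invariant(self):
        # the default coupling targets carry no state-dependent variation,
        # so baseline connectivity there is purely subject-specific
        config = CohortConfig()
        for (i, j), _ in config.prediction_couplings:
            vals = {m[i, j] for m in config.state_covariances}
            assert len(vals) == 1
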