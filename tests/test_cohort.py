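"""Synthetic cohort generator: archetypes, interpolation, epoch noise,
time-series envelope coupling, determinism."""

import numpy as np
import pytest

from spectrumst import (CohortConfig, aecc_matrix, downsample,
                        edge_overlap, epoch_average, generate_cohort,
                        make_archetypes, mst_from_connectivity,
                        sample_subject_connectivity,
                        sample_subject_timeseries)
from spectrumst.cohort import interpolate_weights
from spectrumst.connectivity import band_by_name
from spectrumst.errors import ConfigurationError

SMALL = dict(n_rois=12, group_sizes={"motor": 2, "cibi": 2, "bvftd": 2},
             n_epochs=4, seed=5)


class TestArchetypes:
    def test_deterministic(self):
        a1, b1 = make_archetypes(20, seed=4, target_mst_overlap=0.2)
        a2, b2 = make_archetypes(20, seed=4, target_mst_overlap=0.2)
        assert np.array_equal(a1.weights.weights, a2.weights.weights)
        assert np.array_equal(b1.weights.weights, b2.weights.weights)

    def test_overlap_within_target(self):
        am, ab = make_archetypes(90, seed=7, target_mst_overlap=0.2)
        ov = edge_overlap(mst_from_connectivity(am.weights),
                          mst_from_connectivity(ab.weights))
        assert ov <= 0.3

    def test_edge_disjoint_achievable_on_four_nodes(self):
        for seed in range(5):
            am, ab = make_archetypes(4, seed=seed, target_mst_overlap=0.0)
            assert edge_overlap(mst_from_connectivity(am.weights),
                                mst_from_connectivity(ab.weights)) == 0.0

    def test_matrix_invariants(self):
        am, ab = make_archetypes(30, seed=1, target_mst_overlap=0.2)
        for arch in (am, ab):
            w = arch.weights.weights
            assert np.array_equal(w, w.T)
            assert np.all(np.diag(w) == 0.0)
            off = w[np.triu_indices(30, 1)]
            assert off.min() > 0.0 and off.max() < 1.0

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ConfigurationError):
            make_archetypes(3, seed=0, target_mst_overlap=0.0)


@pytest.fixture(scope="module")
def archetypes():
    return make_archetypes(12, seed=5, target_mst_overlap=0.2)


class TestSubjectConnectivity:
    def test_lambda_zero_reproduces_motor(self, archetypes):
        am, ab = archetypes
        cfg = CohortConfig(**{**SMALL, "edge_noise_sd": 0.0})
        mats = sample_subject_connectivity(am, ab, 0.0, cfg)
        for m in mats:
            assert np.array_equal(m.weights, am.weights.weights)

    def test_lambda_one_reproduces_bvftd(self, archetypes):
        am, ab = archetypes
        cfg = CohortConfig(**{**SMALL, "edge_noise_sd": 0.0})
        mats = sample_subject_connectivity(am, ab, 1.0, cfg)
        for m in mats:
            assert np.array_equal(m.weights, ab.weights.weights)

    def test_epoch_mean_concentrates_on_interpolation(self, archetypes):
        am, ab = archetypes
        sd = 0.05
        cfg = CohortConfig(**{**SMALL, "n_epochs": 8, "edge_noise_sd": sd})
        rng = np.random.default_rng(99)
        mats = sample_subject_connectivity(am, ab, 0.5, cfg, rng)
        mean = epoch_average(mats).weights
        target = interpolate_weights(am, ab, 0.5)
        iu = np.triu_indices(12, 1)
        frac_close = np.mean(
            np.abs(mean[iu] - target[iu]) <= 3 * sd / np.sqrt(8))
        assert frac_close >= 0.99

    def test_epoch_matrices_valid(self, archetypes):
        am, ab = archetypes
        cfg = CohortConfig(**{**SMALL, "edge_noise_sd": 0.4})
        rng = np.random.default_rng(3)
        for m in sample_subject_connectivity(am, ab, 0.5, cfg, rng):
            w = m.weights
            assert np.array_equal(w, w.T)
            assert np.all(np.diag(w) == 0.0)
            assert w.min() >= 0.0 and w.max() <= 1.0

    def test_bad_lambda_rejected(self, archetypes):
        am, ab = archetypes
        with pytest.raises(ConfigurationError):
            sample_subject_connectivity(am, ab, 1.5, CohortConfig(**SMALL))


class TestCohort:
    def test_default_group_sizes(self):
        cohort = generate_cohort(CohortConfig(seed=1))
        counts = {g: sum(s.group == g for s in cohort)
                  for g in ("motor", "cibi", "bvftd")}
        assert counts == {"motor": 9, "cibi": 16, "bvftd": 16}

    def test_followup_drift_moves_cibi_up(self):
        cohort = generate_cohort(CohortConfig(**SMALL))
        for s in cohort:
            if s.group == "cibi":
                lam0, lam1 = s.lambda_true["baseline"], s.lambda_true["followup"]
                assert lam1 > lam0 or lam1 == 1.0
            else:
                assert s.lambda_true["followup"] == s.lambda_true["baseline"]

    def test_bit_identical_under_same_seed(self):
        c1 = generate_cohort(CohortConfig(**SMALL))
        c2 = generate_cohort(CohortConfig(**SMALL))
        for s1, s2 in zip(c1, c2):
            assert s1.subject_id == s2.subject_id
            assert s1.lambda_true == s2.lambda_true
            for tp in ("baseline", "followup"):
                for m1, m2 in zip(s1.epochs[tp], s2.epochs[tp]):
                    assert np.array_equal(m1.weights, m2.weights)

    def test_adding_subjects_preserves_existing(self):
        base = generate_cohort(CohortConfig(**SMALL))
        bigger = generate_cohort(CohortConfig(**{
            **SMALL, "group_sizes": {"motor": 3, "cibi": 4, "bvftd": 2}}))
        by_id = {s.subject_id: s for s in bigger}
        for s in base:
            twin = by_id[s.subject_id]
            assert twin.lambda_true == s.lambda_true
            for tp in ("baseline", "followup"):
                for m1, m2 in zip(s.epochs[tp], twin.epochs[tp]):
                    assert np.array_equal(m1.weights, m2.weights)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(group_sizes={"motor": 0, "cibi": 1, "bvftd": 1})
        with pytest.raises(ConfigurationError):
            CohortConfig(edge_noise_sd=-0.1)
        with pytest.raises(ConfigurationError):
            CohortConfig(mode="something")


TS = dict(n_rois=8, group_sizes={"motor": 1, "cibi": 1, "bvftd": 1},
          n_epochs=4, epoch_samples=8192, fs=1250.0, mode="timeseries",
          seed=21)


class TestTimeseries:
    def test_deterministic_signals(self):
        am, _ = make_archetypes(8, seed=21, target_mst_overlap=0.2)
        cfg = CohortConfig(**TS)
        e1 = sample_subject_timeseries(am.weights, cfg,
                                       np.random.default_rng(1))
        e2 = sample_subject_timeseries(am.weights, cfg,
                                       np.random.default_rng(1))
        for a, b in zip(e1, e2):
            assert np.array_equal(a.data, b.data)

    def test_epoch_shape_and_rate(self):
        am, _ = make_archetypes(8, seed=21, target_mst_overlap=0.2)
        epochs = sample_subject_timeseries(am.weights, CohortConfig(**TS),
                                           np.random.default_rng(2))
        assert len(epochs) == 4
        for ep in epochs:
            assert ep.data.shape == (8, 8192)
            assert ep.fs == 1250.0

    def test_epoch_too_short_for_band_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(**{**TS, "planted_band": "delta",
                            "epoch_samples": 4096})

    def test_strongest_planted_pair_has_largest_aecc(self):
        # a single strong pair (0.8 vs background 0.05) should dominate
        from spectrumst import ConnectivityMatrix

        n = 6
        w = np.full((n, n), 0.05)
        w[0, 1] = w[1, 0] = 0.8
        np.fill_diagonal(w, 0.0)
        target = ConnectivityMatrix(w)
        cfg = CohortConfig(**{**TS, "n_rois": 6})
        band = band_by_name(cfg.planted_band)
        hits = 0
        for seed in range(5):
            eps = sample_subject_timeseries(target, cfg,
                                            np.random.default_rng(seed))
            mean = epoch_average(
                [aecc_matrix(downsample(ep, 4), band) for ep in eps])
            iu = np.triu_indices(n, 1)
            hits += np.argmax(mean.weights[iu]) == 0  # pair (0,1) is first
        assert hits >= 4

    def test_uncoupled_rois_have_small_aecc(self):
        from spectrumst import ConnectivityMatrix

        n = 6
        w = np.full((n, n), 0.3)
        np.fill_diagonal(w, 0.0)
        cfg = CohortConfig(**{**TS, "n_rois": 6, "coupling_scale": 0.0})
        band = band_by_name(cfg.planted_band)
        eps = sample_subject_timeseries(ConnectivityMatrix(w), cfg,
                                        np.random.default_rng(17))
        mean = epoch_average(
            [aecc_matrix(downsample(ep, 4), band) for ep in eps])
        assert np.abs(mean.weights[np.triu_indices(n, 1)]).mean() < 0.1

    def test_motor_subject_estimates_nearer_motor_archetype(self):
        # lambda = 0 subject: estimated AECc (standardized off-diagonals,
        # since AECc compresses the weight scale) is closer in Frobenius
        # norm to the motor archetype than to the bvftd archetype
        am, ab = make_archetypes(10, seed=31, target_mst_overlap=0.2)
        cfg = CohortConfig(n_rois=10,
                           group_sizes={"motor": 1, "cibi": 1, "bvftd": 1},
                           n_epochs=4, epoch_samples=8192,
                           mode="timeseries", seed=31)
        band = band_by_name(cfg.planted_band)
        iu = np.triu_indices(10, 1)

        def z(w):
            v = w[iu]
            return (v - v.mean()) / v.std()

        for seed in (1, 2, 3):
            eps = sample_subject_timeseries(am.weights, cfg,
                                            np.random.default_rng(seed))
            est = epoch_average(
                [aecc_matrix(downsample(ep, 4), band) for ep in eps])
            d_m = np.linalg.norm(z(est.weights) - z(am.weights.weights))
            d_b = np.linalg.norm(z(est.weights) - z(ab.weights.weights))
            assert d_m < d_b

    def test_monotone_coupling_recovery(self):
        # headline generator invariant: estimated AECc is monotone in the
        # planted weights (about 100 ROI pairs, default coupling settings)
        from scipy.stats import spearmanr

        am, _ = make_archetypes(15, seed=3, target_mst_overlap=0.2)
        cfg = CohortConfig(n_rois=15,
                           group_sizes={"motor": 1, "cibi": 1, "bvftd": 1},
                           mode="timeseries", seed=3)
        band = band_by_name(cfg.planted_band)
        eps = sample_subject_timeseries(am.weights, cfg,
                                        np.random.default_rng(5))
        mean = epoch_average(
            [aecc_matrix(downsample(ep, 4), band) for ep in eps])
        iu = np.triu_indices(15, 1)
        rho = spearmanr(am.weights.weights[iu], mean.weights[iu]).statistic
        assert rho > 0.5
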