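"""Decoding operations: resampling primitives, CV decoding, cross-task."""

import numpy as np
import pytest
from scipy.stats import norm

import tgdecode as tg
from tgdecode.cluster import Cluster, ClusterResult

from conftest import condition_epochs, make_epochs, preprocess


class TestUndersampleBalance:
    def test_study_counts(self):
        rng = np.random.default_rng(0)
        a = np.zeros((107, 2, 3))
        b = np.zeros((249, 2, 3))
        a2, b2 = tg.undersample_balance(a, b, rng)
        assert len(a2) == len(b2) == 107

    def test_equal_sizes_pass_through(self):
        rng = np.random.default_rng(0)
        a = np.arange(12.0).reshape(4, 1, 3)
        b = np.arange(12.0, 24.0).reshape(4, 1, 3)
        a2, b2 = tg.undersample_balance(a, b, rng)
        assert np.array_equal(a2, a) and np.array_equal(b2, b)

    def test_deterministic_under_seed(self):
        a = np.arange(30.0).reshape(10, 1, 3)
        b = np.arange(9.0).reshape(3, 1, 3)
        s1 = tg.undersample_balance(a, b, np.random.default_rng(7))
        s2 = tg.undersample_balance(a, b, np.random.default_rng(7))
        assert np.array_equal(s1[0], s2[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tg.undersample_balance(np.zeros((0, 1, 1)), np.zeros((2, 1, 1)),
                                   np.random.default_rng(0))


class TestMakePseudoTrials:
    def test_remainder_dropped(self):
        out = tg.make_pseudo_trials(np.zeros((9, 2, 3)), 4,
                                    np.random.default_rng(0))
        assert out.shape == (2, 2, 3)

    def test_k1_identity_up_to_order(self):
        trials = np.arange(12.0).reshape(4, 1, 3)
        out = tg.make_pseudo_trials(trials, 1, np.random.default_rng(0))
        assert np.array_equal(np.sort(out, axis=0), np.sort(trials, axis=0))

    def test_forced_arithmetic(self):
        trials = np.array([1.0, 2.0, 3.0, 4.0])[:, None, None] * \
            np.ones((4, 1, 3))
        out = tg.make_pseudo_trials(trials, 4, np.random.default_rng(0))
        assert np.allclose(out, 2.5)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="k = 4"):
            tg.make_pseudo_trials(np.zeros((3, 1, 1)), 4,
                                  np.random.default_rng(0))


def _gaussian_pair(n=240, gap=2.0, sd=1.0, n_times=3, seed=0):
    """Two spherical-Gaussian classes separated along channel 0."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, (n, 2, n_times))
    b = rng.normal(0.0, sd, (n, 2, n_times))
    a[:, 0, :] += gap
    ea = make_epochs(data=a, labels=["a"] * n, t_start=0.0, sfreq=100.0)
    eb = make_epochs(data=b, labels=["b"] * n, t_start=0.0, sfreq=100.0)
    return ea, eb


class TestDecodeTimecourse:
    def test_separable_data_decodes_near_perfectly(self):
        ea, eb = _gaussian_pair(n=80, gap=6.0)
        cfg = tg.DecodingConfig(k=4, n_folds=4, n_reps=3, seed=1,
                                decode_window=(0.0, 30.0))
        res = tg.decode_timecourse(ea, eb, cfg)
        assert res.accuracy.min() > 0.9

    def test_matches_bayes_rate_on_gaussian_toy(self):
        """k=1 pipeline accuracy ~ closed-form Bayes rate Phi(d'/2)."""
        gap, sd = 2.0, 1.0
        ea, eb = _gaussian_pair(n=300, gap=gap, sd=sd, seed=2)
        cfg = tg.DecodingConfig(k=1, n_folds=4, n_reps=5, seed=3,
                                decode_window=(0.0, 30.0))
        res = tg.decode_timecourse(ea, eb, cfg)
        bayes = norm.cdf(gap / (2.0 * sd))
        assert np.abs(res.accuracy.mean() - bayes) < 0.03

    def test_swapping_conditions_gives_identical_curve(self):
        ea, eb = _gaussian_pair(n=40, gap=1.0, seed=4)
        cfg = tg.DecodingConfig(k=2, n_folds=2, n_reps=2, seed=5,
                                decode_window=(0.0, 30.0))
        r1 = tg.decode_timecourse(ea, eb, cfg)
        r2 = tg.decode_timecourse(eb, ea, cfg)
        assert np.array_equal(r1.accuracy, r2.accuracy)

    def test_accuracy_invariant_to_channel_affine_rescaling(self):
        ea, eb = _gaussian_pair(n=60, gap=1.5, seed=6)
        cfg = tg.DecodingConfig(k=2, n_folds=3, n_reps=2, seed=7,
                                decode_window=(0.0, 30.0))
        base = tg.decode_timecourse(ea, eb, cfg)
        scale = np.array([3.0, 0.2])[None, :, None]
        shift = np.array([-5.0, 11.0])[None, :, None]
        ea2 = make_epochs(data=ea.data * scale + shift, labels=ea.labels,
                          t_start=0.0, sfreq=100.0)
        eb2 = make_epochs(data=eb.data * scale + shift, labels=eb.labels,
                          t_start=0.0, sfreq=100.0)
        res = tg.decode_timecourse(ea2, eb2, cfg)
        assert np.allclose(res.accuracy, base.accuracy)

    def test_too_few_pseudo_trials_for_folds_rejected(self):
        ea, eb = _gaussian_pair(n=12, gap=1.0)
        cfg = tg.DecodingConfig(k=4, n_folds=4, n_reps=1,
                                decode_window=(0.0, 30.0))
        with pytest.raises(ValueError, match="at least 4"):
            tg.decode_timecourse(ea, eb, cfg)

    def test_accuracies_within_unit_interval(self):
        ea, eb = _gaussian_pair(n=32, gap=0.0, seed=8)
        cfg = tg.DecodingConfig(k=2, n_folds=4, n_reps=3, seed=9,
                                decode_window=(0.0, 30.0))
        res = tg.decode_timecourse(ea, eb, cfg)
        assert np.all((res.accuracy >= 0.0) & (res.accuracy <= 1.0))


class TestTemporalGeneralization:
    def test_diagonal_equals_timecourse_under_shared_seed(self):
        ea, eb = _gaussian_pair(n=48, gap=1.5, n_times=6, seed=10)
        cfg = tg.DecodingConfig(k=2, n_folds=3, n_reps=3, seed=11,
                                decode_window=(0.0, 60.0))
        mat = tg.temporal_generalization(ea, eb, cfg)
        vec = tg.decode_timecourse(ea, eb, cfg)
        assert np.array_equal(np.diag(mat.accuracy), vec.accuracy)

    def test_sustained_component_generalizes_off_diagonal(self):
        # class gap constant across the window -> the pattern generalizes
        ea, eb = _gaussian_pair(n=160, gap=3.0, n_times=6, seed=12)
        cfg = tg.DecodingConfig(k=4, n_folds=4, n_reps=3, seed=13,
                                decode_window=(0.0, 60.0))
        mat = tg.temporal_generalization(ea, eb, cfg)
        off = mat.accuracy[~np.eye(6, dtype=bool)]
        assert off.min() > 0.85


class TestCrossTask:
    def test_shared_is_transpose_average(self):
        res = tg.CrossTaskResult(
            matrix_a=np.array([[0.6, 0.5], [0.5, 0.7]]),
            matrix_b=np.array([[0.6, 0.55], [0.45, 0.7]]),
            times_task1=np.array([0.0, 10.0]),
            times_task2=np.array([0.0, 10.0]))
        assert np.allclose(res.shared,
                           [[0.6, 0.475], [0.525, 0.7]])

    def test_identical_tasks_give_symmetric_shared_matrix(self):
        ea, eb = _gaussian_pair(n=60, gap=1.5, n_times=4, seed=14)
        cfg = tg.DecodingConfig(k=2, n_folds=2, n_reps=2, seed=15,
                                decode_window=(0.0, 40.0))
        res = tg.cross_task_generalization((ea, eb), (ea, eb), cfg)
        assert np.array_equal(res.matrix_a, res.matrix_b)
        assert np.allclose(res.shared, res.shared.T)

    def test_latency_shifted_shared_component_lands_off_diagonal(
            self, montage):
        """Planted 400 vs 550 ms latencies put the transfer peak where the
        n-back (test) time exceeds the oddball (train) time."""
        cfg = tg.default_sim_config(seed=16, n_subjects=2, sfreq=50.0)
        cfg.trial_counts = {
            "oddball": {"oddball": 48, "standard": 48},
            "nback": {"2-back-target": 48, "0-back": 48}}
        study = tg.simulate_dataset(cfg, montage)
        eo = preprocess(study["sub-01"]["oddball"])
        en = preprocess(study["sub-01"]["nback"])
        res = tg.cross_task_generalization(
            (condition_epochs(eo, "oddball"),
             condition_epochs(eo, "standard")),
            (condition_epochs(en, "2-back-target"),
             condition_epochs(en, "0-back")),
            tg.DecodingConfig(n_reps=10, seed=17))
        S = res.shared
        t1, t2 = res.times_task1, res.times_task2
        above = S[t1[:, None] < t2[None, :]].mean()  # test later than train
        below = S[t1[:, None] > t2[None, :]].mean()
        assert above > below
        i, j = np.unravel_index(np.argmax(S), S.shape)
        assert t2[j] > t1[i]  # peak transfer at later n-back time

    def test_cross_task_cv_variant_runs_and_stays_in_range(self):
        ea, eb = _gaussian_pair(n=60, gap=2.0, n_times=4, seed=18)
        ec, ed = _gaussian_pair(n=60, gap=2.0, n_times=4, seed=19)
        cfg = tg.DecodingConfig(k=2, n_folds=3, n_reps=2, seed=20,
                                decode_window=(0.0, 40.0),
                                cross_task_cv=True)
        res = tg.cross_task_generalization((ea, eb), (ec, ed), cfg)
        assert np.all((res.shared >= 0.0) & (res.shared <= 1.0))
        assert res.shared.mean() > 0.7  # strong planted transfer survives CV

    def test_mismatched_grids_rejected(self):
        ea, eb = _gaussian_pair(n=24, gap=1.0, n_times=4)
        ec, ed = _gaussian_pair(n=24, gap=1.0, n_times=5)
        cfg = tg.DecodingConfig(k=2, n_folds=2, n_reps=1,
                                decode_window=(0.0, 100.0))
        with pytest.raises(ValueError, match="grid"):
            tg.cross_task_generalization((ea, eb), (ec, ed), cfg)


class TestPeakExtraction:
    def _cluster_result(self, clusters, shape):
        mask = np.zeros(int(np.prod(shape)), dtype=bool)
        for c in clusters:
            mask[c.indices] = True
        return ClusterResult(clusters=clusters, mask=mask.reshape(shape),
                             alpha=0.05)

    def test_matrix_peak_read_from_cluster(self):
        times = np.arange(0.0, 1000.0, 10.0)
        acc = np.full((100, 100), 0.5)
        acc[41, 41] = 0.82
        idx = np.ravel_multi_index(
            (np.repeat(np.arange(35, 50), 15),
             np.tile(np.arange(35, 50), 15)), acc.shape)
        cres = self._cluster_result(
            [Cluster(indices=idx, mass=50.0, p=0.01)], acc.shape)
        pk = tg.peak_accuracy_latency(acc, cres, window=(250.0, 650.0),
                                      times=times)
        assert pk.found
        assert pk.accuracy == pytest.approx(0.82)
        assert pk.latency_ms == 410.0
        assert pk.test_latency_ms == 410.0

    def test_empty_mask_returns_none_result(self):
        times = np.arange(0.0, 100.0, 10.0)
        acc = np.full(10, 0.6)
        cres = self._cluster_result([], acc.shape)
        pk = tg.peak_accuracy_latency(acc, cres, window=(0.0, 100.0),
                                      times=times)
        assert not pk.found
        assert pk.accuracy is None

    def test_peak_taken_from_largest_mass_cluster_only(self):
        times = np.arange(0.0, 120.0, 10.0)
        acc = np.full(12, 0.5)
        acc[2] = 0.95   # inside the small cluster
        acc[8] = 0.70   # inside the big cluster
        small = Cluster(indices=np.array([1, 2, 3]), mass=5.0, p=0.01)
        big = Cluster(indices=np.array([7, 8, 9]), mass=12.0, p=0.01)
        cres = self._cluster_result([small, big], acc.shape)
        pk = tg.peak_accuracy_latency(acc, cres, window=(0.0, 120.0),
                                      times=times)
        assert pk.accuracy == pytest.approx(0.70)
        assert pk.latency_ms == 80.0
        assert pk.cluster_mass == 12.0

    def test_window_excludes_out_of_range_peak(self):
        times = np.arange(0.0, 120.0, 10.0)
        acc = np.linspace(0.5, 0.9, 12)
        cres = self._cluster_result(
            [Cluster(indices=np.arange(12), mass=30.0, p=0.01)], acc.shape)
        pk = tg.peak_accuracy_latency(acc, cres, window=(0.0, 50.0),
                                      times=times)
        assert pk.latency_ms == 50.0
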