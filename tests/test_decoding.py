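"""Pseudopopulation assembly, SVM decoders, and permutation significance."""

import numpy as np
import pytest

import timecourt as tc
from timecourt import decoding as dec


class TestPseudoPopulation:
    def test_assembly_bookkeeping(self, rng):
        pools = {
            c: [rng.normal(size=(15, 1)) for _ in range(3)] for c in (1500.0, 3000.0, 6000.0)
        }
        pop = dec.PseudoPopulation.from_pools(pools, [0, 1, 2], min_trials=15)
        X, y = pop.draw(rng)
        assert X.shape == (45, 3, 1)
        assert np.all(np.bincount(np.searchsorted(pop.classes, y)) == 15)

    def test_same_seed_gives_identical_assembly(self, rng):
        pools = {c: [np.arange(20.0).reshape(-1, 1)] for c in (0.0, 1.0)}
        pop = dec.PseudoPopulation.from_pools(pools, [0], min_trials=10)
        a, _ = pop.draw(np.random.default_rng(5))
        b, _ = pop.draw(np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_min_trials_exclusion_records_reason(self, rng):
        pools = {
            c: [rng.normal(size=(30, 1)), rng.normal(size=(20, 1))] for c in (0.0, 1.0)
        }
        pop = dec.PseudoPopulation.from_pools(pools, [7, 8], min_trials=30)
        assert pop.neuron_ids.tolist() == [7]
        assert pop.excluded[0][0] == 8 and "min_trials" in pop.excluded[0][1]


class TestSvmDecode:
    def test_separable_clouds_decode_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (30, 4)), rng.normal(5, 0.1, (30, 4))])
        y = np.repeat([0, 1], 30)
        res = dec.svm_decode(X, y, n_folds=5, n_resamples=3, seed=0)
        assert res.mean_accuracy > 99.0

    def test_confusion_accuracy_matches_mean_accuracy(self, tuned_session):
        pop = dec.assemble_pseudopopulation(tuned_session, min_trials=15)
        res = dec.svm_decode(pop, n_folds=5, n_resamples=4, seed=1)
        assert res.confusion_accuracy == pytest.approx(res.mean_accuracy, abs=1e-6)
        # confusion row sums equal tested-trial counts
        assert np.allclose(res.confusion.sum(axis=1), 15)

    def test_shuffled_three_class_chance(self, rng):
        X = rng.normal(size=(60, 10))
        y = np.repeat([0, 1, 2], 20)
        res = dec.svm_decode(X, y, n_folds=5, n_resamples=60, shuffle=True, seed=2)
        assert res.mean_accuracy == pytest.approx(100 / 3, abs=4.0)

    def test_single_informative_neuron_among_silent(self, rng):
        signal = np.concatenate([rng.normal(0, 0.5, 30), rng.normal(3, 0.5, 30)])
        y = np.repeat([0, 1], 30)
        X1 = signal[:, None]
        X99 = np.hstack([X1, np.zeros((60, 49))])  # zero-variance padding
        a1 = dec.svm_decode(X1, y, n_folds=5, n_resamples=5, seed=3).mean_accuracy
        a99 = dec.svm_decode(X99, y, n_folds=5, n_resamples=5, seed=3).mean_accuracy
        assert abs(a1 - a99) < 2.0


class TestProtocolGeneralization:
    def test_invariant_tuning_generalizes_across_protocols(self, tuned_session):
        res = dec.protocol_generalization_decode(
            tuned_session, min_trials=10, n_resamples=8, n_shuffles=10, seed=4
        )
        within = (res["color->color"].mean_accuracy + res["shape->shape"].mean_accuracy) / 2
        across = (res["color->shape"].mean_accuracy + res["shape->color"].mean_accuracy) / 2
        assert within > 80.0
        assert abs(within - across) < 5.0

    def test_protocol_bound_tuning_does_not_generalize(self):
        task = tc.TaskConfig(n_correct_trials_per_cue=12)
        beh = tc.BehaviorModel(weber_fraction=0.15, optout_prob=0.1, lapse_prob=0.0)
        pop = [
            tc.RateProfileSpec(
                "duration_tuned", baseline=3.0, duration_gain={d: 18.0}, protocol_filter="color"
            )
            for d in (1500, 3000, 6000)
            for _ in range(3)
        ]
        ses = tc.generate_session(task, beh, pop, seed=5)
        res = dec.protocol_generalization_decode(
            ses, min_trials=10, n_resamples=8, n_shuffles=10, seed=6
        )
        assert res["color->color"].mean_accuracy > 80.0
        assert res["color->shape"].mean_accuracy < 55.0


@pytest.fixture(scope="module")
def sequence_session():
    task = tc.TaskConfig(n_correct_trials_per_cue=12)
    beh = tc.BehaviorModel(weber_fraction=0.1, optout_prob=0.0, lapse_prob=0.0)
    pop = [
        tc.RateProfileSpec("time_field", baseline=1.0, gain=40.0, center_ms=c, width_ms=80.0)
        for c in np.linspace(60, 1140, 10)
    ]
    return tc.generate_session(task, beh, pop, seed=7)


class TestElapsedTime:
    def test_bookkeeping_matches_design(self, sequence_session):
        res = dec.elapsed_time_decode(
            sequence_session, None, 1500, n_trials=20, n_bins=20, n_resamples=2, seed=8
        )
        assert res.n_observations == 400
        assert (res.n_train, res.n_test) == (320, 80)
        assert res.pred_counts.sum(axis=1).tolist() == [2 * 5 * 4] * 20
        assert res.predictions_per_bin == 2 * 5 * 4

    def test_sequence_population_decodes_elapsed_time(self, sequence_session):
        res = dec.elapsed_time_decode(
            sequence_session, None, 1500, n_trials=20, n_bins=20, n_resamples=3, seed=9
        )
        correct_bins = np.sum(np.abs(res.medians - np.arange(1, 21)) <= 1)
        assert correct_bins >= 16  # median prediction on (or next to) the true bin

    def test_untuned_population_is_near_chance(self):
        task = tc.TaskConfig(n_correct_trials_per_cue=12)
        beh = tc.BehaviorModel(weber_fraction=0.1, optout_prob=0.0, lapse_prob=0.0)
        pop = [tc.RateProfileSpec("untuned", baseline=8.0) for _ in range(6)]
        ses = tc.generate_session(task, beh, pop, seed=10)
        res = dec.elapsed_time_decode(ses, None, 1500, n_trials=20, n_bins=20, n_resamples=2, seed=11)
        assert res.accuracy < 15.0  # chance is 5%


class TestErrorTrialDecode:
    def test_swapped_late_errors_are_systematically_misclassified(self):
        task = tc.TaskConfig(n_correct_trials_per_cue=15)
        beh = tc.BehaviorModel(weber_fraction=0.12, optout_prob=0.1, lapse_prob=0.25)
        pop = [
            tc.RateProfileSpec("duration_tuned", baseline=3.0, duration_gain={d: 20.0})
            for d in (1500, 3000)
            for _ in range(4)
        ]
        ses = tc.generate_session(task, beh, pop, seed=12, late_error_mode="swapped")
        res = dec.error_trial_decode(ses, n_resamples=10, n_shuffles=20, seed=13)
        assert res.correct.mean_accuracy > 85.0
        # systematically misclassified: well below the 2-class chance of 50%
        assert res.late_error.mean_accuracy < 45.0
        assert res.late_error.mean_accuracy < res.null_p99

    def test_veridical_late_errors_decode_like_correct(self):
        task = tc.TaskConfig(n_correct_trials_per_cue=15)
        beh = tc.BehaviorModel(weber_fraction=0.12, optout_prob=0.1, lapse_prob=0.25)
        pop = [
            tc.RateProfileSpec("duration_tuned", baseline=3.0, duration_gain={d: 20.0})
            for d in (1500, 3000)
            for _ in range(4)
        ]
        ses = tc.generate_session(task, beh, pop, seed=14, late_error_mode="veridical")
        res = dec.error_trial_decode(ses, n_resamples=10, n_shuffles=0, seed=15)
        assert abs(res.correct.mean_accuracy - res.late_error.mean_accuracy) < 12.0


class TestCrossTemporal:
    @staticmethod
    def _session(archetypes: str, seed: int):
        task = tc.TaskConfig(n_correct_trials_per_cue=12)
        beh = tc.BehaviorModel(weber_fraction=0.12, optout_prob=0.1, lapse_prob=0.0)
        if archetypes == "static":
            pop = [
                tc.RateProfileSpec("duration_tuned", baseline=3.0, duration_gain={d: 18.0})
                for d in (1500, 3000, 6000)
                for _ in range(4)
            ]
        else:  # dynamic: stretched bump templates carry transient duration info
            pop = []
            for c in (150, 450, 750, 1050):
                t = np.arange(0, 1201, 10.0)
                template = 30.0 * np.exp(-0.5 * ((t - c) / 90.0) ** 2)
                pop.append(
                    tc.RateProfileSpec(
                        "scaled_template", baseline=2.0, template=template,
                        template_dt_ms=10.0, d_reference=1500.0,
                    )
                )
        return tc.generate_session(task, beh, pop, seed=seed)

    def test_static_code_generalizes_and_precue_is_chance(self):
        ses = self._session("static", 16)
        res = dec.cross_temporal_decode(
            ses, span=(-800, 1200), window_ms=200, step_ms=200,
            trials_per_class=20, n_folds=5, n_resamples=3, seed=17,
        )
        post = res.times >= 100
        pre = res.times <= -700  # windows fully before cue onset
        sub = res.accuracy[np.ix_(post, post)]
        off_diag = sub[~np.eye(len(sub), dtype=bool)]
        assert np.median(off_diag) > 80.0  # square pattern: off-diagonal generalizes
        assert abs(res.accuracy[np.ix_(pre, pre)].mean() - 100 / 3) < 12.0

    def test_dynamic_code_is_diagonal(self):
        ses = self._session("dynamic", 18)
        res = dec.cross_temporal_decode(
            ses, span=(0, 1200), window_ms=200, step_ms=200,
            trials_per_class=20, n_folds=5, n_resamples=3, seed=19,
        )
        acc = res.accuracy
        n = len(acc)
        diag = np.diag(acc).mean()
        far = np.array([acc[i, j] for i in range(n) for j in range(n) if abs(i - j) >= 3])
        assert diag > far.mean() + 15.0


class TestClusterPermutation:
    def test_null_calibration(self, rng):
        null = rng.normal(33.3, 2.0, size=(300, 15, 15))
        true = rng.normal(33.3, 2.0, size=(10, 15, 15))
        res = dec.cluster_permutation_test(true, null)
        frac_sig_pixels = (res.labels > 0).mean()
        assert frac_sig_pixels < 0.04  # ~alpha_cluster
        assert len(res.significant_clusters) == 0

    def test_solid_block_detected_as_one_cluster(self, rng):
        null = rng.normal(33.3, 2.0, size=(300, 20, 20))
        true = rng.normal(33.3, 2.0, size=(5, 20, 20))
        true[:, 5:15, 5:15] += 30.0
        res = dec.cluster_permutation_test(true, null)
        assert len(res.significant_clusters) == 1
        block = np.zeros((20, 20), dtype=bool)
        block[5:15, 5:15] = True
        overlap = (res.mask & block).sum() / block.sum()
        assert overlap > 0.9
        assert (res.mask & ~block).sum() < 10

    def test_diagonal_touch_is_two_clusters_under_4_connectivity(self):
        null = np.zeros((100, 5, 5))
        true = np.zeros((5, 5))
        true[1, 1] = true[2, 2] = 10.0
        res = dec.cluster_permutation_test(true, null)
        assert len(res.cluster_sizes) == 2


class TestBinStability:
    def test_stable_duration_code_fills_the_matrix(self):
        task = tc.TaskConfig(n_correct_trials_per_cue=12)
        beh = tc.BehaviorModel(weber_fraction=0.12, optout_prob=0.1, lapse_prob=0.0)
        pop = [
            tc.RateProfileSpec("duration_tuned", baseline=3.0, duration_gain={d: 18.0})
            for d in (1500, 3000, 6000)
            for _ in range(4)
        ]
        ses = tc.generate_session(task, beh, pop, seed=20)
        res = dec.bin_stability_decode(
            ses, n_bins=5, trials_per_class=20, n_folds=5, n_resamples=3, seed=21
        )
        assert res.accuracy.min() > 60.0  # whole matrix well above 33%
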