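"""Selectivity ANOVA, tuning curves, trend test, sequences, ramps, scaling."""

import numpy as np
import pytest

import timecourt as tc
from timecourt import single_unit as su
from timecourt._stats import balanced_anova_ss, omega_squared

# Hand-computed balanced 3 (duration) x 2 (protocol) table, 2 reps/cell:
# values 1..12 arranged so that duration carries all the structure.
TOY_Y = np.array([1, 3, 2, 4, 5, 7, 6, 8, 9, 11, 10, 12], dtype=float)
TOY_DUR = np.repeat([1500, 3000, 6000], 4)
TOY_PROT = np.tile(np.repeat(["color", "shape"], 2), 3)
# manual decomposition: SS_dur=128, SS_prot=3, SS_int=0, SS_err=12, SS_tot=143
TOY_SS = {"duration": 128.0, "protocol": 3.0, "interaction": 0.0, "error": 12.0, "total": 143.0}


class TestTwoWayAnova:
    def test_matches_hand_computed_table(self):
        res = su.two_way_anova(TOY_Y, TOY_DUR, TOY_PROT)
        for k, v in TOY_SS.items():
            assert res.ss[k] == pytest.approx(v, abs=1e-8)
        assert res.f["duration"] == pytest.approx(32.0)
        assert res.f["protocol"] == pytest.approx(1.5)
        assert res.ms_error == pytest.approx(2.0)
        assert res.classification == "time"

    def test_fast_balanced_route_agrees_with_statsmodels(self, rng):
        """The vectorized cell-means ANOVA and the OLS route must coincide."""
        y = rng.normal(5, 2, size=30)
        dur = np.repeat([1500, 3000, 6000], 10)
        prot = np.tile(np.repeat(["color", "shape"], 5), 3)
        slow = su.two_way_anova(y, dur, prot)
        ia = np.searchsorted([1500, 3000, 6000], dur)
        ib = (prot == "shape").astype(int)
        fast = balanced_anova_ss(y, ia, ib, 3, 2)
        for k in ("duration", "protocol", "interaction", "error", "total"):
            assert fast["ss"][k] == pytest.approx(slow.ss[k], rel=1e-8)

    def test_constant_data_classified_none(self):
        res = su.two_way_anova(np.full(12, 4.0), TOY_DUR, TOY_PROT)
        assert res.classification == "none"
        assert all(v == pytest.approx(0.0, abs=1e-12) for k, v in res.ss.items() if k != "total")

    def test_empty_cell_rejected(self):
        dur = np.array([1500] * 4 + [3000] * 4)
        prot = np.array(["color", "color", "shape", "shape"] * 2)
        prot[4:] = "color"  # no (3000, shape) cell
        with pytest.raises(ValueError, match="cell"):
            su.two_way_anova(np.arange(8.0), dur, prot)

    def test_sensitivity_and_false_positive_rate(self, rng):
        """Strongly tuned neurons detected; untuned flagged near alpha."""
        n_trials_cell = 12
        dur = np.repeat([1500, 3000, 6000], 2 * n_trials_cell)
        prot = np.tile(np.repeat(["color", "shape"], n_trials_cell), 3)
        gains = {1500: 12.0, 3000: 0.0, 6000: 0.0}
        hits = 0
        for _ in range(60):  # tuned
            lam = 4.0 + np.array([gains[d] for d in dur])
            y = rng.poisson(lam * 1.2) / 1.2
            hits += su.two_way_anova(y, dur, prot).classification == "time"
        fp = 0
        n_null = 200
        for _ in range(n_null):  # untuned
            y = rng.poisson(4.0 * 1.2, size=len(dur)) / 1.2
            fp += su.two_way_anova(y, dur, prot).classification == "time"
        assert hits / 60 > 0.95
        assert fp / n_null <= 0.03  # ~alpha = 0.01 with binomial slack


class TestTuningCurve:
    def test_normalization_and_monotonicity(self):
        res = su.tuning_curve({1500: 10.0, 3000: 5.0, 6000: 0.0})
        np.testing.assert_allclose(res.curve, [100.0, 50.0, 0.0])
        assert res.preferred_ms == 1500 and res.monotonic is True

    def test_weighted_sd_closed_form(self):
        # w=(1,0,1) at x=(1500,3000,6000): mean 3750, SD 2250
        res = su.tuning_curve({1500: 5.0, 3000: 0.0, 6000: 5.00001})
        assert res.weighted_sd_ms == pytest.approx(2250.0, rel=1e-3)

    def test_narrow_tuning_has_smaller_width_than_broad(self):
        narrow = su.tuning_curve({1500: 10.0, 3000: 0.0, 6000: 0.0})
        broad = su.tuning_curve({1500: 10.0, 3000: 8.0, 6000: 0.0})
        assert narrow.weighted_sd_ms < broad.weighted_sd_ms

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError):
            su.tuning_curve({1500: 2.0, 3000: 2.0, 6000: 2.0})

    def test_tie_goes_to_shorter_duration(self):
        res = su.tuning_curve({1500: 5.0, 3000: 5.0, 6000: 0.0})
        assert res.preferred_ms == 1500 and res.tie


class TestJonckheereTerpstra:
    def test_perfectly_ordered_groups_enumeration(self):
        res = su.jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == 12.0  # maximal pair count
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 90)  # 6!/(2!2!2!) arrangements

    def test_all_identical_observations(self):
        res = su.jonckheere_terpstra([[2, 2, 2], [2, 2], [2, 2, 2]], method="normal")
        assert res.z == 0.0 and res.p_value == 0.5

    def test_normal_approx_close_to_exact_at_n9(self, rng):
        for _ in range(5):
            groups = [rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)]
            exact = su.jonckheere_terpstra(groups, method="exact")
            norm = su.jonckheere_terpstra(groups, method="normal")
            assert abs(norm.p_value - exact.p_value) < 0.03

    def test_statistic_equals_brute_force_pair_count(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 6, size=rng.integers(2, 6)).astype(float) for _ in range(3)]
            t = 0.0
            for i in range(3):
                for j in range(i + 1, 3):
                    for a in groups[i]:
                        for b in groups[j]:
                            t += (a < b) + 0.5 * (a == b)
            assert su.jonckheere_terpstra(groups, method="normal").statistic == t

    def test_tuning_widths_increase_with_preferred_duration(self, tuned_session):
        """Population-level trend: longer-preferring neurons tune more broadly."""
        scan = su.scan_time_neurons(tuned_session)
        cue = tc.preprocessing.extract_window_rates(tuned_session, "cue_offset", (0, 1200))
        trials = tuned_session.trials.set_index("trial_id").loc[cue.trial_ids]
        widths = {1500: [], 3000: [], 6000: []}
        for _, row in scan[scan.time_cue].iterrows():
            j = list(cue.neuron_ids).index(row.neuron_id)
            means = {
                d: cue.rates[trials.duration_ms.to_numpy() == d, j, 0].mean()
                for d in (1500, 3000, 6000)
            }
            tr = su.tuning_curve(means)
            widths[tr.preferred_ms].append(tr.weighted_sd_ms)
        groups = [widths[d] for d in (1500, 3000, 6000) if widths[d]]
        assert len(groups) >= 2  # enough preferences represented to test a trend
        su.jonckheere_terpstra(groups, method="normal")  # runs end to end

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            su.jonckheere_terpstra([[1, 2, 3]])


class TestSequenceSurface:
    def test_time_field_rows_sorted_by_center(self, tuned_session):
        cue = tc.preprocessing.extract_window_rates(tuned_session, "cue_offset", (0, 1200), 20)
        field_ids = [n for n, s in tuned_session.specs.items() if s.archetype == "time_field"]
        idx = [list(cue.neuron_ids).index(n) for n in field_ids]
        rates = cue.rates[:, idx, :].mean(axis=0)
        surface, order = su.sequence_surface(rates, dt_ms=20)
        centers = np.array([tuned_session.specs[field_ids[i]].center_ms for i in order])
        assert np.all(np.diff(centers) > 0)  # recovered tiling order

    def test_constant_row_is_flat_zeros(self):
        rates = np.vstack([np.full(50, 4.0), np.exp(-((np.arange(50) - 30) ** 2) / 40)])
        surface, order = su.sequence_surface(rates, dt_ms=20)
        flat = surface[list(order).index(0)]
        assert np.all(flat == 0.0)

    def test_permutation_invariance_after_sorting(self, rng):
        rates = rng.random((6, 40))
        s1, _ = su.sequence_surface(rates, dt_ms=20)
        perm = rng.permutation(6)
        s2, _ = su.sequence_surface(rates[perm], dt_ms=20)
        np.testing.assert_allclose(s1, s2)


@pytest.fixture(scope="module")
def ramp_session():
    task = tc.TaskConfig(n_correct_trials_per_cue=12)
    beh = tc.BehaviorModel(weber_fraction=0.1, optout_prob=0.0, lapse_prob=0.0)
    pop = [
        tc.RateProfileSpec("ramp_linear", baseline=2.0, gain=30.0, onset_ms=0.0),
        tc.RateProfileSpec("time_field", baseline=3.0, gain=30.0, center_ms=200.0, width_ms=120.0),
    ]
    return tc.generate_session(task, beh, pop, seed=42)


class TestRamping:
    def test_linear_ramp_recovered(self, ramp_session):
        fit = su.ramping_analysis(ramp_session, 0, 3000, n_shuffles=30, n_multistart=2, seed=0)
        assert fit.increasing
        assert fit.r2["linear"] > 0.8
        assert fit.significant["linear"]

    def test_early_time_field_not_increasing(self, ramp_session):
        fit = su.ramping_analysis(ramp_session, 1, 3000, n_shuffles=5, n_multistart=2, seed=0)
        assert not fit.increasing
        assert not fit.peak_in_final

    def test_noiseless_linear_profile_r2_one_with_null_below(self, rng):
        y = np.linspace(0, 1, 12)
        x = np.linspace(0, 1, 12)
        params, r2 = su._fit_one(x, y, "linear", rng, 1)
        assert r2 == pytest.approx(1.0)
        null = [su._fit_one(x, rng.permutation(y), "linear", rng, 1)[1] for _ in range(100)]
        assert np.percentile(null, 95) < 1.0


class TestTemporalScaling:
    @staticmethod
    def _bump(n, center, width):
        t = np.arange(n) * 10.0
        return 3.0 + 20.0 * np.exp(-0.5 * ((t - center) / width) ** 2)

    def test_exact_2x_stretch_recovers_half_with_zero_mse(self):
        short = self._bump(120, 500, 150)  # 1200 ms at 10 ms bins
        t_long = np.arange(240) * 10.0
        long = np.interp(t_long / 2.0, np.arange(120) * 10.0, short)
        res = su.temporal_scaling(long, short, expected_factor=0.5)
        assert res.optimal_factor == 0.5
        assert res.optimal_mse == pytest.approx(0.0, abs=1e-18)
        assert res.within_10pct

    def test_exact_4x_stretch_recovers_quarter(self):
        short = self._bump(120, 500, 150)
        t_long = np.arange(480) * 10.0
        long = np.interp(t_long / 4.0, np.arange(120) * 10.0, short)
        res = su.temporal_scaling(long, short, expected_factor=0.25)
        assert res.optimal_factor == 0.25 and res.within_10pct

    def test_identity_scaling(self):
        p = self._bump(240, 900, 300)
        res = su.temporal_scaling(p, p)
        assert res.optimal_factor == 1.0 and res.optimal_mse == 0.0

    def test_unrelated_noise_profiles_spread_over_grid(self, rng):
        hits = 0
        opts = []
        for _ in range(100):
            long = rng.normal(size=480)
            short = rng.normal(size=120)
            res = su.temporal_scaling(long, short, expected_factor=0.25)
            opts.append(res.optimal_factor)
            hits += res.within_10pct
        # null behavior: optima scattered, few land within the 10% window
        assert len(np.unique(opts)) > 10
        assert hits < 30
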