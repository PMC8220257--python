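"""Site characterization, best frequency, maps and gradient reversal."""

import numpy as np
import pandas as pd
import pytest

from figground import session as ses
from figground import tonotopy as tn


def _flat_tuning_df(rng, n_freq=14, n_level=3, n_reps=10, effect=None):
    freqs = 180.0 * 2 ** (np.arange(n_freq) / 2)
    rows = []
    for f in freqs:
        for level in (50, 60, 70):
            gain = 0.0
            if effect is not None:
                gain = effect * np.exp(-0.5 * (np.log2(f / freqs[6]) / 1.0) ** 2)
            for _ in range(n_reps):
                rows.append(dict(frequency_hz=f, level_db=level,
                                 response=gain + rng.standard_normal()))
    return pd.DataFrame(rows)


class TestSNR:
    def _traces(self, rng, amplitude=0.0, n_trials=30):
        # 300 ms baseline + 200 ms tone + 100 ms tail of unit-mean noise
        x = 1.0 + 0.1 * rng.standard_normal((n_trials, 600))
        x[:, 310:450] += amplitude  # response spanning the full 10-150 ms window
        return x

    def test_null_response_near_zero(self, rng):
        snr = tn.compute_snr(self._traces(rng), t0_ms=-300)
        assert abs(snr) < 1.5

    def test_planted_bump_closed_form(self, rng):
        traces = self._traces(rng, amplitude=0.0)
        m = traces.mean(axis=0)
        base_sd = m[100:300].std(ddof=1)
        traces5 = traces.copy()
        traces5[:, 310:450] += 5 * base_sd
        snr = tn.compute_snr(traces5, t0_ms=-300)
        assert snr == pytest.approx(5.0, abs=1.0)

    def test_zero_baseline_sd_rejected(self):
        with pytest.raises(ValueError):
            tn.compute_snr(np.ones((5, 600)), t0_ms=-300)


class TestAnova:
    def test_null_type_i_error(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            df = _flat_tuning_df(rng, n_reps=3)
            p = tn.anova_frequency_intensity(df)["p_freq"]
            rejections += p < 0.05
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3.5 * se

    def test_power_on_planted_tuning(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(60):
            df = _flat_tuning_df(rng, n_reps=10, effect=2.0)
            hits += tn.anova_frequency_intensity(df)["p_freq"] < 0.05
        assert hits / 60 > 0.95

    def test_single_replicate_rejected(self, rng):
        df = _flat_tuning_df(rng, n_reps=1)
        with pytest.raises(ValueError):
            tn.anova_frequency_intensity(df)


class TestBestFrequency:
    def _curve(self, y):
        freqs = 180.0 * 2 ** (np.arange(14) / 2)
        return tn.TuningCurve(response=np.tile(np.asarray(y)[:, None], (1, 3)),
                              frequencies_hz=freqs, intensities_db=np.array([50, 60, 70]))

    def test_delta_curve_peak_preserved(self):
        y = np.zeros(14)
        y[7] = 1.0
        est = tn.best_frequency(self._curve(y))
        f7 = 180.0 * 2 ** (7 / 2)
        assert abs(np.log2(est.bf_hz / f7)) < 1.0 / 24.0

    def test_monotone_curve_boundary_argmax(self):
        est = tn.best_frequency(self._curve(np.linspace(0, 1, 14)))
        assert est.bf_hz == pytest.approx(180.0 * 2 ** (13 / 2), rel=0.02)

    def test_flat_curve_degenerate(self):
        est = tn.best_frequency(self._curve(np.ones(14)))
        assert est.degenerate
        mid = np.sqrt(180.0 * 180.0 * 2 ** (13 / 2))
        assert est.bf_hz == pytest.approx(mid, rel=1e-6)

    def test_gaussian_tuning_recovery_between_tones(self):
        # planted BF halfway between tones 6 and 7
        rng = np.random.default_rng(2)
        freqs = 180.0 * 2 ** (np.arange(14) / 2)
        bf_true = 180.0 * 2 ** (6.5 / 2)
        errs = []
        for _ in range(200):
            resp = np.exp(-0.5 * (np.log2(freqs / bf_true) / 1.0) ** 2)
            y = resp[:, None] + 0.05 * rng.standard_normal((14, 3))
            est = tn.best_frequency(
                tn.TuningCurve(y, freqs, np.array([50, 60, 70])))
            errs.append(abs(np.log2(est.bf_hz / bf_true)))
        assert np.mean(errs) < 0.25
        f6, f7 = freqs[6], freqs[7]
        est = tn.best_frequency(self._curve(
            np.exp(-0.5 * (np.log2(freqs / bf_true) / 1.0) ** 2)))
        assert f6 <= est.bf_hz <= f7

    def test_recovery_improves_with_repetitions(self):
        # BF error decreases in expectation with more repetitions (the
        # inclusion gate is bypassed so every draw yields an estimate)
        errs = {}
        for n_reps in (3, 30):
            rng = np.random.default_rng(5)
            site = ses.GroundTruthSite(site_id=0, grid_x=0, grid_y=0,
                                       field_label="posterior", bf_hz=1200.0)
            run = []
            for _ in range(15):
                traces, table = ses.simulate_tone_trials(site, rng, n_reps=n_reps)
                df = table.copy()
                df["response"] = (
                    traces[:, 310:450].mean(axis=1) - traces[:, 100:300].mean(axis=1)
                )
                cells = df.groupby(["frequency_hz", "level_db"])["response"].mean().unstack()
                est = tn.best_frequency(
                    tn.TuningCurve(cells.to_numpy(), cells.index.to_numpy(float),
                                   cells.columns.to_numpy(float)))
                run.append(abs(np.log2(est.bf_hz / site.bf_hz)))
            errs[n_reps] = np.mean(run)
        assert errs[30] <= errs[3]


class TestInclusion:
    def test_threshold_is_strict(self):
        # inclusion: SNR > 3 AND ANOVA p < 0.05
        kw = dict(site_id=0, anova_p_freq=0.01)
        assert tn.SiteCharacterization(snr=3.01, included=3.01 > 3 and 0.01 < 0.05, **kw).included
        assert not tn.SiteCharacterization(snr=2.99, included=2.99 > 3 and 0.01 < 0.05, **kw).included

    def test_characterize_site_end_to_end(self, rng):
        site = ses.GroundTruthSite(site_id=7, grid_x=0, grid_y=0,
                                   field_label="anterior", bf_hz=2000.0)
        traces, table = ses.simulate_tone_trials(site, rng, n_reps=10)
        char = tn.characterize_site(traces, table, t0_ms=-300.0, site_id=7)
        assert char.included
        assert abs(np.log2(char.bf_hz / site.bf_hz)) < 0.25
        assert 10 <= char.peak_latency_ms <= 60


class TestMaps:
    def test_cell_means_before_smoothing(self, rng):
        x = np.array([0.2, 0.1, 1.9, 2.1, 0.0])
        y = np.array([0.0, 0.1, 1.1, 0.9, 2.0])
        v = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        m = tn.build_map(x, y, v)
        assert m.values[0, 0] == pytest.approx(2.0)  # mean of 1 and 3
        assert m.values[1, 2] == pytest.approx(6.0)  # mean of 5 and 7
        assert m.values[2, 0] == pytest.approx(9.0)
        assert np.isnan(m.values[0, 1])

    def test_single_cell_smoothing_identity(self):
        m = tn.SpatialMap(values=np.array([[np.nan, np.nan], [np.nan, 4.2]]),
                          y_coords=np.arange(2), x_coords=np.arange(2))
        sm = tn.smooth_map(m)
        assert sm.values[1, 1] == pytest.approx(4.2)
        assert np.isnan(sm.values[0, 0])

    def test_planted_reversal_boundary(self):
        # V-shaped profile with minimum between rows 4 and 5 -> boundary 4.5
        ys, xs, vals = [], [], []
        for y in range(10):
            for x in range(4):
                ys.append(y)
                xs.append(x)
                vals.append(abs(y - 4.5))
        m = tn.smooth_map(tn.build_map(np.array(xs), np.array(ys), np.array(vals)))
        b = tn.reversal_boundary(m)
        assert b.position == pytest.approx(4.5)
        assert not b.monotone_warning
        assert tn.assign_field(5.2, b) == "anterior"
        assert tn.assign_field(3.9, b) == "posterior"

    def test_boundary_invariant_to_mediolateral_permutation(self, rng):
        ys = np.repeat(np.arange(8), 4)
        xs = np.tile(np.arange(4), 8)
        vals = np.abs(ys - 3.5) + 0.1 * rng.standard_normal(len(ys))
        b1 = tn.reversal_boundary(tn.smooth_map(tn.build_map(xs, ys, vals)))
        perm = rng.permutation(4)
        b2 = tn.reversal_boundary(tn.smooth_map(tn.build_map(perm[xs], ys, vals)))
        assert b1.position == b2.position

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            tn.build_map(np.array([0, 1, 2]), np.array([1, 1, 1]), np.ones(3))

    def test_monotone_profile_warns(self):
        ys = np.repeat(np.arange(6), 2)
        xs = np.tile(np.arange(2), 6)
        vals = ys.astype(float)  # monotone: minimum at caudal edge
        b = tn.reversal_boundary(tn.build_map(xs, ys, vals))
        assert b.monotone_warning
        assert b.position == pytest.approx(0.5)


class TestPhaseLocking:
    def test_planted_single_rate(self):
        rng = np.random.default_rng(0)
        site = ses.GroundTruthSite(site_id=0, grid_x=0, grid_y=0,
                                   field_label="posterior", bf_hz=1000.0)
        resp = ses.simulate_click_trials(site, rng, locked_rates_hz=[50.0])
        strength, locked = tn.phase_locking(resp)
        assert locked[50.0]
        assert strength in (1, 2)  # 50 Hz locked; at most one false positive

    def test_all_rates_locked(self):
        rng = np.random.default_rng(1)
        site = ses.GroundTruthSite(site_id=0, grid_x=0, grid_y=0,
                                   field_label="posterior", bf_hz=1000.0,
                                   phase_lock=True)
        strength, locked = tn.phase_locking(ses.simulate_click_trials(site, rng))
        assert strength == 4

    def test_null_false_lock_rate_matches_gaussian_tail(self):
        # threshold mean + 2 SD -> per-rate false-lock ~ P(Z > 2) for a mean
        # of n trials (approximately; power is chi-squared, so the test only
        # brackets the rate)
        rng = np.random.default_rng(2)
        site = ses.GroundTruthSite(site_id=0, grid_x=0, grid_y=0,
                                   field_label="posterior", bf_hz=1000.0)
        locks = 0
        n_sim = 300
        for _ in range(n_sim):
            resp = ses.simulate_click_trials(site, rng, rates_hz=(50.0,),
                                             locked_rates_hz=[])
            locks += tn.phase_locking(resp)[1][50.0]
        rate = locks / n_sim
        assert rate < 0.15  # small, same order as P(Z > 2) ~ 0.023


class TestSoundResponsive:
    def _control_envs(self, chord_gain, seed=0, n=20):
        from figground.stimulus import sample_sfg

        site = ses.GroundTruthSite(site_id=0, grid_x=0, grid_y=0,
                                   field_label="posterior", bf_hz=1000.0,
                                   chord_gain=chord_gain)
        stim = sample_sfg(0, rng=seed)
        rates = np.tile(ses.simulate_rate(site, stim), (n, 1))
        return ses.simulate_envelope(rates, site, np.random.default_rng(seed))

    def test_chord_locked_site_responsive(self):
        assert tn.sound_responsive(self._control_envs(0.6), t0_ms=-400)

    def test_flat_noise_not_responsive(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(40):
            env = 1.0 + 0.3 * rng.standard_normal((10, 3900))
            hits += tn.sound_responsive(env, t0_ms=-400)
        assert hits / 40 <= 0.05

    def test_tonic_response_without_chord_locking_not_responsive(self):
        # strong sustained increase but chord_gain = 0: criterion is 20-Hz
        # specific, tonic drive alone must not trigger it
        env = self._control_envs(0.0, seed=5)
        env[:, 400:3400] *= 2.0
        assert not tn.sound_responsive(env, t0_ms=-400)
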