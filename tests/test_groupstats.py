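import numpy as np
import pandas as pd
import pytest
from scipy import stats

from photoavoid import groupstats, preprocess, synth
from photoavoid.errors import ConfigError
from photoavoid.session_io import DFFTrace, SessionConfig, SpeedTrace

RATE = 15.0


def dff_trace(x, t0=0.0):
    x = np.asarray(x, float)
    return DFFTrace(t0 + np.arange(x.size) / RATE, x, RATE)


class TestAlign:
    def test_constant_trace_gives_constant_rows(self):
        tr = dff_trace(np.full(1500, 2.5))
        m = groupstats.align_to_event(tr, [20.0, 40.0, 60.0], (-4.0, 4.0))
        assert m.data.shape == (3, 121)
        assert np.all(m.data == 2.5)

    def test_window_sample_count(self):
        tr = dff_trace(np.zeros(1500))
        m = groupstats.align_to_event(tr, [50.0], (-4.0, 4.0))
        assert m.time.size == 121
        assert m.time[0] == pytest.approx(-4.0)
        assert m.time[-1] == pytest.approx(4.0)

    def test_partial_windows_dropped_and_empty_ok(self):
        tr = dff_trace(np.zeros(150))
        m = groupstats.align_to_event(tr, [0.5, 5.0, 9.9], (-2.0, 2.0))
        assert m.n_trials == 1
        empty = groupstats.align_to_event(tr, [], (-2.0, 2.0))
        assert empty.n_trials == 0

    def test_trial_average_recovers_kernel_shape(self, avoidance_session):
        s = avoidance_session
        dff, _ = preprocess.compute_dff(s.photometry)
        dff15 = preprocess.lowpass_resample(dff, s.speed.t)
        cross = s.trials.loc[s.trials["outcome"] == "avoid",
                             "crossing_time"].to_numpy(float)
        m = groupstats.align_to_event(dff15, cross, (-1.0, 2.0))
        avg = m.data.mean(axis=0)
        true_k = s.ground_truth.kernel_on_grid("avoid", m.time)
        assert np.corrcoef(avg, true_k)[0, 1] > 0.95


class TestPrePeri:
    def test_constant_trace_pre_equals_peri(self):
        tr = dff_trace(np.full(1500, 1.25))
        m = groupstats.align_to_event(tr, [30.0, 50.0], (-4.0, 4.0))
        c = groupstats.pre_peri_contrast(m)
        assert np.allclose(c["pre"], c["peri"])

    def test_linear_ramp_analytic_means(self):
        """dff(t) = t: pre mean = t0 − 3, peri mean = t0."""
        t0 = 60.0
        tr = dff_trace(np.arange(1500) / RATE)
        m = groupstats.align_to_event(tr, [t0], (-4.0, 4.0))
        c = groupstats.pre_peri_contrast(m)
        assert c.loc[0, "pre"] == pytest.approx(t0 - 3.0, abs=0.05)
        assert c.loc[0, "peri"] == pytest.approx(t0, abs=0.05)

    def test_additive_shift_equivariance(self, rng):
        x = rng.normal(0, 1, 1500)
        m1 = groupstats.align_to_event(dff_trace(x), [40.0], (-4.0, 4.0))
        m2 = groupstats.align_to_event(dff_trace(x + 7.0), [40.0], (-4.0, 4.0))
        c1, c2 = groupstats.pre_peri_contrast(m1), groupstats.pre_peri_contrast(m2)
        assert np.allclose(c2["pre"] - c1["pre"], 7.0)
        assert np.allclose(c2["peri"] - c1["peri"], 7.0)

    def test_window_too_short_rejected(self):
        tr = dff_trace(np.zeros(1500))
        m = groupstats.align_to_event(tr, [40.0], (-2.0, 2.0))
        with pytest.raises(ConfigError):
            groupstats.pre_peri_contrast(m)

    def test_crossing_locked_cohort_peri_exceeds_pre(self):
        cfg = SessionConfig(task="avoidance", n_trials=20)
        per_animal = []
        for s in synth.generate_cohort(cfg, 6, seed=2):
            dff, _ = preprocess.compute_dff(s.photometry)
            dff15 = preprocess.lowpass_resample(dff, s.speed.t)
            cross = s.trials.loc[s.trials["outcome"] == "avoid",
                                 "crossing_time"].to_numpy(float)
            m = groupstats.align_to_event(dff15, cross, (-4.0, 4.0))
            per_animal.append(groupstats.pre_peri_contrast(m))
        res = groupstats.paired_contrast_across_animals(per_animal)
        assert (res["peri_means"] > res["pre_means"]).all()
        assert res["p"] < 0.05


class TestAmplitudeStats:
    def _animal(self, rng, couple=True):
        """Constructed trials where max ΔF/F is proportional to max speed."""
        n = 20
        cross = 20.0 + 30.0 * np.arange(n)
        t = np.arange(0.0, cross[-1] + 30.0, 1 / RATE)
        speed_amp = rng.uniform(10, 30, n)
        dff_amp = speed_amp / 10.0 if couple else rng.uniform(1, 3, n)
        dff = np.zeros_like(t)
        speed = np.zeros_like(t)
        for c, sa, da in zip(cross, speed_amp, dff_amp):
            bump = np.exp(-0.5 * ((t - c) / 0.3) ** 2)
            speed += sa * bump
            dff += da * bump
        trials = pd.DataFrame({
            "trial_id": range(n), "tone_on": cross - 2.0,
            "tone_off": cross, "crossing_time": cross,
            "outcome": "avoid", "latency": 2.0, "stim": False,
            "block_id": 0, "special": ""})
        return (DFFTrace(t, dff, RATE), trials,
                SpeedTrace(t, speed, None, RATE))

    def test_constructed_coupling_gives_high_r(self, rng):
        per = [groupstats.trial_amplitude_stats(*self._animal(rng))
               for _ in range(4)]
        res = groupstats.amplitude_correlations(per)
        assert np.all(res["r_speed"] > 0.9)

    def test_uncoupled_amplitudes_r_near_zero(self):
        rng = np.random.default_rng(5)
        per = [groupstats.trial_amplitude_stats(*self._animal(rng, couple=False))
               for _ in range(8)]
        res = groupstats.amplitude_correlations(per)
        assert res["p_speed"] > 0.05

    def test_too_few_trials_excluded(self, rng):
        dff15, trials, speed = self._animal(rng)
        assert groupstats.trial_amplitude_stats(dff15, trials.head(2),
                                                speed) is None


class TestStimSpeed:
    def test_exclusion_of_early_crossings(self):
        trials = pd.DataFrame({
            "trial_id": [0, 1], "tone_on": [10.0, 60.0],
            "tone_off": [10.3, 62.0], "crossing_time": [10.3, 62.0],
            "outcome": ["avoid", "avoid"], "latency": [0.3, 2.0],
            "stim": [True, True], "block_id": [0, 0], "special": ["", ""]})
        t = np.arange(0.0, 100.0, 1 / RATE)
        speed = SpeedTrace(t, np.ones_like(t), None, RATE)
        per = groupstats.stim_window_speed(trials, speed)
        assert list(per["trial_id"]) == [1]   # +0.3 s crossing excluded

    def test_interaction_detected_for_group_specific_effect(self):
        rows = []
        rng = np.random.default_rng(0)
        for g, effect in (("NpHR", -5.0), ("eYFP", 0.0)):
            for a in range(6):
                base = rng.normal(20, 1)
                rows.append(dict(animal=f"{g}{a}", opsin=g, stim=False,
                                 mean_speed=base + rng.normal(0, 0.5)))
                rows.append(dict(animal=f"{g}{a}", opsin=g, stim=True,
                                 mean_speed=base + effect + rng.normal(0, 0.5)))
        res = groupstats.stim_speed_analysis(pd.DataFrame(rows))
        assert res["p"] < 0.01

    def test_single_animal_group_skipped(self):
        rows = [dict(animal="a", opsin="NpHR", stim=False, mean_speed=1.0),
                dict(animal="a", opsin="NpHR", stim=True, mean_speed=2.0),
                dict(animal="b", opsin="eYFP", stim=False, mean_speed=1.0),
                dict(animal="b", opsin="eYFP", stim=True, mean_speed=2.0)]
        res = groupstats.stim_speed_analysis(pd.DataFrame(rows))
        assert res["skipped"]


class TestCrossingHist:
    def _trials(self, latencies, stim):
        lat = np.asarray(latencies, float)
        return pd.DataFrame({
            "trial_id": range(lat.size), "tone_on": 0.0, "tone_off": 0.0,
            "crossing_time": np.where(np.isfinite(lat), lat, np.nan),
            "outcome": "avoid", "latency": lat, "stim": stim,
            "block_id": 0, "special": ""})

    def test_all_latencies_in_one_bin(self):
        tr = self._trials([1.0] * 10, stim=False)
        h = groupstats.crossing_probability_hist(tr)
        idx = 4                                   # bin [1.00, 1.25)
        assert h["p_no_stim"][idx] == 1.0
        assert h["p_no_stim"].sum() == 1.0

    def test_mass_conservation(self):
        lat = [0.6, 1.1, 2.2, np.nan, 8.5, 3.3]   # one miss, one > 7 s
        tr = self._trials(lat, stim=False)
        h = groupstats.crossing_probability_hist(tr)
        crossed_within = sum(1 for v in lat if np.isfinite(v) and v < 7.0)
        assert h["p_no_stim"].sum() == pytest.approx(crossed_within / len(lat))

    def test_hand_tabulated_example(self):
        """12 trials, half illuminated; ratio from direct counting."""
        stim_lat = [0.7, 1.1, 2.7, 3.1, 4.0, np.nan]
        no_lat = [0.8, 1.2, 1.9, 2.2, 2.4, 3.0]
        tr = pd.concat([self._trials(stim_lat, True),
                        self._trials(no_lat, False)], ignore_index=True)
        h = groupstats.crossing_probability_hist(tr)
        # window 0.5–2.5 s: stim crossings at 0.7, 1.1 → 2/6; no-stim at
        # 0.8, 1.2, 1.9, 2.2, 2.4 → 5/6
        assert h["window_ratio"] == pytest.approx((2 / 6) / (5 / 6))

    def test_zero_denominator_gives_nan(self):
        tr = pd.concat([self._trials([1.0], True),
                        self._trials([6.0], False)], ignore_index=True)
        h = groupstats.crossing_probability_hist(tr)
        assert np.isnan(h["window_ratio"])


class TestBlockSeries:
    def _trials(self, latencies):
        lat = np.asarray(latencies, float)
        stim = [((i // 6) % 2 == 1) for i in range(lat.size)]
        return pd.DataFrame({
            "trial_id": range(lat.size), "tone_on": 0.0, "tone_off": 0.0,
            "crossing_time": lat, "outcome": "avoid", "latency": lat,
            "stim": stim, "block_id": [i // 6 for i in range(lat.size)],
            "special": ""})

    def test_constant_latencies_flat_series(self):
        s = groupstats.block_latency_series(self._trials([2.0] * 72))
        assert s.size == 12
        assert np.allclose(s, 2.0)

    def test_stim_effect_elevates_on_positions(self):
        lat = np.array([2.0 + (1.0 if (i // 6) % 2 else 0.0)
                        for i in range(72)])
        s = groupstats.block_latency_series(self._trials(lat))
        assert np.allclose(s[:6], 2.0) and np.allclose(s[6:], 3.0)
        per_animal = np.vstack([s, s, s, s])
        c = groupstats.block_contrasts(per_animal)
        assert np.all(per_animal[:, 6] > per_animal[:, :6].mean(axis=1))

    def test_pre3_on6_post3_gives_five_chunks(self):
        tr = self._trials(np.arange(72.0))
        s = groupstats.block_latency_series(tr, chunking="pre3_on6_post3")
        # 72 trials, chunks of 12 starting at trial 3 → 5 full chunks
        starts = np.arange(3, 72 - 12 + 1, 12)
        assert len(starts) == 5
        expected = np.mean([np.arange(st, st + 12.0) for st in starts], axis=0)
        assert np.allclose(s, expected)

    def test_on6_post6_excludes_first_off_and_last_on(self):
        tr = self._trials(np.arange(72.0))
        s = groupstats.block_latency_series(tr, chunking="on6_post6")
        starts = np.arange(6, 72 - 12 + 1, 12)
        assert len(starts) == 5
        expected = np.mean([np.arange(st, st + 12.0) for st in starts], axis=0)
        assert np.allclose(s, expected)


class TestStandardTests:
    def test_paired_identical_vectors(self):
        t, p = groupstats.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_two_sample_matches_closed_form(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        t, p = groupstats.unpaired_t(a, b)
        # pooled-variance closed form
        sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
               / (a.size + b.size - 2))
        t_cf = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_cf = 2 * stats.t.sf(abs(t_cf), a.size + b.size - 2)
        assert t == pytest.approx(t_cf, abs=1e-10)
        assert p == pytest.approx(p_cf, abs=1e-10)

    def test_paired_matches_closed_form(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.5, 0.3, 10)
        t, p = groupstats.paired_t(a, b)
        d = a - b
        t_cf = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(t_cf, abs=1e-10)

    def test_repeated_anova_matches_pingouin(self, rng):
        """Cross-check the repeated-measures ANOVA against pingouin."""
        pg = pytest.importorskip("pingouin")
        rows = []
        for a in range(8):
            base = rng.normal(0, 1)
            for j, cond in enumerate(["R", "S", "L"]):
                rows.append(dict(animal=a, condition=cond,
                                 value=base + 0.4 * j + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows)
        res = groupstats.repeated_anova(df)
        ref = pg.rm_anova(data=df, dv="value", within="condition",
                          subject="animal")
        assert res["F"] == pytest.approx(float(ref["F"].iloc[0]), abs=1e-8)
        assert res["p"] == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-10)

    def test_anova_null_p_roughly_uniform(self):
        """Equal-mean groups: repeated-ANOVA p-values behave like U(0,1)."""
        ps = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            rows = [dict(animal=a, condition=c, value=r.normal())
                    for a in range(8) for c in "RSL"]
            ps.append(groupstats.repeated_anova(pd.DataFrame(rows))["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_samples_rejected(self):
        from photoavoid.errors import ValidationError
        with pytest.raises(ValidationError):
            groupstats.one_sample_t([1.0])
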