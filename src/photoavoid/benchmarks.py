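"""Ground-truth validation suite on synthetic sessions.

Each function here generates data with the synthetic module at the study
conditions, runs the corresponding analysis path, and measures how well
the known ground truth is recovered (exact kernel recovery, ΔR²
discrimination, artifact removal, cross-covariance oracles and the
post-shock coupling step, peri-event contrasts, freezing detection,
movement-detector rules, optogenetic interaction power, and closed-form
agreement of the statistical wrappers).  The functions are deterministic
given their seed and are shared by the test suite and the reproduction
script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, encoding, groupstats, preprocess, synth, xcov
from .session_io import RawPhotometry, SessionConfig, SpeedTrace

DT = 1.0 / 15.0


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, n)]


# ---------------------------------------------------------------------------
# kernel recovery (noiseless superposition model)


def kernel_recovery(seed: int = 0, n_per_type: int = 30,
                    duration: float = 600.0) -> dict:
    """Noiseless session, isolated events of one action and one sensory
    type on the 15 Hz grid; OLS recovery of both kernels.

    Returns the max abs kernel error of the fit on the session's noiseless
    ΔF/F signal (``max_abs_error``, machine-precision by construction) and
    of the full preprocess→encode chain (``end_to_end_error``), which
    carries the documented multiplicative normalization bias of the ΔF/F
    estimator and is therefore of order ``mean(ΔF/F)/100``.
    """
    cfg = SessionConfig(photometry_rate_hz=15.0)
    spacing = (duration - 20.0) / (2 * n_per_type)
    rows = [("iti_cross" if i % 2 == 0 else "tone_on", 5.0 + i * spacing, None)
            for i in range(2 * n_per_type)]
    ev = pd.DataFrame(rows, columns=["event_type", "time", "trial_id"])
    ev["trial_id"] = ev["trial_id"].astype("Int64")
    gt = synth.GroundTruth(
        kernel_params={
            "iti_cross": dict(amp=1.5, rise_s=0.1, decay_s=0.6,
                              peak_at_event=True),
            "tone_on": dict(amp=0.8, rise_s=0.1, decay_s=0.6,
                            peak_at_event=False)},
        bleach_475=(60.0, 1 / 1500, 240.0), bleach_405=(60.0, 1 / 1500, 150.0),
        noise_sd=0.0, artifact_sd=0.0, artifact_cutoff_hz=1.0,
        post_shock_gain=1.0)
    phot = synth.generate_photometry(ev, gt, cfg, seed=seed,
                                     session_end=duration)
    specs = encoding.default_specs(["iti_cross", "tone_on"], dt=DT)

    def max_err(fit):
        return max(float(np.max(np.abs(
            fit.kernels[s.event_type] - gt.kernel_on_grid(s.event_type, s.tau))))
            for s in specs)

    fit_exact = encoding.fit_session(gt.event_signal, phot.t, ev, specs)
    dff, _ = preprocess.compute_dff(phot)
    fit_e2e = encoding.fit_session(dff.dff, dff.t, ev, specs)
    return dict(max_abs_error=max_err(fit_exact),
                end_to_end_error=max_err(fit_e2e),
                r2=fit_exact.r2, n=2 * n_per_type)


# ---------------------------------------------------------------------------
# ΔR² discrimination


def crossing_only_params() -> synth.GeneratorParams:
    p = synth.GeneratorParams()
    p.kernel_amps = {"avoid": 1.5, "escape": 1.5, "iti_cross": 1.5,
                     "tone_on": 0.0, "tone_off": 0.0, "shock_on": 0.0}
    return p


def delta_r2_discrimination(seed: int = 0, n_trials: int = 30,
                            n_shuffles: int = 20) -> dict:
    """One session whose signal is driven only by crossing events; ΔR² of
    the informative crossing type vs the sham tone-offset type."""
    cfg = SessionConfig(task="avoidance", n_trials=n_trials, habituation_s=0.0)
    s = synth.generate_session(cfg, seed, crossing_only_params())
    dff, _ = preprocess.compute_dff(s.photometry)
    dff15 = preprocess.lowpass_resample(dff, s.speed.t)
    mev = encoding.label_model_events(s.events, s.trials)
    specs = encoding.default_specs(sorted(set(mev["event_type"])))
    fit = encoding.fit_session(dff15.dff, dff15.t, mev, specs)
    d_cross = encoding.delta_r2(dff15.dff, dff15.t, mev, specs, "avoid",
                                n_shuffles, seed, full_fit=fit)
    d_sham = encoding.delta_r2(dff15.dff, dff15.t, mev, specs, "tone_off",
                               n_shuffles, seed, full_fit=fit)
    return dict(delta_r2_crossing=d_cross.delta_r2,
                delta_r2_sham=d_sham.delta_r2, r2_full=fit.r2)


# ---------------------------------------------------------------------------
# ΔF/F properties


def dff_invariance(seed: int = 0, gamma: float = 3.7) -> float:
    """Max |ΔF/F change| under joint rescaling of both channels."""
    cfg = SessionConfig(task="avoidance", n_trials=10)
    s = synth.generate_session(cfg, seed)
    d1, _ = preprocess.compute_dff(s.photometry)
    p = s.photometry
    d2, _ = preprocess.compute_dff(
        RawPhotometry(p.t, gamma * p.f405, gamma * p.f475, p.rate_hz))
    return float(np.max(np.abs(d1.dff - d2.dff)))


def artifact_attenuation(seed: int = 0) -> bool:
    """True when ΔF/F correlates less with the shared motion artifact than
    the raw 475 nm trace does."""
    cfg = SessionConfig(task="avoidance", n_trials=10)
    s = synth.generate_session(cfg, seed)
    dff, _ = preprocess.compute_dff(s.photometry)
    art = s.ground_truth.artifact_trace
    return bool(abs(stats.pearsonr(dff.dff, art)[0])
                < abs(stats.pearsonr(s.photometry.f475, art)[0]))


# ---------------------------------------------------------------------------
# cross-covariance


def xcov_oracle(seed: int = 0, n_pairs: int = 100) -> dict:
    """Brute-force shifted-dot-product oracle over random segment pairs
    (lengths 40–600 samples; the lag range shrinks to fit the shortest
    segments) plus exact recovery of a known 8-sample shift."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        n = int(rng.integers(40, 601))
        max_lag = min(30, (n - 1) // 2)
        x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
        r = xcov.segment_xcov(x, y, 15.0, max_lag / 15.0, scale="none")
        xc, yc = x - x.mean(), y - y.mean()
        oracle = np.array([
            sum(xc[i + lag] * yc[i] for i in range(n) if 0 <= i + lag < n)
            for lag in range(-max_lag, max_lag + 1)])
        worst = max(worst, float(np.max(np.abs(r.values - oracle))))
    y = rng.normal(0, 1, 400)
    x = np.roll(y, 8)[8:]
    shift = xcov.segment_xcov(x, y[8:], 15.0, 2.0)
    return dict(max_abs_diff=worst, shift_lag_s=shift.extremal_lag,
                shift_sign=float(np.sign(shift.extremal_value)))


def firstday_config() -> SessionConfig:
    """First training day: habituation, two tone–shock pairings, then trials."""
    return SessionConfig(task="avoidance", n_trials=20, n_pavlovian=2,
                         habituation_s=300.0)


def post_shock_step(seed: int, gain: float, n_mice: int = 8) -> float:
    """Cohort mean of (post-first-shock − pre-shock) extremal cross-covariance."""
    params = synth.GeneratorParams()
    params.post_shock_gain = gain
    diffs = []
    for s in synth.generate_cohort(firstday_config(), n_mice, seed, params):
        dff, _ = preprocess.compute_dff(s.photometry)
        dff15 = preprocess.lowpass_resample(dff, s.speed.t)
        evo = xcov.xcov_evolution(dff15, s.speed, s.trials,
                                  s.ground_truth.first_shock_time)
        pre = evo.loc[~evo["post_first_shock"], "extremal_value"]
        post = evo.loc[evo["post_first_shock"], "extremal_value"]
        if len(pre) and len(post):
            diffs.append(post.mean() - pre.mean())
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# peri-event contrast


def peri_contrast_cohort(seed: int, n_mice: int = 8, n_trials: int = 25) -> dict:
    """Crossing-locked cohort: per-animal pre/peri means and the paired t."""
    cfg = SessionConfig(task="avoidance", n_trials=n_trials)
    per_animal = []
    for s in synth.generate_cohort(cfg, n_mice, seed):
        dff, _ = preprocess.compute_dff(s.photometry)
        dff15 = preprocess.lowpass_resample(dff, s.speed.t)
        cross = s.trials.loc[s.trials["outcome"] == "avoid",
                             "crossing_time"].to_numpy(float)
        mat = groupstats.align_to_event(dff15, cross, (-4.0, 4.0))
        per_animal.append(groupstats.pre_peri_contrast(mat))
    res = groupstats.paired_contrast_across_animals(per_animal)
    return dict(all_peri_gt_pre=bool(np.all(res["peri_means"]
                                            > res["pre_means"])),
                p=res["p"],
                mean_pre=float(res["pre_means"].mean()),
                mean_peri=float(res["peri_means"].mean()))


# ---------------------------------------------------------------------------
# freezing


def freezing_recovery(seed: int, duration: float = 120.0) -> float:
    """Bout-level IoU of detected vs true freezing on one synthetic video."""
    bouts = synth.generate_freezing_bouts(duration, seed)
    frames = synth.generate_video(bouts, duration_s=duration, seed=seed + 1)
    fr = behavior.detect_freezing(frames)
    truth = np.zeros(fr.freezing.size, bool)
    for a, b in bouts:
        truth[(fr.t >= a) & (fr.t < b)] = True
    union = (fr.freezing | truth).sum()
    if union == 0:
        return 1.0
    return float((fr.freezing & truth).sum() / union)


def freezing_identical_frames(n: int = 300) -> float:
    """Fraction of frames marked freezing on an identical-frame stack."""
    frames = np.full((n, 48, 48), 200, np.uint8)
    frames[:, 18:30, 18:30] = 5
    fr = behavior.detect_freezing(frames)
    return float(fr.freezing.mean())


# ---------------------------------------------------------------------------
# movement detector rules (hand-constructed traces)


def movement_rule_checks() -> dict:
    """Each detector rule exercised on a trace built to isolate it; every
    entry must be True (the hand-derived epoch list is matched exactly)."""
    out = {}
    t30 = np.arange(0, 30, DT)

    # absolute-height rule: a clean 9 cm/s bump is rejected
    v = 9.0 * np.exp(-0.5 * ((t30 - 15) / 0.8) ** 2)
    eps = behavior.detect_movements_iti(SpeedTrace(t30, v, None, 15.0),
                                        [(2.0, 28.0)])
    out["absolute_height"] = eps == []

    # prominence rule: a 12 cm/s ripple on a 10.5 cm/s plateau (prominence
    # ~1.5 < 3) is rejected even though it clears the height rule
    v = np.full_like(t30, 10.5)
    v += 1.5 * np.exp(-0.5 * ((t30 - 15) / 0.6) ** 2)
    v[:30] = 0.0
    eps = behavior.detect_movements_iti(SpeedTrace(t30, v, None, 15.0),
                                        [(3.0, 28.0)])
    out["prominence"] = eps == []

    # initiation rule: ramp onto a 20 cm/s peak initiates at 10% of peak
    t = np.arange(0, 30, DT)
    v = np.interp(t, [0, 10, 12, 14, 30], [0, 0, 20, 0, 0])
    eps = behavior.detect_movements_oft(SpeedTrace(t, v, None, 15.0),
                                        threshold=5.0)
    want_init = t[np.flatnonzero((t >= 10.0) & (v > 2.0))[0]]
    out["initiation_10pct"] = (len(eps) == 1
                               and abs(eps[0].init_time - want_init) < 1e-9)

    # quiescence rule: a bump preceded by super-threshold speed is dropped
    t40 = np.arange(0, 40, DT)
    v = np.interp(t40, [0, 10, 12, 13.5, 14.5, 16, 40],
                  [0, 0, 20, 6, 6, 22, 0])
    eps = behavior.detect_movements_oft(SpeedTrace(t40, v, None, 15.0),
                                        threshold=5.0)
    out["quiescence_1s"] = [round(e.peak_time) for e in eps] == [12]

    # 5-s exclusion rule: the second of two qualifying peaks 3 s apart goes
    t60 = np.arange(0, 60, DT)
    v = 15 * np.exp(-0.5 * ((t60 - 20) / 0.5) ** 2) \
        + 15 * np.exp(-0.5 * ((t60 - 23) / 0.5) ** 2)
    eps = behavior.detect_movements_iti(SpeedTrace(t60, v, None, 15.0),
                                        [(5.0, 55.0)])
    out["exclusion_5s"] = (len(eps) == 1
                           and abs(eps[0].peak_time - 20.0) < 0.25)
    return out


# ---------------------------------------------------------------------------
# optogenetic block analyses


def opto_cohort_analysis(seed: int, effect: bool,
                         n_nphr: int = 8, n_eyfp: int = 5) -> dict:
    """One simulated opsin-vs-control cohort: 72 trials, 12 alternating
    blocks, stimulation 0.5–2.5 s after tone onset.  The opsin group's
    stimulation trials are slowed (longer latency, suppressed speed) when
    ``effect`` is set; returns the two-way interaction p and the
    stimulation-window crossing-probability ratio of the opsin group."""
    nphr = synth.GeneratorParams(stim_latency_shift_s=1.0 if effect else 0.0,
                                 stim_speed_factor=0.6 if effect else 1.0)
    eyfp = synth.GeneratorParams()
    cfg = SessionConfig(task="avoidance", n_trials=72, stim=True,
                        habituation_s=0.0)
    sub = _subseeds(seed, 2)
    rows, nphr_trials = [], []
    for g, (params, n, gseed) in enumerate(
            [(nphr, n_nphr, sub[0]), (eyfp, n_eyfp, sub[1])]):
        for i, s in enumerate(synth.generate_cohort(cfg, n, gseed, params,
                                                    photometry=False)):
            per_trial = groupstats.stim_window_speed(s.trials, s.speed)
            for stim, grp in per_trial.groupby("stim"):
                rows.append(dict(animal=f"g{g}a{i}",
                                 opsin="NpHR" if g == 0 else "eYFP",
                                 stim=stim,
                                 mean_speed=grp["mean_speed"].mean()))
            if g == 0:
                nphr_trials.append(s.trials)
    anova = groupstats.stim_speed_analysis(pd.DataFrame(rows))
    hist = groupstats.crossing_probability_hist(
        pd.concat(nphr_trials, ignore_index=True))
    return dict(interaction_p=anova["p"], window_ratio=hist["window_ratio"])


# ---------------------------------------------------------------------------
# statistical wrappers vs closed forms


def stats_closed_form_check(seed: int = 0) -> float:
    """Max abs deviation of the t wrappers from hand-written closed forms."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.7, 1.3, 17)
    worst = 0.0

    t, p = groupstats.unpaired_t(a, b)
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    t_cf = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p_cf = 2 * stats.t.sf(abs(t_cf), a.size + b.size - 2)
    worst = max(worst, abs(t - t_cf), abs(p - p_cf))

    c = rng.normal(0, 1, 10)
    d = c + rng.normal(0.4, 0.5, 10)
    t, p = groupstats.paired_t(c, d)
    diff = c - d
    t_cf = diff.mean() / (diff.std(ddof=1) / np.sqrt(diff.size))
    p_cf = 2 * stats.t.sf(abs(t_cf), diff.size - 1)
    worst = max(worst, abs(t - t_cf), abs(p - p_cf))

    e = rng.normal(0.3, 1, 9)
    t, p = groupstats.one_sample_t(e)
    t_cf = e.mean() / (e.std(ddof=1) / np.sqrt(e.size))
    p_cf = 2 * stats.t.sf(abs(t_cf), e.size - 1)
    worst = max(worst, abs(t - t_cf), abs(p - p_cf))
    return float(worst)
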