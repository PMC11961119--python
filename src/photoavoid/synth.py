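"""Synthetic session generator with known ground truth.

Emulates the study conditions of a cued two-chamber task: tone-triggered
trials with a 5-s response window, a 2-s foot shock on misses,
inter-trial intervals pseudo-randomized around 40 s, optional 10%
short/long special tones or reward omissions, and optogenetic
stimulation delivered 0.5–2.5 s after tone onset on alternating blocks
of six trials.  Photometry is generated as the inverse of the ΔF/F and
kernel models used downstream:

    f475(t) = (a·e^{−b·t} + c) · (1 + s(t)/100) + artifact(t) + ε₁
    f405(t) = (a'·e^{−b'·t} + c')                + artifact(t) + ε₂

where ``s(t)`` is the kernel-convolved event signal in percent ΔF/F and
``artifact`` is a band-limited motion component added equally to both
channels.  Movement-locked kernels are scaled by ``post_shock_gain`` for
events after the first shock, emulating the shock-gated coupling between
activity and locomotion.

Every generated quantity is recomputable from ``(config, seed)``; the
hidden parameters and realized nuisance draws are returned as a
:class:`GroundTruth` for recovery tests.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import encoding
from .errors import ConfigError, GenerationError
from .session_io import (RawPhotometry, Session, SessionConfig, SpeedTrace,
                         make_events)

DEFAULT_KERNEL_AMPS = {
    "avoid": 1.5,      # % ΔF/F at peak; avoidance crossings carry the strongest response
    "escape": 1.0,
    "iti_cross": 1.2,
    "crossing": 1.5,
    "tone_on": 0.3,
    "tone_off": 0.0,   # flat tone-offset kernel: the signal tracks the action, not the cue
    "shock_on": 2.0,
}


@dataclass
class GeneratorParams:
    """Tunable knobs of the generator (defaults = the emulated study conditions)."""

    # crossing latency: shift + lognormal(median, sigma) → ~80% within the 5-s window
    latency_shift_s: float = 0.5
    latency_median_s: float = 2.0
    latency_sigma: float = 0.9
    escape_latency_range: tuple = (0.2, 2.5)   # uniform; beyond the shock → fail
    # optogenetic effect (applied to stimulation trials only)
    stim_latency_shift_s: float = 0.0
    stim_speed_factor: float = 1.0
    # calcium kernels: difference of exponentials, GCaMP6f-like dynamics
    kernel_amps: dict = field(default_factory=lambda: dict(DEFAULT_KERNEL_AMPS))
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 0.6
    post_shock_gain: float = 1.0
    # raw fluorescence model
    # both channels bleach with the same kinetics (same fluorophore pool,
    # same fiber) and differ in baseline level; the 405→475 linear fit then
    # has slope ≈ 1, so the shared additive artifact is removed by the
    # subtraction — the property the reference channel exists to provide
    bleach_475: tuple = (60.0, 1.0 / 1500.0, 240.0)
    bleach_405: tuple = (60.0, 1.0 / 1500.0, 150.0)
    artifact_sd: float = 1.0          # raw fluorescence units, shared across channels
    artifact_cutoff_hz: float = 1.0
    noise_sd: float = 0.3             # independent per channel, raw units
    # locomotion model
    movement_rate_hz: float = 1.0 / 15.0   # spontaneous movement epochs per second
    movement_min_gap_s: float = 8.0
    movement_peak_range: tuple = (12.0, 25.0)
    crossing_peak_range: tuple = (15.0, 30.0)
    movement_sigma_s: float = 0.4     # Gaussian speed bump width
    iti_cross_prob: float = 0.5       # fraction of ITI movements that cross the midline
    speed_noise_sd: float = 0.3


@dataclass
class GroundTruth:
    """Hidden generator state needed to score recovery."""

    kernel_params: dict               # event_type -> {amp, rise_s, decay_s, peak_at_event}
    bleach_475: tuple
    bleach_405: tuple
    noise_sd: float
    artifact_sd: float
    artifact_cutoff_hz: float
    post_shock_gain: float
    first_shock_time: float | None = None
    movement_epochs: list = field(default_factory=list)   # dicts: init/peak/end/peak_speed/crossing
    freezing_bouts: list = field(default_factory=list)    # (start, end) seconds
    artifact_trace: np.ndarray | None = None
    event_signal: np.ndarray | None = None                # s(t) on the photometry grid

    def kernel_on_grid(self, event_type: str, tau: np.ndarray) -> np.ndarray:
        """Sample the continuous true kernel of one event type at lags ``tau``."""
        if event_type not in self.kernel_params:
            raise GenerationError(f"no true kernel for event type {event_type!r}")
        p = self.kernel_params[event_type]
        return _doe_kernel(np.asarray(tau, float), p["amp"], p["rise_s"],
                           p["decay_s"], p["peak_at_event"])

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("artifact_trace", "event_signal"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        for key in ("artifact_trace", "event_signal"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], float)
        for key in ("bleach_475", "bleach_405"):
            d[key] = tuple(d[key])
        d["movement_epochs"] = [dict(e) for e in d.get("movement_epochs", [])]
        d["freezing_bouts"] = [tuple(b) for b in d.get("freezing_bouts", [])]
        return cls(**d)


def _doe_kernel(tau: np.ndarray, amp: float, rise: float, decay: float,
                peak_at_event: bool) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to ``amp``."""
    if rise <= 0 or decay <= rise:
        raise GenerationError("need 0 < rise < decay")
    u_peak = math.log(decay / rise) / (1.0 / rise - 1.0 / decay)
    g_peak = math.exp(-u_peak / decay) - math.exp(-u_peak / rise)
    u = tau + u_peak if peak_at_event else tau
    g = np.where(u >= 0, np.exp(-np.maximum(u, 0) / decay)
                 - np.exp(-np.maximum(u, 0) / rise), 0.0)
    return amp * g / g_peak


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# trials and events


def generate_trials(config: SessionConfig, seed: int,
                    params: GeneratorParams | None = None):
    """Trial sequence with outcomes, special trials, and stimulation blocks.

    Returns ``(events, trials)`` as validated DataFrames.  ITIs are drawn
    uniformly on ``[0.5, 1.5]·iti_mean_s``; crossing latencies from a
    shifted log-normal; escapes occur when a uniform escape latency falls
    inside the shock.
    """
    params = params or GeneratorParams()
    if config.task != "oft" and config.n_trials <= 0:
        raise ConfigError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    ev: list[tuple] = []
    rows: list[dict] = []
    if config.task == "oft":
        return make_events(ev), pd.DataFrame(columns=pd.Index(
            ["trial_id", "tone_on", "tone_off", "crossing_time", "outcome",
             "latency", "stim", "block_id", "special"]))

    t = config.habituation_s
    first_shock = None
    trial_id = 0
    window = config.response_window_s

    def add_shock(time):
        nonlocal first_shock
        ev.append(("shock_on", time, trial_id))
        if first_shock is None:
            first_shock = time
            ev.append(("first_shock", time, trial_id))

    for _ in range(config.n_pavlovian):
        t += rng.uniform(0.5, 1.5) * config.iti_mean_s
        tone_on = t
        tone_off = tone_on + config.tone_max_s
        ev.append(("tone_on", tone_on, trial_id))
        add_shock(tone_on + config.tone_max_s - config.shock_dur_s)
        ev.append(("tone_off", tone_off, trial_id))
        rows.append(dict(trial_id=trial_id, tone_on=tone_on, tone_off=tone_off,
                         crossing_time=np.nan, outcome="fail", latency=np.nan,
                         stim=False, block_id=-1, special="pavlovian"))
        trial_id += 1
        t = tone_off

    for i in range(config.n_trials):
        stim_flag = bool(config.stim and ((i // config.stim_block_len) % 2 == 1))
        block_id = i // config.stim_block_len if config.stim else 0
        special = ""
        if config.special_tones:
            u = rng.random()
            if u < config.special_trial_fraction:
                special = "short"
            elif u < 2 * config.special_trial_fraction:
                special = "long"

        t += rng.uniform(0.5, 1.5) * config.iti_mean_s
        tone_on = t
        lat = params.latency_shift_s + rng.lognormal(
            math.log(params.latency_median_s), params.latency_sigma)
        if stim_flag:
            lat += params.stim_latency_shift_s

        crossing = np.nan
        latency = np.nan
        ev.append(("tone_on", tone_on, trial_id))
        if stim_flag:
            ev.append(("laser_on", tone_on + config.stim_window[0], trial_id))
            ev.append(("laser_off", tone_on + config.stim_window[1], trial_id))

        if config.task == "avoidance":
            if special == "short":
                tone_off = tone_on + 1.5          # no shock in short-tone trials
                if lat <= 1.5:
                    crossing, latency, outcome = tone_on + lat, lat, "avoid"
                else:
                    outcome = "fail"
            elif lat <= window:
                crossing, latency, outcome = tone_on + lat, lat, "avoid"
                tone_off = crossing + (1.5 if special == "long" else 0.0)
            else:
                shock_on = tone_on + window
                add_shock(shock_on)
                esc = rng.uniform(*params.escape_latency_range)
                if esc <= config.shock_dur_s:
                    crossing = shock_on + esc
                    latency = crossing - tone_on
                    outcome = "escape"
                else:
                    outcome = "fail"
                tone_off = tone_on + config.tone_max_s
        else:  # approach: same structure, reward instead of shock
            if lat <= window:
                crossing, latency = tone_on + lat, lat
                tone_off = crossing
                if rng.random() < config.special_trial_fraction:
                    outcome = "omission"
                else:
                    outcome = "approach"
                    first_lick = crossing + rng.uniform(0.5, 1.5)
                    for k in range(3):
                        ev.append(("lick", first_lick + 0.3 * k, trial_id))
            else:
                outcome = "fail"
                tone_off = tone_on + window

        if np.isfinite(crossing):
            ev.append(("crossing", crossing, trial_id))
        ev.append(("tone_off", tone_off, trial_id))
        rows.append(dict(trial_id=trial_id, tone_on=tone_on, tone_off=tone_off,
                         crossing_time=crossing, outcome=outcome, latency=latency,
                         stim=stim_flag, block_id=block_id, special=special))
        t = max(tone_off, crossing if np.isfinite(crossing) else tone_off)
        trial_id += 1

    events = make_events(ev)
    trials = pd.DataFrame(rows)
    return events, trials


def session_end_time(events: pd.DataFrame, config: SessionConfig) -> float:
    if len(events) == 0:
        return config.oft_duration_s
    return float(events["time"].max()) + config.iti_mean_s


def draw_movement_epochs(trials: pd.DataFrame, config: SessionConfig,
                         params: GeneratorParams, rng,
                         habituation: bool = True) -> list[dict]:
    """ITI (and habituation) movement epochs with peak times and speeds."""
    margin = config.detectors.iti_margin_s + 1.0
    windows = []
    if habituation and config.habituation_s > 10.0:
        windows.append((5.0, config.habituation_s - 5.0))
    tone_ons = trials["tone_on"].to_numpy(float)
    ends = np.maximum(trials["tone_off"].to_numpy(float),
                      trials["crossing_time"].fillna(-np.inf).to_numpy(float))
    for i in range(len(trials) - 1):
        lo, hi = ends[i] + margin, tone_ons[i + 1] - margin
        if hi - lo > 4.0:
            windows.append((lo, hi))
    epochs = []
    sig = params.movement_sigma_s
    init_off = sig * math.sqrt(2.0 * math.log(10.0))       # 10%-of-peak point
    for lo, hi in windows:
        dur = hi - lo - 4.0                                # 2-s margins
        if dur <= 0:
            continue
        n = rng.poisson(dur * params.movement_rate_hz)
        peaks = np.sort(rng.uniform(lo + 2.0, hi - 2.0, size=n))
        last = -np.inf
        for peak in peaks:
            if peak - last < params.movement_min_gap_s:
                continue
            last = peak
            epochs.append(dict(
                init=peak - init_off, peak=peak, end=peak + init_off,
                peak_speed=float(rng.uniform(*params.movement_peak_range)),
                crossing=bool(rng.random() < params.iti_cross_prob)))
    return epochs


# ---------------------------------------------------------------------------
# continuous traces


def generate_speed(trials: pd.DataFrame, ground_truth: GroundTruth,
                   config: SessionConfig, seed: int, session_end: float,
                   params: GeneratorParams | None = None) -> SpeedTrace:
    """15-frames/s speed and position with movement bumps at crossings and
    ITI epochs, near-zero speed in freezing bouts, and midline sign changes
    at every crossing."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.video_rate_hz
    t = np.arange(0.0, session_end, dt)
    speed = np.zeros_like(t)
    sig = params.movement_sigma_s

    def add_bump(center, peak):
        lo = np.searchsorted(t, center - 5 * sig)
        hi = np.searchsorted(t, center + 5 * sig)
        speed[lo:hi] += peak * np.exp(-0.5 * ((t[lo:hi] - center) / sig) ** 2)

    crossing_times = []
    for _, tr in trials.iterrows():
        if np.isfinite(tr["crossing_time"]):
            peak = rng.uniform(*params.crossing_peak_range)
            if tr["stim"]:
                peak *= params.stim_speed_factor
            add_bump(tr["crossing_time"], peak)
            crossing_times.append(tr["crossing_time"])
    for ep in ground_truth.movement_epochs:
        add_bump(ep["peak"], ep["peak_speed"])
        if ep["crossing"]:
            crossing_times.append(ep["peak"])

    speed += np.abs(rng.normal(0.0, params.speed_noise_sd, size=t.size))
    for start, end in ground_truth.freezing_bouts:
        mask = (t >= start) & (t < end)
        speed[mask] = np.abs(rng.normal(0.0, 0.02, size=int(mask.sum())))

    # midline position: each crossing flips the side, smoothly, with the
    # sign change exactly at the crossing time
    position = np.full_like(t, 1.0)
    for tc in sorted(crossing_times):
        position *= np.tanh((tc - t) / 0.3)
    position = -10.0 * position
    return SpeedTrace(t, speed, position, rate_hz=config.video_rate_hz)


def event_signal(events: pd.DataFrame, ground_truth: GroundTruth,
                 t: np.ndarray, first_shock_time: float | None = None) -> np.ndarray:
    """Kernel-convolved event signal s(t), percent ΔF/F, on grid ``t``.

    Equivalent, sample for sample, to the encoding design matrix times the
    true kernel vectors; movement-locked (action) kernels of events after
    ``first_shock_time`` are scaled by the post-shock gain.
    """
    t = np.asarray(t, float)
    dt = float(t[1] - t[0])
    s = np.zeros_like(t)
    present = sorted(set(events["event_type"]))
    missing = [et for et in present if et not in ground_truth.kernel_params]
    if missing:
        raise GenerationError(f"no true kernel defined for event types {missing}")
    specs = encoding.default_specs(present, dt=dt)
    gain = ground_truth.post_shock_gain
    for spec in specs:
        k = ground_truth.kernel_on_grid(spec.event_type, spec.tau)
        times = events.loc[events["event_type"] == spec.event_type,
                           "time"].to_numpy(float)
        idx = encoding.snap_to_grid(times, t[0], dt)
        for j, time in zip(idx, times):
            w = 1.0
            if (gain != 1.0 and first_shock_time is not None
                    and spec.klass == "action" and time > first_shock_time):
                w = gain
            rows = j + spec.lags
            ok = (rows >= 0) & (rows < t.size)
            s[rows[ok]] += w * k[ok]
    return s


def generate_photometry(events: pd.DataFrame, ground_truth: GroundTruth,
                        config: SessionConfig, seed: int,
                        session_end: float) -> RawPhotometry:
    """Two-channel photometry from the generative ΔF/F model.

    ``events`` must already carry model event types (avoid, escape,
    iti_cross, tone_on, tone_off, shock_on); a missing kernel raises a
    :class:`GenerationError` naming the type.
    """
    rng = np.random.default_rng(seed)
    fs = config.photometry_rate_hz
    t = np.arange(0.0, session_end, 1.0 / fs)
    s = event_signal(events, ground_truth, t, ground_truth.first_shock_time)

    a, b, c = ground_truth.bleach_475
    a4, b4, c4 = ground_truth.bleach_405
    f475 = (a * np.exp(-b * t) + c) * (1.0 + s / 100.0)
    f405 = a4 * np.exp(-b4 * t) + c4

    artifact = np.zeros_like(t)
    if ground_truth.artifact_sd > 0:
        from scipy import signal as sps
        white = rng.normal(0.0, 1.0, size=t.size)
        sos = sps.butter(2, ground_truth.artifact_cutoff_hz / (fs / 2.0),
                         output="sos")
        artifact = sps.sosfiltfilt(sos, white)
        sd = artifact.std()
        artifact = ground_truth.artifact_sd * artifact / sd if sd > 0 else artifact
    f475 = f475 + artifact
    f405 = f405 + artifact
    if ground_truth.noise_sd > 0:
        f475 = f475 + rng.normal(0.0, ground_truth.noise_sd, size=t.size)
        f405 = f405 + rng.normal(0.0, ground_truth.noise_sd, size=t.size)

    ground_truth.artifact_trace = artifact
    ground_truth.event_signal = s
    return RawPhotometry(t, f405, f475, rate_hz=fs)


# ---------------------------------------------------------------------------
# video


def generate_video(freezing_bouts, frame_shape=(64, 64), rate: float = 15.0,
                   duration_s: float = 120.0, seed: int = 0,
                   blob_radius: int = 12, jitter_px: int = 6,
                   background: int = 200, blob_value: int = 10) -> np.ndarray:
    """Grayscale frame stack: a dark blob on a light background that is
    static during freezing bouts and jumps ≥ ``jitter_px`` otherwise."""
    h, w = frame_shape
    margin = blob_radius + jitter_px + 2
    if h < 2 * margin or w < 2 * margin:
        raise ConfigError("frame_shape too small for the blob and its jitter")
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    bouts = [(float(a), float(b)) for a, b in freezing_bouts]
    for a, b in bouts:
        if a < 0 or b > duration_s or b <= a:
            raise ConfigError(f"freezing bout ({a}, {b}) outside the session")

    def frozen(i):
        time = i / rate
        return any(a <= time < b for a, b in bouts)

    steps = jitter_px * np.array(
        [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)])
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.full((n, h, w), background, dtype=np.uint8)
    cy, cx = h // 2, w // 2
    for i in range(n):
        if i > 0 and not frozen(i):
            dy, dx = steps[rng.integers(0, len(steps))]
            # reflect at the walls so the displacement is never absorbed
            if not margin <= cy + dy <= h - margin - 1:
                dy = -dy
            if not margin <= cx + dx <= w - margin - 1:
                dx = -dx
            cy, cx = cy + dy, cx + dx
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= blob_radius ** 2
        frames[i][mask] = blob_value
    return frames


def generate_freezing_bouts(duration_s: float, seed: int,
                            bout_range=(3.0, 15.0), gap_range=(5.0, 20.0),
                            t_start: float = 5.0) -> list[tuple]:
    """Non-overlapping freezing bouts with uniform durations and gaps."""
    rng = np.random.default_rng(seed)
    bouts = []
    t = t_start + rng.uniform(0.0, gap_range[0])
    while True:
        dur = rng.uniform(*bout_range)
        if t + dur > duration_s - 2.0:
            break
        bouts.append((t, t + dur))
        t += dur + rng.uniform(*gap_range)
    return bouts


# ---------------------------------------------------------------------------
# whole sessions


def generate_session(config: SessionConfig, seed: int,
                     params: GeneratorParams | None = None,
                     photometry: bool = True) -> Session:
    """One complete synthetic session (events, trials, speed, photometry)."""
    params = params or GeneratorParams()
    s_trials, s_epochs, s_speed, s_phot = _child_seeds(seed, 4)
    events, trials = generate_trials(config, s_trials, params)
    end = session_end_time(events, config)

    fs_times = events.loc[events["event_type"] == "first_shock", "time"]
    first_shock = float(fs_times.iloc[0]) if len(fs_times) else None

    rng = np.random.default_rng(s_epochs)
    epochs = draw_movement_epochs(trials, config, params, rng) if len(trials) else []
    gt = GroundTruth(
        kernel_params={et: dict(amp=amp, rise_s=params.kernel_rise_s,
                                decay_s=params.kernel_decay_s,
                                peak_at_event=et in encoding.ACTION_EVENTS)
                       for et, amp in params.kernel_amps.items()},
        bleach_475=tuple(params.bleach_475),
        bleach_405=tuple(params.bleach_405),
        noise_sd=params.noise_sd,
        artifact_sd=params.artifact_sd,
        artifact_cutoff_hz=params.artifact_cutoff_hz,
        post_shock_gain=params.post_shock_gain,
        first_shock_time=first_shock,
        movement_epochs=epochs,
    )

    iti_cross = [("crossing", ep["peak"], None) for ep in epochs if ep["crossing"]]
    if iti_cross:
        events = make_events(
            list(events.itertuples(index=False, name=None)) + iti_cross)

    speed = generate_speed(trials, gt, config, s_speed, end, params)
    phot = None
    if photometry and config.task != "oft":
        model_ev = encoding.label_model_events(events, trials)
        phot = generate_photometry(model_ev, gt, config, s_phot, end)
    return Session(phot, speed, events, config, trials, gt)


def generate_cohort(config: SessionConfig, n_mice: int, seed: int,
                    params: GeneratorParams | None = None,
                    photometry: bool = True) -> list[Session]:
    """Independent sessions for ``n_mice`` animals (seeds derived from ``seed``)."""
    seeds = _child_seeds(seed, n_mice)
    return [generate_session(config, s, params, photometry) for s in seeds]
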