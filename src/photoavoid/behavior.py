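"""Movement-epoch detection, freezing detection, and trial scoring.

Movement epochs are speed peaks passing absolute-height and prominence
rules, with initiation defined as the earliest time within 2 s before
the peak at which the speed exceeds 10% of the peak speed.  Open-field
epochs use a data-driven threshold (k-means on speeds) with prominence
5 cm/s and a 1-s pre-initiation quiescence rule; inter-trial epochs use
a fixed 10 cm/s height, prominence 3 cm/s, 7-frame Gaussian smoothing
and a 5-s refractory exclusion.  Freezing is detected from grayscale
video by counting changed mouse pixels (silhouette = pixels below an
intensity threshold) between frames, band-limiting that movement signal,
and marking frames whose filtered count falls below 190 pixels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.cluster import KMeans

from .errors import DegenerateFitError, ValidationError
from .session_io import (DetectorParams, SessionConfig, SpeedTrace,
                         event_times)

log = logging.getLogger(__name__)


@dataclass
class MovementEpoch:
    init_time: float
    peak_time: float
    peak_speed: float
    context: str  # "oft" | "habituation" | "iti"


@dataclass
class FreezingTrace:
    t: np.ndarray
    freezing: np.ndarray  # boolean per frame
    rate_hz: float

    @property
    def bouts(self) -> list[tuple[float, float]]:
        """Maximal runs of freezing frames as (start, end) seconds."""
        f = np.asarray(self.freezing, bool)
        if f.size == 0:
            return []
        padded = np.concatenate([[False], f, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        starts, ends = edges[::2], edges[1::2]
        dt = 1.0 / self.rate_hz
        return [(float(self.t[a]), float(self.t[b - 1] + dt))
                for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# movement


def movement_threshold_oft(speed: np.ndarray, seed: int = 0) -> float:
    """Speed threshold from k-means (k=3) over instantaneous speeds.

    Clusters are ordered by centroid (nonmovement, low movement, high
    movement); the threshold is the lowest speed among samples assigned
    to the middle (low-movement) cluster, so it is invariant to k-means
    label permutations.
    """
    speed = np.asarray(speed, float)
    if np.unique(speed).size < 3:
        raise DegenerateFitError("need at least 3 distinct speed values")
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    labels = km.fit_predict(speed.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    low_label = order[1]
    return float(speed[labels == low_label].min())


def find_movement_initiation(speed: SpeedTrace, peak_time: float,
                             peak_speed: float,
                             frac: float = 0.1,
                             window_s: float = 2.0) -> float | None:
    """Earliest time in ``[peak−window, peak]`` with speed above
    ``frac·peak_speed``; ``None`` if the speed never drops to that level
    inside the window."""
    t, v = speed.t, speed.speed
    sel = (t >= peak_time - window_s) & (t <= peak_time)
    tw, vw = t[sel], v[sel]
    if tw.size == 0:
        return None
    level = frac * peak_speed
    if not np.any(vw <= level):
        return None
    above = np.flatnonzero(vw > level)
    return float(tw[above[0]]) if above.size else None


def _gaussian_smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Gaussian-weighted moving average (σ = window/5, truncated and
    renormalized at the edges)."""
    sigma = window / 5.0
    half = window // 2
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def detect_movements_oft(speed: SpeedTrace, threshold: float | None = None,
                         detectors: DetectorParams | None = None,
                         context: str = "oft",
                         seed: int = 0) -> list[MovementEpoch]:
    """Open-field movement epochs: peak height ≥ threshold, prominence ≥ 5,
    a resolvable initiation, and ≥ 1 s below threshold before initiation."""
    d = detectors or DetectorParams()
    if threshold is None:
        threshold = movement_threshold_oft(speed.speed, seed=seed)
    v = speed.speed
    peaks, _ = signal.find_peaks(v, height=threshold, prominence=d.oft_prominence)
    dt = 1.0 / speed.rate_hz
    epochs: list[MovementEpoch] = []
    for p in peaks:
        pt, pv = float(speed.t[p]), float(v[p])
        init = find_movement_initiation(speed, pt, pv, d.initiation_frac,
                                        d.initiation_window_s)
        if init is None:
            continue
        # quiescence: the second preceding initiation stays below threshold;
        # time before the trace is treated as still (zero-speed padding)
        i0 = np.searchsorted(speed.t, init - d.quiescence_s)
        i1 = np.searchsorted(speed.t, init - 0.5 * dt)
        if np.any(v[i0:i1] >= threshold):
            continue
        epochs.append(MovementEpoch(init, pt, pv, context))
    return epochs


def iti_windows(trials: pd.DataFrame, margin_s: float = 5.0) -> list[tuple]:
    """Inter-trial windows from 5 s after the end of each trial to 5 s
    before the next tone onset."""
    out = []
    ends = np.maximum(trials["tone_off"].to_numpy(float),
                      trials["crossing_time"].fillna(-np.inf).to_numpy(float))
    tone_ons = trials["tone_on"].to_numpy(float)
    for i in range(len(trials) - 1):
        lo, hi = ends[i] + margin_s, tone_ons[i + 1] - margin_s
        if hi > lo:
            out.append((float(lo), float(hi)))
    return out


def detect_movements_iti(speed: SpeedTrace, windows,
                         detectors: DetectorParams | None = None,
                         context: str = "iti") -> list[MovementEpoch]:
    """Movement epochs inside ITI windows on the smoothed speed trace.

    Peaks need absolute height > 10 cm/s and prominence ≥ 3 cm/s; a peak
    within 5 s after a kept one is excluded (greedy, in time order).
    """
    d = detectors or DetectorParams()
    windows = sorted(windows)
    for (a0, b0), (a1, _) in zip(windows, windows[1:]):
        if a1 < b0:
            raise ValidationError("overlapping ITI windows")
    sm = _gaussian_smooth(speed.speed, d.iti_smooth_window)
    smoothed = SpeedTrace(speed.t, np.maximum(sm, 0.0), None, speed.rate_hz)
    candidates = []
    for lo, hi in windows:
        i0, i1 = np.searchsorted(speed.t, [lo, hi])
        if i1 - i0 < 3:
            continue
        seg = sm[i0:i1]
        peaks, _ = signal.find_peaks(seg, prominence=d.iti_prominence)
        for p in peaks:
            if seg[p] > d.iti_peak_height:
                candidates.append((float(speed.t[i0 + p]), float(seg[p])))
    candidates.sort()
    epochs: list[MovementEpoch] = []
    last_kept = -np.inf
    for pt, pv in candidates:
        if pt - last_kept <= d.iti_exclusion_s:
            continue
        init = find_movement_initiation(smoothed, pt, pv, d.initiation_frac,
                                        d.initiation_window_s)
        epochs.append(MovementEpoch(init if init is not None else pt, pt, pv,
                                    context))
        last_kept = pt
    return epochs


# ---------------------------------------------------------------------------
# freezing


def load_frames(path) -> np.ndarray:
    """Load a grayscale frame stack from a TIFF or a .npy array file."""
    from pathlib import Path
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        frames = tifffile.imread(p)
    elif p.suffix.lower() == ".npy":
        frames = np.load(p)
    else:
        raise ValidationError(f"unsupported frame-stack format: {p.suffix}")
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValidationError("frame stack must be (n_frames, height, width)")
    return frames


def detect_freezing(frames: np.ndarray, detectors: DetectorParams | None = None,
                    rate_hz: float = 15.0, t0: float = 0.0) -> FreezingTrace:
    """Frame-differencing freezing detector.

    The mouse silhouette is segmented by thresholding pixel values below
    ``freeze_pixel_thresh``; the per-frame movement signal is the count of
    silhouette pixels that changed since the previous frame.  That signal
    is smoothed by a zero-phase Butterworth lowpass at the upper band edge
    (a fraction of Nyquist) so that implausibly fast switching between
    states is suppressed; frames whose filtered count is below
    ``freeze_changed_thresh`` are marked freezing.  The lower band edge is
    applied as a highpass only when ``freeze_highpass`` is enabled: an
    absolute pixel-count threshold needs the sustained (near-DC) component
    of the movement signal, which a highpass would strip from long bouts
    and long movement stretches alike.  The first frame inherits the
    second frame's label.
    """
    d = detectors or DetectorParams()
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValidationError("need a non-empty (n, h, w) grayscale stack")
    mouse = frames < d.freeze_pixel_thresh
    changed = np.count_nonzero(mouse[1:] ^ mouse[:-1], axis=(1, 2)).astype(float)

    lo, hi = d.freeze_band
    if changed.size > 12 and 0 < hi < 1:
        if d.freeze_highpass and lo > 0:
            sos = signal.butter(2, [lo, hi], btype="bandpass", output="sos")
        else:
            sos = signal.butter(2, hi, btype="lowpass", output="sos")
        filtered = signal.sosfiltfilt(sos, changed)
    else:
        filtered = changed
    freezing = np.empty(frames.shape[0], dtype=bool)
    freezing[1:] = filtered < d.freeze_changed_thresh
    freezing[0] = freezing[1] if frames.shape[0] > 1 else True
    t = t0 + np.arange(frames.shape[0]) / rate_hz
    return FreezingTrace(t, freezing, rate_hz)


def freezing_latency_ratio(trials: pd.DataFrame,
                           freezing: FreezingTrace) -> pd.Series:
    """Per-trial ratio of freezing duration to avoidance latency.

    Freezing frames are counted in ``[tone_on, crossing)``; trials without
    a crossing or with zero latency are skipped (NaN) with a log entry.
    """
    ratios = {}
    f = np.asarray(freezing.freezing, bool)
    for _, tr in trials.iterrows():
        tid = tr["trial_id"]
        if not np.isfinite(tr["crossing_time"]) or not np.isfinite(tr["latency"]):
            continue
        if tr["latency"] <= 0:
            log.warning("trial %s has zero latency; ratio undefined", tid)
            continue
        i0 = np.searchsorted(freezing.t, tr["tone_on"])
        i1 = np.searchsorted(freezing.t, tr["crossing_time"])
        n_total = i1 - i0
        if n_total <= 0:
            continue
        ratios[tid] = float(np.count_nonzero(f[i0:i1]) / n_total)
    return pd.Series(ratios, name="freezing_latency_ratio", dtype=float)


# ---------------------------------------------------------------------------
# trial scoring


def detect_crossings(speed: SpeedTrace, midline_x: float = 0.0,
                     hysteresis_cm: float = 1.0) -> np.ndarray:
    """Midline crossing times from position sign changes with hysteresis.

    A crossing is registered when the position passes the midline after
    having been at least ``hysteresis_cm`` beyond it on the previous side,
    which suppresses tracking jitter around the midline.
    """
    if speed.position_x is None:
        raise ValidationError("position_x required to detect crossings")
    x = speed.position_x - midline_x
    t = speed.t
    crossings = []
    # armed side: the side the animal has committed to (beyond hysteresis)
    side = 0
    for i in range(x.size):
        if side == 0:
            if abs(x[i]) >= hysteresis_cm:
                side = int(np.sign(x[i]))
            continue
        if x[i] * side < 0:  # crossed the midline from the armed side
            crossings.append(t[i])
            side = int(np.sign(x[i])) if abs(x[i]) >= hysteresis_cm else 0
        elif abs(x[i]) >= hysteresis_cm:
            side = int(np.sign(x[i]))
    return np.asarray(crossings, float)


def score_trials(events: pd.DataFrame, speed: SpeedTrace | None,
                 config: SessionConfig) -> pd.DataFrame:
    """Score trials from tone events plus crossings.

    Crossings are taken from the event table when present, otherwise
    detected from ``position_x``.  Within the response window a crossing
    scores ``avoid`` (``approach`` in the approach task, or ``omission``
    if flagged); during the shock it scores ``escape``; otherwise the
    trial is a ``fail``.
    """
    tone_ons = event_times(events, "tone_on")
    if tone_ons.size == 0:
        raise ValidationError("no tone_on events to score")
    tone_offs = event_times(events, "tone_off")
    shock_ons = event_times(events, "shock_on")
    licks = event_times(events, "lick")
    lasers = event_times(events, "laser_on")
    cross = event_times(events, "crossing")
    if cross.size == 0 and speed is not None and speed.position_x is not None:
        cross = detect_crossings(speed, config.detectors.midline_x,
                                 config.detectors.midline_hysteresis_cm)

    # data-ordering check: a crossing tagged to a trial must not precede
    # that trial's tone onset
    tagged = events[(events["event_type"] == "crossing")
                    & events["trial_id"].notna()]
    tones = events[events["event_type"] == "tone_on"].set_index("trial_id")
    for _, row in tagged.iterrows():
        tid = row["trial_id"]
        if tid in tones.index and row["time"] < tones.loc[tid, "time"]:
            raise ValidationError(
                f"crossing precedes tone_on within trial {tid}")

    window = config.response_window_s
    rows = []
    for i, on in enumerate(tone_ons):
        t_next = tone_ons[i + 1] if i + 1 < tone_ons.size else np.inf
        off_candidates = tone_offs[(tone_offs >= on) & (tone_offs < t_next)]
        off = float(off_candidates[0]) if off_candidates.size else min(
            on + config.tone_max_s, t_next)
        trial_end = max(off, on + config.tone_max_s)
        in_trial = cross[(cross < min(t_next, trial_end)) & (cross >= on)]
        crossing = float(in_trial[0]) if in_trial.size else np.nan
        shock = shock_ons[(shock_ons >= on) & (shock_ons < t_next)]
        shock_on = float(shock[0]) if shock.size else np.nan
        stim = bool(np.any((lasers >= on) & (lasers < t_next)))

        latency = np.nan
        if np.isfinite(crossing):
            latency = crossing - on
            if latency <= window:
                if config.task == "approach":
                    got_water = np.any((licks >= crossing) & (licks < t_next))
                    outcome = "approach" if got_water else "omission"
                else:
                    outcome = "avoid"
            elif np.isfinite(shock_on) and crossing <= shock_on + config.shock_dur_s:
                outcome = "escape"
            else:
                outcome = "fail"
                crossing, latency = np.nan, np.nan
        else:
            outcome = "fail"
        rows.append(dict(trial_id=i, tone_on=float(on), tone_off=off,
                         crossing_time=crossing, outcome=outcome,
                         latency=latency, stim=stim, block_id=0, special=""))
    return pd.DataFrame(rows)
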