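"""Segment-wise cross-covariance between ΔF/F and locomotion speed.

Each inter-trial segment runs from 5 s after tone offset to 5 s before
the next tone onset.  For each segment the mean-removed cross-covariance
of the (15 Hz, lowpassed) ΔF/F and the speed trace is computed at lags
up to ±2 s, and the signed value with the largest magnitude across lags
is the segment's summary statistic.  Tracking these summaries in trial
order shows when neural activity becomes coupled to movement — in the
emulated paradigm, immediately after the first foot shock.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .session_io import DFFTrace, SpeedTrace

log = logging.getLogger(__name__)

MIN_SEGMENT_SAMPLES = 61   # 2·max_lag + 1 at 15 Hz


@dataclass
class XcovResult:
    segment_id: int
    trial_index: int
    lags: np.ndarray           # seconds, symmetric about 0
    values: np.ndarray         # covariance at each lag
    extremal_value: float      # signed value of largest magnitude
    extremal_lag: float


def segment_xcov(x: np.ndarray, y: np.ndarray, rate_hz: float = 15.0,
                 max_lag_s: float = 2.0, segment_id: int = 0,
                 trial_index: int = -1, scale: str = "biased",
                 normalize: bool = False) -> XcovResult:
    """Mean-removed cross-covariance of two equal-length traces.

    ``values[ℓ] = Σ_i (x[i+ℓ] − x̄)(y[i] − ȳ)`` over the overlapping
    samples, divided by the segment length under the default ``"biased"``
    scaling so that segments of different durations are comparable
    (``scale="none"`` keeps the raw sums).  Setting ``normalize`` applies
    the correlation-coefficient scaling instead.  Ties in ``|values|``
    keep the earlier lag.  Constant input gives all-zero values (not an
    error).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("segments must be equal-length 1-d arrays")
    if scale not in ("biased", "none"):
        raise ValueError("scale must be 'biased' or 'none'")
    max_lag = int(round(max_lag_s * rate_hz))
    if x.size < 2 * max_lag + 1:
        raise AlignmentError("segment shorter than the lag window")
    xc = x - x.mean()
    yc = y - y.mean()
    full = np.correlate(xc, yc, mode="full")   # index n−1+ℓ holds Σ x[i+ℓ]·y[i]
    mid = x.size - 1
    values = full[mid - max_lag: mid + max_lag + 1]
    if normalize:
        denom = np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
        values = values / denom if denom > 0 else np.zeros_like(values)
    elif scale == "biased":
        values = values / x.size
    lags = np.arange(-max_lag, max_lag + 1) / rate_hz
    k = int(np.argmax(np.abs(values)))         # first (earliest lag) on ties
    return XcovResult(segment_id, trial_index, lags, values,
                      float(values[k]), float(lags[k]))


def extract_segments(dff15: DFFTrace, speed: SpeedTrace, trials: pd.DataFrame,
                     margin_s: float = 5.0,
                     min_samples: int = MIN_SEGMENT_SAMPLES,
                     include_habituation: bool = True,
                     hab_chunk_s: float = 40.0):
    """Paired (ΔF/F, speed) inter-trial segments.

    ``dff15`` must already live on the video time base.  Segments shorter
    than ``min_samples`` are dropped with a log entry.  When the session
    has a pre-task period (before the first tone), it is processed as its
    own segment set (``trial_index = −1``), chopped into chunks of roughly
    ``hab_chunk_s`` so its segments are commensurate with inter-trial ones.
    """
    if dff15.t.shape != speed.t.shape or np.max(np.abs(dff15.t - speed.t)) > 1e-6:
        raise AlignmentError("ΔF/F and speed must share the video time base")
    tone_ons = trials["tone_on"].to_numpy(float)
    tone_offs = trials["tone_off"].to_numpy(float)
    bounds = []
    if include_habituation and len(trials) and tone_ons[0] > margin_s:
        hab_end = tone_ons[0] - margin_s
        n_chunks = max(1, int(round((hab_end - dff15.t[0]) / hab_chunk_s)))
        edges = np.linspace(dff15.t[0], hab_end, n_chunks + 1)
        for a, b in zip(edges[:-1], edges[1:]):
            bounds.append((-1, a, b))
    for i in range(len(trials) - 1):
        bounds.append((i, tone_offs[i] + margin_s, tone_ons[i + 1] - margin_s))
    segments = []
    for trial_index, lo, hi in bounds:
        i0, i1 = np.searchsorted(dff15.t, [lo, hi])
        if i1 - i0 < min_samples:
            log.info("segment after trial %d too short (%d samples); dropped",
                     trial_index, i1 - i0)
            continue
        segments.append(dict(trial_index=int(trial_index),
                             dff=dff15.dff[i0:i1], speed=speed.speed[i0:i1],
                             t0=float(dff15.t[i0])))
    return segments


def xcov_evolution(dff15: DFFTrace, speed: SpeedTrace, trials: pd.DataFrame,
                   first_shock_time: float | None = None,
                   rate_hz: float = 15.0, max_lag_s: float = 2.0,
                   success_window: int = 5, scale: str = "biased",
                   normalize: bool = False) -> pd.DataFrame:
    """Per-segment extremal cross-covariance in trial order.

    Returns one row per retained segment with the extremal value and lag,
    whether the segment follows the first shock, and the running avoidance
    success rate at that trial (mean of the surrounding ``success_window``
    trial outcomes).
    """
    segments = extract_segments(dff15, speed, trials)
    success = (trials["outcome"].isin(["avoid", "approach"])).to_numpy(float)
    rows = []
    for seg_id, seg in enumerate(segments):
        r = segment_xcov(seg["dff"], seg["speed"], rate_hz, max_lag_s,
                         segment_id=seg_id, trial_index=seg["trial_index"],
                         scale=scale, normalize=normalize)
        ti = seg["trial_index"]
        if ti >= 0:
            lo = max(0, ti - success_window // 2)
            rate = float(np.mean(success[lo: ti + success_window // 2 + 1]))
        else:
            rate = np.nan
        rows.append(dict(segment_id=seg_id, trial_index=ti,
                         t0=seg["t0"],
                         extremal_value=r.extremal_value,
                         extremal_lag=r.extremal_lag,
                         post_first_shock=bool(
                             first_shock_time is not None
                             and seg["t0"] > first_shock_time),
                         success_rate=rate))
    return pd.DataFrame(rows)
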