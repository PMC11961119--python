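"""Peri-event alignment and the group-level statistical analyses.

Covers: trial alignment of ΔF/F or speed to task events; the pre/peri
contrast around chamber crossing (mean ΔF/F 4–2 s before vs ±1 s around
the crossing, paired t across animals); trial-amplitude correlations
(max ΔF/F around crossing vs max speed and vs latency, one-sample t on
per-animal Pearson r); optogenetic speed and crossing-probability
analyses (two-way opsin × stimulation ANOVA; 0.25-s latency histograms
0–7 s with the stimulation-window probability ratio); block-structure
latency series; and thin wrappers over the routine tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import AnovaRM, anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigError, ValidationError
from .session_io import DFFTrace

log = logging.getLogger(__name__)


@dataclass
class PeriEventMatrix:
    data: np.ndarray          # trials × time
    time: np.ndarray          # seconds relative to the event
    alignment: str
    event_times: np.ndarray   # the events actually retained

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def align_to_event(trace: DFFTrace, event_times, window: tuple[float, float],
                   alignment: str = "crossing") -> PeriEventMatrix:
    """Trials × time matrix of the trace around each event.

    The trace must be uniformly sampled; events are snapped to the nearest
    sample and rows with partial windows are dropped (logged).  An empty
    event list yields an empty (0 × n) matrix.
    """
    t = trace.t
    dt = 1.0 / trace.rate_hz
    lo = int(round(window[0] / dt))
    hi = int(round(window[1] / dt))
    rel = np.arange(lo, hi + 1) * dt
    rows, kept = [], []
    for te in np.asarray(event_times, float):
        i = int(np.ceil((te - t[0]) / dt - 0.5))
        if i + lo < 0 or i + hi >= t.size:
            log.info("event at %.2f s has a partial window; dropped", te)
            continue
        rows.append(trace.dff[i + lo: i + hi + 1])
        kept.append(te)
    data = np.vstack(rows) if rows else np.empty((0, rel.size))
    return PeriEventMatrix(data, rel, alignment, np.asarray(kept))


def pre_peri_contrast(matrix: PeriEventMatrix,
                      pre_window: tuple[float, float] = (-4.0, -2.0),
                      peri_window: tuple[float, float] = (-1.0, 1.0)) -> pd.DataFrame:
    """Per-trial mean ΔF/F 4–2 s before vs 1 s before/after the event.

    The pre window is half-open on the left edge convention ``[−4, −2)``
    so its last sample is not shared with any adjacent window; peri is
    the closed ``[−1, +1]``.
    """
    tt = matrix.time
    if tt[0] > pre_window[0] + 1e-9 or tt[-1] < peri_window[1] - 1e-9:
        raise ConfigError("alignment window must cover the pre and peri windows")
    pre_sel = (tt >= pre_window[0] - 1e-9) & (tt < pre_window[1] - 1e-9)
    peri_sel = (tt >= peri_window[0] - 1e-9) & (tt <= peri_window[1] + 1e-9)
    return pd.DataFrame({
        "pre": matrix.data[:, pre_sel].mean(axis=1),
        "peri": matrix.data[:, peri_sel].mean(axis=1),
    })


def paired_contrast_across_animals(per_animal: list[pd.DataFrame]) -> dict:
    """Animal-level means of a per-trial (pre, peri) table, paired t-test."""
    pre = np.array([df["pre"].mean() for df in per_animal])
    peri = np.array([df["peri"].mean() for df in per_animal])
    t, p = stats.ttest_rel(peri, pre)
    return dict(pre_means=pre, peri_means=peri, t=float(t), p=float(p),
                n_animals=len(per_animal))


def trial_amplitude_stats(dff15: DFFTrace, trials: pd.DataFrame,
                          speed) -> pd.DataFrame | None:
    """Per-trial amplitude summaries for one animal's successful trials.

    max ΔF/F is taken 0.5 s before to 1 s after the crossing; max speed
    0.5 s before and after it.  Animals with fewer than 3 successful
    trials are excluded (returns ``None``, logged).
    """
    ok = trials[trials["outcome"].isin(["avoid", "approach"])
                & np.isfinite(trials["crossing_time"])]
    if len(ok) < 3:
        log.warning("fewer than 3 successful trials; animal excluded")
        return None
    rows = []
    for _, tr in ok.iterrows():
        tc = tr["crossing_time"]
        d0, d1 = np.searchsorted(dff15.t, [tc - 0.5, tc + 1.0])
        s0, s1 = np.searchsorted(speed.t, [tc - 0.5, tc + 0.5])
        if d1 <= d0 or s1 <= s0:
            continue
        rows.append(dict(trial_id=tr["trial_id"],
                         max_dff=float(dff15.dff[d0:d1].max()),
                         max_speed=float(speed.speed[s0:s1].max()),
                         latency=float(tr["latency"])))
    return pd.DataFrame(rows)


def amplitude_correlations(per_animal: list[pd.DataFrame]) -> dict:
    """Per-animal Pearson r (max ΔF/F vs max speed, vs latency) and the
    one-sample t-test of each correlation against zero across animals."""
    r_speed, r_lat = [], []
    for df in per_animal:
        if df is None or len(df) < 3:
            continue
        r_speed.append(stats.pearsonr(df["max_dff"], df["max_speed"])[0])
        r_lat.append(stats.pearsonr(df["max_dff"], df["latency"])[0])
    t_s, p_s = stats.ttest_1samp(r_speed, 0.0)
    t_l, p_l = stats.ttest_1samp(r_lat, 0.0)
    return dict(r_speed=np.asarray(r_speed), r_latency=np.asarray(r_lat),
                t_speed=float(t_s), p_speed=float(p_s),
                t_latency=float(t_l), p_latency=float(p_l))


# ---------------------------------------------------------------------------
# optogenetics


def stim_window_speed(trials: pd.DataFrame, speed,
                      stim_window: tuple[float, float] = (0.5, 2.5)) -> pd.DataFrame:
    """Per-trial mean speed in the stimulation window after tone onset.

    Trials where the animal crossed before the window opened (and so was
    already on the far side when the laser would fire) are excluded.
    """
    rows = []
    for _, tr in trials.iterrows():
        if tr.get("special", "") == "pavlovian":
            continue
        on = tr["tone_on"]
        if np.isfinite(tr["crossing_time"]) and (
                tr["crossing_time"] < on + stim_window[0]):
            continue
        i0, i1 = np.searchsorted(speed.t, [on + stim_window[0],
                                           on + stim_window[1]])
        if i1 <= i0:
            continue
        rows.append(dict(trial_id=tr["trial_id"], stim=bool(tr["stim"]),
                         mean_speed=float(speed.speed[i0:i1].mean())))
    return pd.DataFrame(rows)


def stim_speed_analysis(per_animal: pd.DataFrame) -> dict:
    """Two-way ANOVA (opsin × stimulation) on per-animal mean speeds.

    ``per_animal`` needs columns animal, opsin, stim, mean_speed with one
    row per (animal, stim condition).  Returns the interaction F and p.
    """
    groups = per_animal.groupby("opsin")["animal"].nunique()
    if (groups < 2).any():
        log.warning("a group has fewer than 2 animals; ANOVA skipped")
        return dict(F=np.nan, p=np.nan, table=None, skipped=True)
    model = ols("mean_speed ~ C(opsin) * C(stim)", data=per_animal).fit()
    table = anova_lm(model, typ=2)
    inter = table.loc["C(opsin):C(stim)"]
    return dict(F=float(inter["F"]), p=float(inter["PR(>F)"]),
                table=table, skipped=False)


def crossing_probability_hist(trials: pd.DataFrame, bin_s: float = 0.25,
                              t_max: float = 7.0,
                              stim_window: tuple[float, float] = (0.5, 2.5)) -> dict:
    """Crossing-latency histograms per condition and the stim/no-stim ratio.

    Latencies of all crossed trials are binned into 0.25-s bins over
    0–7 s and normalized by the total trial count of the condition, so
    the bin sum is the fraction of trials with a crossing ≤ 7 s.  The
    ratio divides the summed probability inside the stimulation window
    under illumination by the same quantity without illumination; a zero
    denominator yields NaN.
    """
    edges = np.arange(0.0, t_max + bin_s / 2, bin_s)
    out = {}
    for label, sel in (("stim", trials["stim"].astype(bool)),
                       ("no_stim", ~trials["stim"].astype(bool))):
        sub = trials[sel]
        n_total = len(sub)
        lat = sub["latency"].dropna().to_numpy(float)
        counts, _ = np.histogram(lat, bins=edges)
        out[label] = counts / n_total if n_total else np.zeros(len(edges) - 1)
    centers = edges[:-1] + bin_s / 2
    in_win = (edges[:-1] >= stim_window[0] - 1e-9) & (edges[1:] <= stim_window[1] + 1e-9)
    p_stim = float(out["stim"][in_win].sum())
    p_no = float(out["no_stim"][in_win].sum())
    ratio = p_stim / p_no if p_no > 0 else np.nan
    if p_no == 0:
        log.warning("no unilluminated crossings in the window; ratio undefined")
    return dict(edges=edges, centers=centers, p_stim=out["stim"],
                p_no_stim=out["no_stim"], window_ratio=ratio)


CHUNKINGS = ("pre6_on6", "on6_post6", "pre3_on6_post3")


def block_latency_series(trials: pd.DataFrame, chunking: str = "pre6_on6",
                         block_len: int = 6) -> np.ndarray:
    """Chunk-aligned mean latencies at relative trial positions.

    ``pre6_on6`` sections the session into chunks of (block_len off +
    block_len on) trials; ``on6_post6`` aligns on→off transitions, which
    drops the first off and last on block; ``pre3_on6_post3`` centers each
    on-block between its flanking half off-blocks.  Failed trials (no
    crossing) contribute NaN and are ignored in the position means.
    """
    if chunking not in CHUNKINGS:
        raise ConfigError(f"unknown chunking {chunking!r}")
    main = trials[trials["block_id"] >= 0].reset_index(drop=True)
    lat = main["latency"].to_numpy(float)
    n = len(main)
    L = 2 * block_len
    if chunking == "pre6_on6":
        starts = np.arange(0, n - L + 1, L)
    elif chunking == "on6_post6":
        starts = np.arange(block_len, n - L + 1, L)
    else:  # pre3_on6_post3
        starts = np.arange(block_len // 2, n - L + 1, L)
    if n % L:
        log.info("%d trailing trials do not fill a chunk; dropped", n % L)
    chunks = np.vstack([lat[s: s + L] for s in starts])
    with np.errstate(invalid="ignore"):
        return np.nanmean(chunks, axis=0)


def block_contrasts(per_animal_series: np.ndarray, block_len: int = 6,
                    chunking: str = "pre6_on6") -> dict:
    """Paired t-tests between block positions across animals.

    For the off→on chunkings: the first stimulated position vs the mean of
    the pre-stimulation positions, and the first stimulated position vs
    the mean of the remaining stimulated positions.
    """
    s = np.asarray(per_animal_series, float)   # animals × positions
    first_on = s[:, block_len]
    pre_mean = np.nanmean(s[:, :block_len], axis=1)
    rest_on = np.nanmean(s[:, block_len + 1: 2 * block_len], axis=1)
    t1, p1 = stats.ttest_rel(first_on, pre_mean)
    t2, p2 = stats.ttest_rel(first_on, rest_on)
    return dict(first_on_vs_pre=(float(t1), float(p1)),
                first_on_vs_rest=(float(t2), float(p2)))


# ---------------------------------------------------------------------------
# routine tests


def paired_t(a, b) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2:
        raise ValidationError("need at least 2 pairs")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def unpaired_t(a, b) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 samples per group")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def one_sample_t(a, popmean: float = 0.0) -> tuple[float, float]:
    a = np.asarray(a, float)
    if a.size < 2:
        raise ValidationError("need at least 2 samples")
    t, p = stats.ttest_1samp(a, popmean)
    return float(t), float(p)


def repeated_anova(data: pd.DataFrame, dv: str = "value",
                   subject: str = "animal", within: str = "condition") -> dict:
    """One-way repeated-measures ANOVA with Tukey HSD post-hoc pairs."""
    res = AnovaRM(data, depvar=dv, subject=subject, within=[within]).fit()
    row = res.anova_table.iloc[0]
    tukey = pairwise_tukeyhsd(data[dv], data[within])
    return dict(F=float(row["F Value"]), p=float(row["Pr > F"]),
                df=(float(row["Num DF"]), float(row["Den DF"])),
                posthoc=pd.DataFrame(tukey.summary().data[1:],
                                     columns=tukey.summary().data[0]))
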