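"""Event-kernel linear encoding model with shuffled-event ΔR².

The calcium signal is modeled as a superposition of event-locked kernels,

    ΔF/F(t) = Σ_i Σ_τ k_i(τ) · N_i(t − τ) + intercept + error,

where ``N_i`` counts events of type ``i`` at each sample.  *Action*
kernels (avoidance, escape, inter-trial crossing) span −1 s to +2 s
around the event so that they cover the movement from initiation to
termination; *sensory* kernels (tone onset, tone offset, shock onset)
start at the event and last 2 s.  Kernels are estimated by ordinary
least squares on a uniform time grid.

The unique contribution of one event type is measured as
``ΔR² = R²_full − mean_shuffles R²_reduced`` where each reduced model
refits every kernel after replacing that type's event times with times
drawn uniformly over the session.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConfigError
from .session_io import event_times

log = logging.getLogger(__name__)

ACTION_WINDOW = (-1.0, 2.0)
SENSORY_WINDOW = (0.0, 2.0)

#: model event types derived from a scored session
ACTION_EVENTS = ("avoid", "escape", "iti_cross", "crossing")
SENSORY_EVENTS = ("tone_on", "tone_off", "shock_on")


@dataclass
class KernelSpec:
    """Time window and resolution of one event type's kernel."""

    event_type: str
    klass: str                       # "action" | "sensory"
    window: tuple[float, float] | None = None
    dt: float = 1.0 / 15.0

    def __post_init__(self):
        if self.klass not in ("action", "sensory"):
            raise ConfigError(f"unknown kernel class {self.klass!r}")
        if self.window is None:
            self.window = ACTION_WINDOW if self.klass == "action" else SENSORY_WINDOW
        if self.window[0] >= self.window[1]:
            raise ConfigError("kernel window start must precede end")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        n = (self.window[1] - self.window[0]) / self.dt
        if abs(n - round(n)) > 1e-6:
            raise ConfigError("window endpoints must be integer multiples of dt")

    @property
    def n_taps(self) -> int:
        return int(round((self.window[1] - self.window[0]) / self.dt)) + 1

    @property
    def lags(self) -> np.ndarray:
        """Lag index of each tap relative to the event sample."""
        start = int(round(self.window[0] / self.dt))
        return np.arange(start, start + self.n_taps)

    @property
    def tau(self) -> np.ndarray:
        return self.lags * self.dt


def default_specs(event_types, dt: float = 1.0 / 15.0) -> list[KernelSpec]:
    """Action/sensory kernel specs for the given model event types."""
    specs = []
    for et in event_types:
        if et in ACTION_EVENTS:
            specs.append(KernelSpec(et, "action", dt=dt))
        elif et in SENSORY_EVENTS:
            specs.append(KernelSpec(et, "sensory", dt=dt))
        else:
            raise ConfigError(f"no kernel class known for event type {et!r}")
    return specs


def label_model_events(events: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Split generic ``crossing`` events into model event types.

    Crossings belonging to a scored trial become ``avoid`` or ``escape``
    according to the trial outcome (``approach`` crossings are treated as
    actions under the label ``avoid`` of the mirrored task structure);
    crossings without a trial become ``iti_cross``.  Sensory events pass
    through unchanged; laser/lick/first_shock markers are dropped.
    """
    outcome_by_trial = dict(zip(trials["trial_id"], trials["outcome"]))
    rows = []
    for _, ev in events.iterrows():
        et, time, tid = ev["event_type"], ev["time"], ev["trial_id"]
        if et in ("tone_on", "tone_off", "shock_on"):
            rows.append((et, time, tid))
        elif et == "crossing":
            if pd.isna(tid):
                rows.append(("iti_cross", time, tid))
            else:
                outcome = outcome_by_trial.get(tid, "avoid")
                label = "escape" if outcome == "escape" else "avoid"
                rows.append((label, time, tid))
    out = pd.DataFrame(rows, columns=["event_type", "time", "trial_id"])
    out["trial_id"] = out["trial_id"].astype("Int64")
    return out


def snap_to_grid(times: np.ndarray, t0: float, dt: float) -> np.ndarray:
    """Nearest-sample indices; exact midpoints snap to the earlier sample."""
    x = (np.asarray(times, float) - t0) / dt
    return np.ceil(x - 0.5).astype(int)


def build_design_matrix(events: pd.DataFrame, specs: list[KernelSpec],
                        t: np.ndarray):
    """Design matrix of lagged event indicators plus an intercept column.

    ``t`` must be evenly spaced at the specs' ``dt``.  Column ``(e, τ)``
    holds, at row ``i``, the number of events of type ``e`` snapped to
    sample ``i − τ/dt``.  Returns ``(X, columns)`` where ``columns`` is a
    list of ``(event_type, tau)`` pairs followed by ``"intercept"``.
    """
    t = np.asarray(t, float)
    dt = specs[0].dt if specs else 1.0 / 15.0
    for s in specs:
        if abs(s.dt - dt) > 1e-12:
            raise ConfigError("all kernel specs must share one dt")
    if t.size > 1 and np.max(np.abs(np.diff(t) - dt)) > 1e-6 * dt:
        raise ConfigError("time base must be evenly spaced at the kernel dt")

    present = set(events["event_type"])
    known = {s.event_type for s in specs}
    unknown = present - known
    if unknown:
        raise ConfigError(f"event types without a kernel spec: {sorted(unknown)}")

    n = t.size
    n_cols = sum(s.n_taps for s in specs) + 1
    X = np.zeros((n, n_cols))
    columns: list = []
    col = 0
    for s in specs:
        idx = snap_to_grid(event_times(events, s.event_type), t[0], dt)
        for lag, tau in zip(s.lags, s.tau):
            rows = idx + lag
            rows = rows[(rows >= 0) & (rows < n)]
            np.add.at(X[:, col], rows, 1.0)
            columns.append((s.event_type, float(tau)))
            col += 1
    X[:, -1] = 1.0
    columns.append("intercept")
    return X, columns


@dataclass
class EncodingFit:
    """OLS solution of the kernel model and its diagnostics."""

    kernels: dict[str, np.ndarray]
    taus: dict[str, np.ndarray]
    intercept: float
    r2: float
    residuals: np.ndarray
    n_samples: int
    n_params: int
    rank: int


def fit_kernels(X: np.ndarray, dff: np.ndarray, columns) -> EncodingFit:
    """Least-squares kernel estimates and the coefficient of determination.

    Uses a rank-revealing solver (SVD); a rank-deficient design yields the
    minimum-norm solution with a logged warning rather than an error.
    """
    y = np.asarray(dff, float)
    # cond truncates near-collinear directions (e.g. tone offsets coinciding
    # with avoidance crossings) instead of letting them blow up
    coef, _, rank, _ = linalg.lstsq(X, y, cond=1e-8, lapack_driver="gelsd")
    if rank < X.shape[1]:
        log.warning("rank-deficient design (%d < %d); minimum-norm solution",
                    rank, X.shape[1])
    fitted = X @ coef
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    kernels: dict[str, np.ndarray] = {}
    taus: dict[str, np.ndarray] = {}
    for j, colkey in enumerate(columns):
        if colkey == "intercept":
            intercept = float(coef[j])
            continue
        et, tau = colkey
        kernels.setdefault(et, []).append(coef[j])
        taus.setdefault(et, []).append(tau)
    kernels = {k: np.asarray(v) for k, v in kernels.items()}
    taus = {k: np.asarray(v) for k, v in taus.items()}
    return EncodingFit(kernels, taus, intercept, r2, resid,
                       n_samples=X.shape[0], n_params=X.shape[1], rank=rank)


def fit_session(dff: np.ndarray, t: np.ndarray, events: pd.DataFrame,
                specs: list[KernelSpec]) -> EncodingFit:
    X, columns = build_design_matrix(events, specs, t)
    return fit_kernels(X, dff, columns)


def extract_kernel(fit: EncodingFit, event_type: str):
    """(τ grid, coefficients) of one fitted kernel, in ΔF/F percent per event."""
    if event_type not in fit.kernels:
        raise KeyError(f"no kernel fitted for event type {event_type!r}")
    return fit.taus[event_type], fit.kernels[event_type]


def shuffle_events(events: pd.DataFrame, event_type: str,
                   rng, t_span: tuple[float, float]) -> pd.DataFrame:
    """Replace one event type's times with uniform draws over the session.

    All other event types are returned unchanged (same rows, same order).
    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = events.copy()
    mask = out["event_type"] == event_type
    n = int(mask.sum())
    out.loc[mask, "time"] = rng.uniform(t_span[0], t_span[1], size=n)
    return out


@dataclass
class DeltaR2Result:
    """Loss of explanatory power when one event type's times are shuffled."""

    event_type: str
    r2_full: float
    r2_reduced_per_shuffle: np.ndarray
    n_shuffles: int
    seed: int
    kernels_full: dict = field(repr=False, default_factory=dict)

    @property
    def r2_reduced_mean(self) -> float:
        return float(np.mean(self.r2_reduced_per_shuffle))

    @property
    def delta_r2(self) -> float:
        return self.r2_full - self.r2_reduced_mean


def delta_r2(dff: np.ndarray, t: np.ndarray, events: pd.DataFrame,
             specs: list[KernelSpec], event_type: str,
             n_shuffles: int = 20, seed: int = 0,
             full_fit: EncodingFit | None = None) -> DeltaR2Result:
    """ΔR² of one event type via the shuffled-event reduced model."""
    if n_shuffles < 1:
        raise ConfigError("n_shuffles must be at least 1")
    t = np.asarray(t, float)
    if full_fit is None:
        full_fit = fit_session(dff, t, events, specs)
    rng = np.random.default_rng(seed)
    span = (float(t[0]), float(t[-1]))
    r2_red = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = shuffle_events(events, event_type, rng, span)
        r2_red[i] = fit_session(dff, t, shuffled, specs).r2
    return DeltaR2Result(event_type, full_fit.r2, r2_red, n_shuffles, seed,
                         kernels_full=full_fit.kernels)
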