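"""ΔF/F computation from two-channel photometry.

The calcium-independent 405 nm reference is linearly fitted to the 475 nm
signal and subtracted; the difference is divided by an exponential
photobleaching curve ``a·exp(−b·t) + c`` fitted to the 475 nm signal and
expressed in percent:

    ΔF/F(t) = 100 · (f475(t) − (m·f405(t) + q)) / (a·e^{−b·t} + c)

The reference subtraction removes motion artifacts shared by the two
excitation wavelengths; the exponential divisor normalizes away slow
photobleaching.  Note one structural property of this estimator: the
divisor is fitted to the *signal* channel, so its constant term absorbs
the session-mean calcium signal, biasing ΔF/F amplitudes multiplicatively
by a factor of order ``1 + mean(ΔF/F)/100``.  For physiological signal
densities this is a ≲0.1% relative effect.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import DegenerateFitError, ValidationError
from .session_io import DFFTrace, RawPhotometry

log = logging.getLogger(__name__)


@dataclass
class ReferenceFit:
    """Audit record of the two fits behind one ΔF/F trace."""

    slope: float
    intercept: float
    a: float
    b: float
    c: float
    linear_rss: float
    exp_rss: float
    degenerate_reference: bool = False


def fit_reference(f405: np.ndarray, f475: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares fit of the 405 nm channel to the 475 nm channel.

    Returns ``(slope, intercept)`` minimizing ``Σ (f475 − slope·f405 − intercept)²``.
    Raises :class:`DegenerateFitError` when f405 is constant; callers that
    want the conventional fallback substitute ``(0, mean(f475))`` themselves.
    """
    f405 = np.asarray(f405, float)
    f475 = np.asarray(f475, float)
    if f405.size < 2:
        raise DegenerateFitError("need at least 2 samples")
    if np.ptp(f405) == 0:
        raise DegenerateFitError("constant 405 nm reference")
    slope, intercept = np.polyfit(f405, f475, 1)
    return float(slope), float(intercept)


def _exp_design(t: np.ndarray, b: float) -> np.ndarray:
    return np.column_stack([np.exp(-b * t), np.ones_like(t)])


def fit_bleach(t: np.ndarray, f475: np.ndarray,
               b_max: float | None = None) -> tuple[float, float, float]:
    """Nonlinear least-squares fit of ``a·exp(−b·t) + c`` with ``b ≥ 0``.

    Solved by variable projection: for each candidate decay rate ``b`` the
    amplitudes ``(a, c)`` have a closed-form linear solution, so only the
    scalar ``b`` is optimized (bounded Brent search on ``[0, b_max]``,
    ``b_max`` defaulting to 100 decay constants per session).  This makes
    the fit deterministic and exactly equivariant under rescaling of the
    fluorescence values.
    """
    t = np.asarray(t, float)
    f475 = np.asarray(f475, float)
    if t.size < 4:
        raise DegenerateFitError("need at least 4 samples for the bleach fit")
    t0 = t - t[0]
    span = t0[-1] if t0[-1] > 0 else 1.0
    if b_max is None:
        b_max = 100.0 / span

    def sse(b: float) -> float:
        X = _exp_design(t0, b)
        coef, *_ = np.linalg.lstsq(X, f475, rcond=None)
        r = f475 - X @ coef
        return float(r @ r)

    try:
        res = optimize.minimize_scalar(
            sse, bounds=(0.0, b_max), method="bounded",
            options={"xatol": 1e-12 * b_max})
        b = float(res.x)
        X = _exp_design(t0, b)
        coef, *_ = np.linalg.lstsq(X, f475, rcond=None)
        a, c = float(coef[0]), float(coef[1])
        if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(c)):
            raise FloatingPointError("non-finite bleach fit")
    except Exception as exc:  # pragma: no cover - defensive fallback
        warnings.warn(f"bleach fit did not converge ({exc}); "
                      "falling back to a constant baseline")
        return 0.0, 0.0, float(np.mean(f475))
    # report in absolute session time: a·e^{−b(t−t0)} = (a·e^{b·t0})·e^{−b·t}
    return a * float(np.exp(b * t[0])), b, c


def eval_bleach(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * np.asarray(t, float)) + c


def compute_dff(raw: RawPhotometry) -> tuple[DFFTrace, ReferenceFit]:
    """Percent ΔF/F and the audit record of the fits it used."""
    degenerate = False
    try:
        slope, intercept = fit_reference(raw.f405, raw.f475)
    except DegenerateFitError:
        slope, intercept = 0.0, float(np.mean(raw.f475))
        degenerate = True
        log.warning("constant 405 nm reference; subtracting mean(f475) instead")
    fitted405 = slope * raw.f405 + intercept
    a, b, c = fit_bleach(raw.t, raw.f475)
    divisor = eval_bleach(raw.t, a, b, c)
    if np.any(divisor <= 0):
        raise ValidationError("fitted bleach curve is not positive")
    dff = 100.0 * (raw.f475 - fitted405) / divisor
    fit = ReferenceFit(
        slope=slope, intercept=intercept, a=a, b=b, c=c,
        linear_rss=float(np.sum((raw.f475 - fitted405) ** 2)),
        exp_rss=float(np.sum((raw.f475 - divisor) ** 2)),
        degenerate_reference=degenerate,
    )
    return DFFTrace(raw.t, dff, raw.rate_hz), fit


def lowpass_resample(dff: DFFTrace, video_t: np.ndarray,
                     half_power_hz: float = 7.0) -> DFFTrace:
    """Zero-phase lowpass then linear interpolation onto the video clock.

    A second-order Butterworth filter with half-power frequency
    ``half_power_hz`` is applied forward-backward (``filtfilt``) so that
    event-locked features are not delayed, then the trace is interpolated
    onto ``video_t`` (nominally 15 Hz).
    """
    video_t = np.asarray(video_t, float)
    if dff.rate_hz < 15.0:
        raise ValidationError("ΔF/F rate must be at least 15 Hz")
    if video_t[0] < dff.t[0] - 1e-9 or video_t[-1] > dff.t[-1] + 1e-9:
        raise ValidationError("video time base extends beyond the ΔF/F trace")
    wn = half_power_hz / (dff.rate_hz / 2.0)
    if wn < 1.0:
        sos = signal.butter(2, wn, output="sos")
        filtered = signal.sosfiltfilt(sos, dff.dff)
    else:  # already at/below the video rate; nothing above the band to remove
        filtered = dff.dff
    out = np.interp(video_t, dff.t, filtered)
    rate = 1.0 / float(np.median(np.diff(video_t))) if video_t.size > 1 else dff.rate_hz
    return DFFTrace(video_t, out, rate)
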