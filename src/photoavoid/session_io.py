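"""Session data model and on-disk formats.

A *session* is one animal's recording: a two-channel photometry trace
(405 nm calcium-independent reference, 475 nm calcium-dependent signal),
a video-rate tracking trace (speed, horizontal position), a typed event
table, a trial table, and the configuration that produced or describes
them.  All times are absolute seconds from session start; positions and
speeds are in cm and cm/s.

On disk a session is a directory of plain-text files:

==================  ============================================
photometry.csv      t, f405, f475
tracking.csv        t, speed, position_x
events.csv          event_type, time, trial_id
trials.csv          per-trial records (optional)
config.json         SessionConfig
ground_truth.json   generator ground truth (optional)
==================  ============================================
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, ValidationError

EVENT_TYPES = (
    "tone_on",
    "tone_off",
    "shock_on",
    "crossing",
    "lick",
    "laser_on",
    "laser_off",
    "first_shock",
)

OUTCOMES = ("avoid", "escape", "fail", "approach", "omission")

EVENT_COLUMNS = ["event_type", "time", "trial_id"]
TRIAL_COLUMNS = [
    "trial_id",
    "tone_on",
    "tone_off",
    "crossing_time",
    "outcome",
    "latency",
    "stim",
    "block_id",
    "special",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class RawPhotometry:
    """Paired 405/475 nm fluorescence traces for one session."""

    t: np.ndarray
    f405: np.ndarray
    f475: np.ndarray
    rate_hz: float

    def __post_init__(self):
        self.t = _as_float_array(self.t, "t")
        self.f405 = _as_float_array(self.f405, "f405")
        self.f475 = _as_float_array(self.f475, "f475")
        self.validate()

    def validate(self):
        n = len(self.t)
        if len(self.f405) != n or len(self.f475) != n:
            raise ValidationError("t, f405, f475 must have equal lengths")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        for name, arr in (("t", self.t), ("f405", self.f405), ("f475", self.f475)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValidationError(
                    f"non-finite samples in {name} at rows {bad[:10].tolist()}"
                )
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("photometry time must be strictly increasing")


@dataclass
class SpeedTrace:
    """Video-rate locomotion trace (nominally 15 frames/s)."""

    t: np.ndarray
    speed: np.ndarray
    position_x: np.ndarray | None = None
    rate_hz: float = 15.0

    def __post_init__(self):
        self.t = _as_float_array(self.t, "t")
        self.speed = _as_float_array(self.speed, "speed")
        if self.position_x is not None:
            self.position_x = _as_float_array(self.position_x, "position_x")
        self.validate()

    def validate(self):
        if len(self.speed) != len(self.t):
            raise ValidationError("t and speed must have equal lengths")
        if self.position_x is not None and len(self.position_x) != len(self.t):
            raise ValidationError("position_x length mismatch")
        if np.any(self.speed < 0):
            raise ValidationError("speed must be non-negative")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("tracking time must be strictly increasing")


@dataclass
class DFFTrace:
    """Percent ΔF/F on a uniform time base."""

    t: np.ndarray
    dff: np.ndarray
    rate_hz: float

    def __post_init__(self):
        self.t = _as_float_array(self.t, "t")
        self.dff = _as_float_array(self.dff, "dff")
        if len(self.dff) != len(self.t):
            raise ValidationError("t and dff must have equal lengths")
        if not np.all(np.isfinite(self.dff)):
            raise ValidationError("ΔF/F contains non-finite values")


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({"event_type": pd.Series(dtype=str),
                         "time": pd.Series(dtype=float),
                         "trial_id": pd.Series(dtype="Int64")})


def make_events(records) -> pd.DataFrame:
    """Build a validated event table from (event_type, time, trial_id) records."""
    df = pd.DataFrame(records, columns=EVENT_COLUMNS)
    df["time"] = df["time"].astype(float)
    df["trial_id"] = df["trial_id"].astype("Int64")
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    validate_events(df)
    return df


def validate_events(events: pd.DataFrame, t_max: float | None = None):
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table missing columns: {missing}")
    unknown = set(events["event_type"]) - set(EVENT_TYPES)
    if unknown:
        raise ValidationError(f"unknown event types: {sorted(unknown)}")
    if len(events) and events["time"].min() < 0:
        raise ValidationError("event times must be non-negative")
    if t_max is not None and len(events) and events["time"].max() > t_max:
        raise ValidationError("event time beyond session end")
    if (events["event_type"] == "first_shock").sum() > 1:
        raise ValidationError("at most one first_shock per session")


def event_times(events: pd.DataFrame, event_type: str) -> np.ndarray:
    return events.loc[events["event_type"] == event_type, "time"].to_numpy(float)


def validate_trials(trials: pd.DataFrame):
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    bad = set(trials["outcome"].dropna()) - set(OUTCOMES)
    if bad:
        raise ValidationError(f"unknown outcomes: {sorted(bad)}")


@dataclass
class DetectorParams:
    """Detector constants with published defaults.

    Pixel-based constants (freezing) depend on camera resolution and are
    therefore overridable per session.
    """

    # open-field movement epochs
    oft_prominence: float = 5.0        # cm/s above local baseline
    # inter-trial-interval movement epochs
    iti_peak_height: float = 10.0      # cm/s absolute
    iti_prominence: float = 3.0        # cm/s above local baseline
    iti_smooth_window: int = 7         # frames, Gaussian-weighted moving average
    iti_exclusion_s: float = 5.0       # discard peaks this close after a kept one
    iti_margin_s: float = 5.0          # ITI window margin after/before tones
    # movement initiation
    initiation_frac: float = 0.1       # fraction of peak speed
    initiation_window_s: float = 2.0   # look-back from the peak
    quiescence_s: float = 1.0          # sub-threshold time required before init
    # freezing detection
    freeze_pixel_thresh: int = 27      # grayscale level; mouse = pixels below it
    freeze_changed_thresh: float = 190.0  # changed mouse pixels
    freeze_band: tuple = (0.01, 0.9)   # fractions of Nyquist
    freeze_highpass: bool = False      # apply the lower band edge as a highpass
    # chamber geometry
    midline_x: float = 0.0             # cm
    midline_hysteresis_cm: float = 1.0


@dataclass
class SessionConfig:
    """Task and acquisition parameters for one session.

    Defaults follow the avoidance paradigm: a tone that the animal must
    answer by crossing the chamber midline within ``response_window_s``;
    otherwise a ``shock_dur_s`` foot shock; inter-trial intervals
    pseudo-randomized around ``iti_mean_s``; optional optogenetic
    stimulation delivered on alternating blocks of ``stim_block_len``
    trials during ``stim_window`` after tone onset.
    """

    task: str = "avoidance"            # avoidance | approach | oft
    n_trials: int = 30
    response_window_s: float = 5.0
    shock_dur_s: float = 2.0
    tone_max_s: float = 7.0
    iti_mean_s: float = 40.0
    special_trial_fraction: float = 0.10   # short/long tone or reward omission
    special_tones: bool = False            # enable 10% short + 10% long tones
    n_pavlovian: int = 0                   # tone-shock pairings before trial 1
    habituation_s: float = 0.0
    stim: bool = False
    stim_block_len: int = 6
    stim_window: tuple = (0.5, 2.5)        # s after tone onset
    photometry_rate_hz: float = 60.0
    video_rate_hz: float = 15.0
    oft_duration_s: float = 600.0
    detectors: DetectorParams = field(default_factory=DetectorParams)

    def __post_init__(self):
        if isinstance(self.detectors, dict):
            self.detectors = DetectorParams(**self.detectors)
        if isinstance(self.stim_window, list):
            self.stim_window = tuple(self.stim_window)
        if isinstance(self.detectors.freeze_band, list):
            self.detectors.freeze_band = tuple(self.detectors.freeze_band)
        self.validate()

    def validate(self):
        if self.task not in ("avoidance", "approach", "oft"):
            raise ConfigError(f"unknown task {self.task!r}")
        for name in ("response_window_s", "shock_dur_s", "tone_max_s",
                     "iti_mean_s", "photometry_rate_hz", "video_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.special_trial_fraction <= 1:
            raise ConfigError("special_trial_fraction must be in [0, 1]")
        if self.task != "oft" and self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        if self.stim_block_len <= 0:
            raise ConfigError("stim_block_len must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SessionConfig":
        return cls(**json.loads(text))


@dataclass
class Session:
    """Everything known about one recording."""

    photometry: RawPhotometry | None
    speed: SpeedTrace | None
    events: pd.DataFrame
    config: SessionConfig
    trials: pd.DataFrame | None = None
    ground_truth: "object | None" = None   # synth.GroundTruth when simulated


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv_checked(path: Path, required: list[str]) -> pd.DataFrame:
    # round_trip parsing + %.17g writing makes read(write(s)) bitwise exact
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} missing columns: {missing}")
    return df


def read_session(directory) -> Session:
    """Read a session directory written by :func:`write_session`."""
    d = Path(directory)
    config = SessionConfig.from_json((d / "config.json").read_text())

    photometry = None
    if (d / "photometry.csv").exists():
        pf = _read_csv_checked(d / "photometry.csv", ["t", "f405", "f475"])
        for col in ("t", "f405", "f475"):
            bad = np.flatnonzero(~np.isfinite(pf[col].to_numpy(float)))
            if bad.size:
                raise ValidationError(
                    f"photometry.csv column {col} has invalid values at rows "
                    f"{bad[:10].tolist()}"
                )
        photometry = RawPhotometry(pf["t"], pf["f405"], pf["f475"],
                                   rate_hz=config.photometry_rate_hz)

    speed = None
    if (d / "tracking.csv").exists():
        tf = _read_csv_checked(d / "tracking.csv", ["t", "speed"])
        pos = tf["position_x"] if "position_x" in tf.columns else None
        speed = SpeedTrace(tf["t"], tf["speed"], pos,
                           rate_hz=config.video_rate_hz)

    events = empty_events()
    if (d / "events.csv").exists():
        events = _read_csv_checked(d / "events.csv", EVENT_COLUMNS)
        events["time"] = events["time"].astype(float)
        events["trial_id"] = events["trial_id"].astype("Int64")
        validate_events(events)

    trials = None
    if (d / "trials.csv").exists():
        trials = _read_csv_checked(d / "trials.csv", TRIAL_COLUMNS)
        validate_trials(trials)

    ground_truth = None
    if (d / "ground_truth.json").exists():
        from .synth import GroundTruth
        ground_truth = GroundTruth.from_json((d / "ground_truth.json").read_text())

    return Session(photometry, speed, events, config, trials, ground_truth)


def write_session(session: Session, directory) -> list[Path]:
    """Write a session as plain-text files; returns the paths written."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []

    (d / "config.json").write_text(session.config.to_json())
    written.append(d / "config.json")

    if session.photometry is not None:
        p = session.photometry
        pd.DataFrame({"t": p.t, "f405": p.f405, "f475": p.f475}).to_csv(
            d / "photometry.csv", index=False, float_format="%.17g")
        written.append(d / "photometry.csv")

    if session.speed is not None:
        s = session.speed
        cols = {"t": s.t, "speed": s.speed}
        if s.position_x is not None:
            cols["position_x"] = s.position_x
        pd.DataFrame(cols).to_csv(d / "tracking.csv", index=False,
                                  float_format="%.17g")
        written.append(d / "tracking.csv")

    # %.17g guarantees exact float64 round-trip through text
    session.events.to_csv(d / "events.csv", index=False, float_format="%.17g")
    written.append(d / "events.csv")

    if session.trials is not None:
        session.trials.to_csv(d / "trials.csv", index=False,
                              float_format="%.17g")
        written.append(d / "trials.csv")

    if session.ground_truth is not None:
        (d / "ground_truth.json").write_text(session.ground_truth.to_json())
        written.append(d / "ground_truth.json")

    return written
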