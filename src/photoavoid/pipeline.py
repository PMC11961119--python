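"""Stage runner chaining simulation, preprocessing, behavior, encoding,
cross-covariance and summary statistics over a session directory."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, encoding, groupstats, preprocess, synth, xcov
from .errors import ConfigError
from .session_io import Session, SessionConfig, read_session, write_session

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "behavior", "encode", "xcov", "groupstats")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def run_pipeline(config: SessionConfig, stages, seed: int, outdir) -> dict:
    """Run the requested stages in canonical order; returns the manifest.

    ``simulate`` writes a session directory under ``outdir``; later stages
    read it back (so they run identically on recorded data dropped into
    the same layout) and write their tables next to it.
    """
    stages = list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(
            f"unknown stage(s) {unknown}; choose from {', '.join(STAGES)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sess_dir = out / "session"
    manifest: dict = {"seed": seed, "stages": {}, "log": []}

    def record(stage, paths):
        manifest["stages"][stage] = {
            str(p.relative_to(out)): _sha256(p) for p in paths}
        manifest["log"].append(f"{stage}: wrote {len(paths)} file(s)")

    session: Session | None = None

    def load() -> Session:
        nonlocal session
        if session is None:
            session = read_session(sess_dir)
        return session

    for stage in [s for s in STAGES if s in stages]:
        if stage == "simulate":
            session = synth.generate_session(config, seed)
            record(stage, write_session(session, sess_dir))
            continue

        s = load()
        if stage == "preprocess":
            dff, fit = preprocess.compute_dff(s.photometry)
            paths = [_write_df(pd.DataFrame({"t": dff.t, "dff": dff.dff}),
                               out / "dff.csv")]
            dff15 = preprocess.lowpass_resample(dff, s.speed.t)
            paths.append(_write_df(
                pd.DataFrame({"t": dff15.t, "dff": dff15.dff}),
                out / "dff15.csv"))
            fit_json = out / "reference_fit.json"
            fit_json.write_text(json.dumps(
                {k: v for k, v in fit.__dict__.items()}, indent=2))
            paths.append(fit_json)
            record(stage, paths)

        elif stage == "behavior":
            trials = behavior.score_trials(s.events, s.speed, s.config)
            windows = behavior.iti_windows(trials)
            moves = behavior.detect_movements_iti(s.speed, windows,
                                                  s.config.detectors)
            paths = [_write_df(trials, out / "trials_scored.csv"),
                     _write_df(pd.DataFrame([m.__dict__ for m in moves]),
                               out / "movements.csv")]
            record(stage, paths)

        elif stage == "encode":
            dff15 = _read_dff15(out, s)
            model_ev = encoding.label_model_events(s.events, _trials(out, s))
            specs = encoding.default_specs(sorted(set(model_ev["event_type"])))
            fit = encoding.fit_session(dff15.dff, dff15.t, model_ev, specs)
            krows = []
            for et in fit.kernels:
                for tau, c in zip(fit.taus[et], fit.kernels[et]):
                    krows.append(dict(event_type=et, tau=tau, coefficient=c))
            paths = [_write_df(pd.DataFrame(krows), out / "kernels.csv")]
            deltas = {}
            for et in ("avoid", "tone_off"):
                if et in fit.kernels:
                    d = encoding.delta_r2(dff15.dff, dff15.t, model_ev, specs,
                                          et, seed=seed, full_fit=fit)
                    deltas[et] = dict(delta_r2=d.delta_r2, r2_full=d.r2_full,
                                      r2_reduced_mean=d.r2_reduced_mean,
                                      n_shuffles=d.n_shuffles)
            fj = out / "fit.json"
            fj.write_text(json.dumps(dict(r2=fit.r2, n_samples=fit.n_samples,
                                          n_params=fit.n_params,
                                          delta_r2=deltas), indent=2))
            paths.append(fj)
            record(stage, paths)

        elif stage == "xcov":
            dff15 = _read_dff15(out, s)
            trials = _trials(out, s)
            fs = None
            if s.ground_truth is not None:
                fs = s.ground_truth.first_shock_time
            evo = xcov.xcov_evolution(dff15, s.speed, trials, fs)
            record(stage, [_write_df(evo, out / "xcov.csv")])

        elif stage == "groupstats":
            dff15 = _read_dff15(out, s)
            trials = _trials(out, s)
            ok = trials[np.isfinite(trials["crossing_time"])]
            mat = groupstats.align_to_event(
                dff15, ok["crossing_time"].to_numpy(float), (-4.0, 4.0))
            contrast = groupstats.pre_peri_contrast(mat)
            hist = groupstats.crossing_probability_hist(trials)
            summary = dict(
                pre_mean=float(contrast["pre"].mean()),
                peri_mean=float(contrast["peri"].mean()),
                n_aligned_trials=int(mat.n_trials),
                crossing_hist_stim=hist["p_stim"].tolist(),
                crossing_hist_no_stim=hist["p_no_stim"].tolist(),
                window_ratio=(None if np.isnan(hist["window_ratio"])
                              else hist["window_ratio"]),
            )
            gj = out / "group_summary.json"
            gj.write_text(json.dumps(summary, indent=2))
            paths = [gj, _write_df(
                pd.DataFrame(mat.data,
                             columns=[f"{x:.4f}" for x in mat.time]),
                out / "peri_event.csv")]
            record(stage, paths)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _read_dff15(out: Path, s: Session):
    from .session_io import DFFTrace
    f = out / "dff15.csv"
    if f.exists():
        df = pd.read_csv(f)
        return DFFTrace(df["t"], df["dff"], 15.0)
    dff, _ = preprocess.compute_dff(s.photometry)
    return preprocess.lowpass_resample(dff, s.speed.t)


def _trials(out: Path, s: Session) -> pd.DataFrame:
    f = out / "trials_scored.csv"
    if f.exists():
        return pd.read_csv(f)
    if s.trials is not None:
        return s.trials
    return behavior.score_trials(s.events, s.speed, s.config)
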