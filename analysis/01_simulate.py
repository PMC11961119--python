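#!/usr/bin/env python
"""Simulate the study's session types and write them to results/sessions/.

Produces a photometry cohort (8 animals, first-day avoidance with
habituation and two tone–shock pairings), an optogenetic cohort (8
opsin + 5 control animals, 72 trials in 12 alternating stimulation
blocks, with the opsin group slowed on stimulation trials), and one
synthetic freezing video, then prints what was generated.
"""
import json
from pathlib import Path

import numpy as np

from photoavoid import benchmarks, synth
from photoavoid.session_io import SessionConfig, write_session

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}

    cfg = benchmarks.firstday_config()
    params = synth.GeneratorParams()
    params.post_shock_gain = 3.0
    cohort = synth.generate_cohort(cfg, 8, SEED, params)
    for i, s in enumerate(cohort):
        write_session(s, OUT / f"photometry_m{i:02d}")
    rates = [float((s.trials["outcome"] == "avoid").mean()) for s in cohort]
    summary["photometry_cohort"] = dict(
        n_mice=len(cohort), n_trials=int(cfg.n_trials),
        avoid_rate_mean=float(np.mean(rates)))
    print(f"photometry cohort: {len(cohort)} mice, "
          f"mean avoidance rate {np.mean(rates):.2f}")

    opto_cfg = SessionConfig(task="avoidance", n_trials=72, stim=True,
                             habituation_s=0.0)
    nphr = synth.GeneratorParams(stim_latency_shift_s=1.0,
                                 stim_speed_factor=0.6)
    for label, params_g, n in (("nphr", nphr, 8),
                               ("eyfp", synth.GeneratorParams(), 5)):
        for i, s in enumerate(synth.generate_cohort(opto_cfg, n, SEED + 7,
                                                    params_g,
                                                    photometry=False)):
            write_session(s, OUT / f"opto_{label}_m{i:02d}")
    summary["opto_cohort"] = dict(n_nphr=8, n_eyfp=5, n_trials=72,
                                  blocks=12)
    print("opto cohort: 8 NpHR + 5 eYFP mice, 72 trials / 12 blocks each")

    bouts = synth.generate_freezing_bouts(120.0, SEED)
    frames = synth.generate_video(bouts, duration_s=120.0, seed=SEED + 1)
    np.save(OUT / "freezing_video.npy", frames)
    (OUT / "freezing_bouts.json").write_text(json.dumps(bouts))
    summary["freezing_video"] = dict(n_frames=int(frames.shape[0]),
                                     n_bouts=len(bouts))
    print(f"freezing video: {frames.shape[0]} frames, {len(bouts)} true bouts")

    (OUT.parent / "simulate_summary.json").write_text(
        json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
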