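#!/usr/bin/env python
"""Group-level statistics: peri-crossing contrast and optogenetic analyses.

Computes the pre/peri ΔF/F contrast around chamber crossings across the
photometry cohort (paired t), then the optogenetic cohort's stimulation-
window speed ANOVA (opsin × stimulation), the crossing-probability
histograms with the stimulation-window ratio, and the block-structure
latency series.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from photoavoid import groupstats
from photoavoid.session_io import DFFTrace, read_session

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    summary = {}

    per_animal = []
    for d in sorted(ROOT.glob("sessions/photometry_m*")):
        s = read_session(d)
        df = pd.read_csv(d / "dff15.csv")
        dff15 = DFFTrace(df["t"], df["dff"], 15.0)
        cross = s.trials.loc[s.trials["outcome"] == "avoid",
                             "crossing_time"].to_numpy(float)
        mat = groupstats.align_to_event(dff15, cross, (-4.0, 4.0))
        per_animal.append(groupstats.pre_peri_contrast(mat))
    contrast = groupstats.paired_contrast_across_animals(per_animal)
    summary["pre_peri"] = dict(
        pre=float(contrast["pre_means"].mean()),
        peri=float(contrast["peri_means"].mean()),
        t=contrast["t"], p=contrast["p"], n=contrast["n_animals"])
    print(f"peri-crossing contrast: pre {summary['pre_peri']['pre']:+.3f} vs "
          f"peri {summary['pre_peri']['peri']:+.3f} %ΔF/F, paired t"
          f"({contrast['n_animals'] - 1}) = {contrast['t']:.2f}, "
          f"p = {contrast['p']:.2e}")

    rows, nphr_trials, series = [], [], []
    for d in sorted(ROOT.glob("sessions/opto_*")):
        s = read_session(d)
        opsin = "NpHR" if "nphr" in d.name else "eYFP"
        per_trial = groupstats.stim_window_speed(s.trials, s.speed)
        for stim, grp in per_trial.groupby("stim"):
            rows.append(dict(animal=d.name, opsin=opsin, stim=stim,
                             mean_speed=grp["mean_speed"].mean()))
        if opsin == "NpHR":
            nphr_trials.append(s.trials)
            series.append(groupstats.block_latency_series(s.trials))
    anova = groupstats.stim_speed_analysis(pd.DataFrame(rows))
    hist = groupstats.crossing_probability_hist(
        pd.concat(nphr_trials, ignore_index=True))
    contrasts = groupstats.block_contrasts(np.vstack(series))
    summary["opto"] = dict(
        interaction_F=anova["F"], interaction_p=anova["p"],
        window_ratio=hist["window_ratio"],
        first_on_vs_pre_p=contrasts["first_on_vs_pre"][1],
        first_on_vs_rest_p=contrasts["first_on_vs_rest"][1])
    print(f"opsin × stimulation interaction: F = {anova['F']:.2f}, "
          f"p = {anova['p']:.2e}")
    print(f"stim-window crossing ratio (illuminated/non-illuminated): "
          f"{hist['window_ratio']:.2f}")
    print(f"block structure: first stimulated trial vs pre-stim latency "
          f"p = {contrasts['first_on_vs_pre'][1]:.4f}; vs later stimulated "
          f"trials p = {contrasts['first_on_vs_rest'][1]:.4f}")

    (ROOT / "group_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
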