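#!/usr/bin/env python
"""Trial-by-trial cross-covariance between ΔF/F and speed.

For each photometry session, computes the per-segment extremal
cross-covariance (±2 s lags) across habituation and inter-trial
segments, annotates the first shock, and summarizes the pre→post step
that marks the emergence of activity–movement coupling.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from photoavoid import xcov
from photoavoid.session_io import DFFTrace, read_session

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    rows = []
    for d in sorted(ROOT.glob("sessions/photometry_m*")):
        s = read_session(d)
        df = pd.read_csv(d / "dff15.csv")
        dff15 = DFFTrace(df["t"], df["dff"], 15.0)
        evo = xcov.xcov_evolution(dff15, s.speed, s.trials,
                                  s.ground_truth.first_shock_time)
        evo["session"] = d.name
        rows.append(evo)
    evo = pd.concat(rows, ignore_index=True)
    evo.to_csv(ROOT / "xcov_evolution.csv", index=False)
    per = evo.groupby(["session", "post_first_shock"])[
        "extremal_value"].mean().unstack()
    step = per[True] - per[False]
    print(per.to_string(float_format=lambda v: f"{v:.3f}"))
    print(f"\npre-shock mean {per[False].mean():.3f}, post-shock mean "
          f"{per[True].mean():.3f}; the coupling step is positive in "
          f"{(step > 0).sum()}/{len(step)} animals "
          f"(cohort mean step {step.mean():.3f}).")


if __name__ == "__main__":
    main()
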