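#!/usr/bin/env python
"""ΔF/F preprocessing of the simulated photometry cohort.

Reads results/sessions/photometry_m*, computes percent ΔF/F (405 nm
reference subtraction, exponential bleach normalization), lowpasses and
resamples it onto the 15 Hz video clock, and reports how well the
estimate tracks the generator's true event signal and how strongly the
shared motion artifact was attenuated.
"""
from pathlib import Path

import pandas as pd
from scipy.stats import pearsonr

from photoavoid import preprocess
from photoavoid.session_io import read_session

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    rows = []
    for d in sorted(ROOT.glob("sessions/photometry_m*")):
        s = read_session(d)
        dff, fit = preprocess.compute_dff(s.photometry)
        dff15 = preprocess.lowpass_resample(dff, s.speed.t)
        pd.DataFrame({"t": dff15.t, "dff": dff15.dff}).to_csv(
            d / "dff15.csv", index=False)
        art = s.ground_truth.artifact_trace
        rows.append(dict(
            session=d.name, slope=fit.slope, bleach_b=fit.b,
            corr_with_true_signal=pearsonr(
                dff.dff, s.ground_truth.event_signal)[0],
            artifact_corr_raw=abs(pearsonr(s.photometry.f475, art)[0]),
            artifact_corr_dff=abs(pearsonr(dff.dff, art)[0])))
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "preprocess_summary.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\nΔF/F tracks the true event signal at r = "
          f"{df.corr_with_true_signal.mean():.3f} (cohort mean); the shared "
          f"artifact correlation drops from "
          f"{df.artifact_corr_raw.mean():.3f} (raw 475) to "
          f"{df.artifact_corr_dff.mean():.3f} (ΔF/F).")


if __name__ == "__main__":
    main()
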