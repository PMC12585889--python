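#!/usr/bin/env python
"""Detect fixations in the simulated gaze traces.

Applies the angular-speed threshold (30 deg/s), the 0.5 deg / 75 ms merge
rule, the 50 ms minimum duration, and the per-participant 3 SD duration
outlier rule, then writes the fixation events as CSV.
"""

import csv
import json
from pathlib import Path

import numpy as np

from retinasample import synth
from retinasample.events import apply_duration_outlier_rule, detect_fixations
from retinasample.geometry import default_geometry

ROOT = Path(__file__).resolve().parent
OUT = ROOT.parent / "results" / "analysis"


def main():
    cohort = json.loads((OUT / "cohort_config.json").read_text())
    geometry = default_geometry(cohort["image_size"])
    traces = synth.read_traces_csv(OUT / "gaze_traces.csv")

    per_trial = {(t.participant_id, t.trial_id): detect_fixations(t, geometry)
                 for t in traces}
    n_before = sum(len(v) for v in per_trial.values())
    cleaned = apply_duration_outlier_rule(per_trial)
    n_after = sum(len(v) for v in cleaned.values())
    pct = {(t.participant_id, t.trial_id): t.spotlight_pct for t in traces}

    with open(OUT / "fixations.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["participant_id", "trial_id", "spotlight_pct", "onset_ms",
                     "offset_ms", "x_px", "y_px", "duration_ms"])
        for (pid, tid), fixes in cleaned.items():
            for f in fixes:
                wr.writerow([pid, tid, pct[(pid, tid)], f"{f.onset:.3f}",
                             f"{f.offset:.3f}", f"{f.x:.3f}", f"{f.y:.3f}",
                             f"{f.duration:.3f}"])

    durs = [f.duration for v in cleaned.values() for f in v]
    counts = [len(v) for v in cleaned.values()]
    print(f"{len(traces)} traces -> {n_before} fixations after merge/min-"
          f"duration, {n_after} after the 3 SD outlier rule")
    print(f"per-trial fixation count: mean {np.mean(counts):.1f} "
          f"(range {min(counts)}-{max(counts)})")
    print(f"fixation duration: mean {np.mean(durs):.0f} ms, "
          f"sd {np.std(durs):.0f} ms")
    print(f"wrote {OUT / 'fixations.csv'}")


if __name__ == "__main__":
    main()
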