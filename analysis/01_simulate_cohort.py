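#!/usr/bin/env python
"""Simulate the synthetic cohort: identities, stimuli and learning-phase gaze.

Writes the raw gaze traces (CSV), identity metadata (JSON), the face-region
mask and per-identity stimuli (PNG) under results/analysis/.
"""

import json
from pathlib import Path

from PIL import Image

from retinasample import synth
from retinasample.pipeline import (RunConfig, generate_cohort_traces,
                                   synthesize_cohort)

ROOT = Path(__file__).resolve().parent
OUT = ROOT.parent / "results" / "analysis"


def main():
    cfg = RunConfig.from_yaml(ROOT / "config.yaml")
    OUT.mkdir(parents=True, exist_ok=True)

    identities, stimuli, mask, geometry, policies = synthesize_cohort(cfg)
    traces = generate_cohort_traces(cfg, identities, stimuli, geometry, policies)

    synth.write_traces_csv(traces, OUT / "gaze_traces.csv")
    synth.write_identity_metadata(identities, OUT / "identities.json")
    Image.fromarray(mask.labels, mode="L").save(OUT / "region_mask.png")
    (OUT / "region_legend.json").write_text(json.dumps(mask.legend))
    for (iid, expr), stim in stimuli.items():
        synth.write_stimulus_png(stim, OUT / f"stim_{iid}_{expr}.png")
    (OUT / "cohort_config.json").write_text(json.dumps({
        "seed": cfg.seed, "n_identities": cfg.n_identities,
        "observers_per_source": cfg.observers_per_source,
        "image_size": cfg.image_size,
        "spotlight_set": list(cfg.spotlight_set)}))

    n_samples = sum(len(t.t_ms) for t in traces)
    print(f"cohort: {cfg.n_identities} identities x 2 expressions, "
          f"{3 * cfg.observers_per_source} observers, "
          f"{len(traces)} learning trials ({n_samples} gaze samples)")
    for name, pol in policies.items():
        print(f"  policy {name:8s} targeting={pol.targeting_weight:.1f} "
              f"spread={pol.spread_sigma:.0f}px")
    print(f"wrote gaze_traces.csv and stimuli to {OUT}")


if __name__ == "__main__":
    main()
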