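#!/usr/bin/env python
"""Plot identity-matching accuracy by spotlight size and sampling source."""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent
OUT = ROOT.parent / "results" / "analysis"

COLORS = {"random": "#999999", "control": "#1f77b4", "super": "#d62728"}


def main():
    auc = pd.read_csv(OUT / "auc_table.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    for src, g in auc.groupby("source_label"):
        m = g.groupby("spotlight_pct")["auc"]
        ax.errorbar(m.mean().index, m.mean(), yerr=m.std(),
                    label=src, color=COLORS.get(src), marker="o", capsize=3)
    ax.set_xlabel("spotlight size (% of face revealed per fixation)")
    ax.set_ylabel("identity matching AUC")
    ax.set_ylim(0.45, 1.0)
    ax.axhline(0.5, color="k", lw=0.5, ls=":")
    ax.legend(title="fixation source", frameon=False)
    fig.tight_layout()
    fig.savefig(OUT / "figure_auc.png", dpi=150)
    print(f"wrote {OUT / 'figure_auc.png'}")


if __name__ == "__main__":
    main()
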