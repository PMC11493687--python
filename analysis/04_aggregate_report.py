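#!/usr/bin/env python
"""Aggregate the study table into figures and a readable summary.

Reads results/table.csv (produced by 03_run_reduced_study.py) and writes
boxplots of sensitivity, precision, localization error and spatial
dispersion per model variant to results/figures/.
"""

from pathlib import Path

import pandas as pd

OUT = Path(__file__).resolve().parent.parent / "results"
FIG = OUT / "figures"

METRICS = [
    ("sensitivity", "Sensitivity"),
    ("precision", "Precision"),
    ("locerr_mm", "Localization error (mm)"),
    ("dispersion", "Spatial dispersion"),
]


def main() -> None:
    table_path = OUT / "table.csv"
    if not table_path.exists():
        raise SystemExit("run analysis/03_run_reduced_study.py first")
    table = pd.read_csv(table_path)
    at30 = table[table["max_dist_mm"] == 30.0]

    print("cohort medians at the 3 cm classification radius:")
    med = at30.groupby(["network", "model_variant"])[
        ["sensitivity", "precision", "locerr_mm", "dispersion"]
    ].median(numeric_only=True)
    print(med.round(3).to_string())

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib not available; skipping figures")
        return

    FIG.mkdir(exist_ok=True, parents=True)
    for col, label in METRICS:
        fig, axes = plt.subplots(
            1, at30["network"].nunique(), figsize=(9, 3.2), sharey=True
        )
        for ax, (network, g) in zip(
            axes if hasattr(axes, "__len__") else [axes], at30.groupby("network")
        ):
            groups = [
                sub[col].dropna() for _, sub in g.groupby("model_variant")
            ]
            names = [name for name, _ in g.groupby("model_variant")]
            ax.boxplot(groups, tick_labels=[n.replace("_", "\n") for n in names])
            ax.set_title(network)
            ax.set_ylabel(label)
        fig.tight_layout()
        fig.savefig(FIG / f"{col}_by_variant.png", dpi=120)
        plt.close(fig)
    print(f"wrote figures to {FIG}/")


if __name__ == "__main__":
    main()
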