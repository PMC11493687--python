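#!/usr/bin/env python
"""Build the synthetic head-model cohort and characterize its forward physics.

Writes results/forward_summary.csv with, per conductivity preset:
the Legendre mode-factor decay, leadfield column-norm statistics, and the
depth dependence of sensor gain — the quantities that determine how well
each model variant can see the simulated sources.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import erplocsim as els
from erplocsim.forward import shell_mode_factors

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    montage = els.make_montage(64, 0.100, seed=1)
    rows = []
    for preset, radii in [
        ("fem_meta", els.DEFAULT_RADII_4),
        ("fem_default", els.DEFAULT_RADII_4),
        ("bem_default", els.DEFAULT_RADII_3),
    ]:
        model = els.make_shell_model(preset, radii)
        sources = els.make_source_space(model, spacing_mm=8.0)
        lf = els.compute_leadfield(model, montage.projected_to(model.r_outer), sources)
        f = shell_mode_factors(model, 60)
        norms = np.linalg.norm(lf.gain, axis=0)
        rows.append(
            {
                "preset": preset,
                "n_shells": model.n_shells,
                "n_dipoles": sources.n_dipoles,
                "mode_factor_n1": f[0],
                "mode_factor_n10": f[9],
                "mode_factor_n40": f[39],
                "col_norm_median": np.median(norms),
                "col_norm_iqr": np.subtract(*np.percentile(norms, [75, 25])),
                "avg_ref_residual": float(np.abs(lf.gain.sum(0)).max() / norms.min()),
            }
        )
        print(
            f"{preset:12s} shells={model.n_shells} f1={f[0]:.3f} f10={f[9]:.3f} "
            f"median|col|={np.median(norms):.3e}"
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "forward_summary.csv", index=False)
    print(f"\nThe skull attenuates high spatial frequencies: the mode factor "
          f"falls from {df.mode_factor_n1.iloc[0]:.3f} (n=1) to "
          f"{df.mode_factor_n40.iloc[0]:.4f} (n=40) for the detailed model.")
    print(f"wrote {OUT / 'forward_summary.csv'}")


if __name__ == "__main__":
    main()
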