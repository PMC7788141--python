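#!/usr/bin/env python
"""TOF-kernel mismatch demonstration with the toy 2-D TOF-OSEM.

Two experiments on the 2-D IEC-like phantom:

1. Kernel mismatch: sinograms generated with true timing FWHM 300-900 ps are
   reconstructed with (a) a kernel matching the true FWHM and (b) a kernel
   stuck at 300 ps.  The misfit arm loses contrast and SNR monotonically as
   the data's timing spread grows — the mechanism suspected behind the
   paradoxical TOF-image degradation of the analog camera at high rates.
2. TOF-vs-noTOF gain near convergence (12 iterations): matched-kernel TOF
   reconstruction beats noTOF of the same data.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from petqc.tofrecon import (ReconConfig, kernel_mismatch_experiment,
                            tof_vs_notof_experiment)

OUT = Path("results/analysis")
SEEDS = (1, 2, 3)
TRUE_FWHMS = (300.0, 500.0, 700.0, 900.0)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ReconConfig(n_iterations=2)
    tables = [kernel_mismatch_experiment(TRUE_FWHMS, 300.0, cfg, seed=s,
                                         total_counts=3e6)
              for s in SEEDS]
    tab = pd.concat(tables, ignore_index=True)
    tab.to_csv(OUT / "07_kernel_mismatch.csv", index=False)
    agg = tab.groupby(["true_fwhm_ps", "arm"])[["snr", "crc_pct"]].mean()
    print("kernel mismatch (mean over spheres and seeds):")
    print(agg.round(2).to_string())

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for arm, style in (("matched", "o-"), ("misfit", "s--")):
        g = agg.xs(arm, level="arm")
        axes[0].plot(g.index, g["snr"], style, label=arm)
        axes[1].plot(g.index, g["crc_pct"], style, label=arm)
    axes[0].set_xlabel("true timing FWHM (ps)")
    axes[0].set_ylabel("mean sphere SNR")
    axes[1].set_xlabel("true timing FWHM (ps)")
    axes[1].set_ylabel("mean CRC (%)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(OUT / "07_kernel_mismatch.png", dpi=120)

    gains = tof_vs_notof_experiment(ReconConfig(n_iterations=12), 400.0,
                                    SEEDS, total_counts=3e5)
    gains.to_csv(OUT / "07_tof_vs_notof.csv", index=False)
    mean_gain = float(np.mean(gains["snr_tof"] / gains["snr_notof"]))
    print(f"\nmean TOF/noTOF SNR gain at 12 iterations: {mean_gain:.2f}")


if __name__ == "__main__":
    main()
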