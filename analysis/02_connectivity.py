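"""Surrogate-corrected interrelation matrices for every cohort epoch.

For each epoch written by 01_simulate_cohort.py: slide 4 s windows, build
the three surrogate null families, correct the Pearson and mutual-
information matrices, and store the window matrices plus epoch averages
under results/connectivity/.  Run 01 first.
"""

from pathlib import Path

import pandas as pd

from preictalnet.interrelation import (
    CorrectionConfig,
    WindowingConfig,
    epoch_average,
    epoch_matrices,
)
from preictalnet.io import read_epoch_hdf5
from preictalnet.pipeline import write_matrices_hdf5

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2027


def main():
    out = ROOT / "connectivity"
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted((ROOT / "cohort").glob("*.h5"))
    if not paths:
        raise SystemExit("run 01_simulate_cohort.py first")
    wcfg = WindowingConfig(window_length=4.0, step=4.0, epoch_length=40.0)
    ccfg = CorrectionConfig(
        families=("linear", "nonlinear_excess", "mi_shift"), max_iter=20
    )
    for k, p in enumerate(paths):
        ep = read_epoch_hdf5(p)
        mats = epoch_matrices(ep, wcfg, ccfg, seed=SEED + k)
        for fam, ms in mats.items():
            write_matrices_hdf5(ms, out / f"{p.stem}_{fam}.h5")
            avg = epoch_average(ms)
            pd.DataFrame(avg.values, index=ep.labels, columns=ep.labels).to_csv(
                out / f"{p.stem}_{fam}_average.csv"
            )
        nz = {fam: float((epoch_average(ms).values > 0).mean())
              for fam, ms in mats.items() if fam != "linear"}
        print(f"{p.stem}: {len(mats['linear'])} windows; "
              f"nonzero fractions {nz}")
    print(f"matrices written to {out}")


if __name__ == "__main__":
    main()
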