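"""Receptive-field characterization of the learned dictionaries.

For every dictionary written by step 02: probe each unit with the grating
bank, compute circular variance and preferred orientation, fit Gabors, and
emit the population tables (circular-variance histogram, preferred-
orientation proportions, envelope-shape scatter with the r^2 >= 0.6 filter).
Also renders a small receptive-field mosaic per method.

Writes results/05_units_<method>.csv, results/05_cv_hist_<method>.csv,
results/05_orientation_<method>.csv, results/05_shapes_<method>.csv and
results/05_mosaic_<method>.png.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from v1sparse import io
from v1sparse.rf import (
    circular_variance,
    fit_gabor,
    make_grating_bank,
    orientation_histograms,
    shape_table,
    tuning_curve,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--max-units", type=int, default=64, help="cap per-method unit count")
args = parser.parse_args()

OUT = Path("results")
OUT.mkdir(exist_ok=True)

dict_paths = sorted(OUT.glob("02_dict_*.h5"))
if not dict_paths:
    raise SystemExit("no dictionaries found under results/; run analysis/02_train_dictionaries.py first")

bank = None
for path in dict_paths:
    method = path.stem.replace("02_dict_", "")
    dictionary = io.load_dictionary(path)
    patch = int(np.sqrt(dictionary.m))
    if bank is None or bank.patch_size != patch:
        bank = make_grating_bank(patch)
    n = min(dictionary.n, args.max_units)

    rows, stats, fits = [], [], []
    for i in range(n):
        unit = dictionary.phi[:, i]
        tc = tuning_curve(unit, bank)
        st = circular_variance(tc)
        fit = fit_gabor(unit, restarts=6, seed=args.seed + i, max_nfev=800)
        stats.append(st)
        fits.append(fit)
        rows.append(
            {
                "unit": i,
                "optimal_sf": tc.optimal_sf,
                "circular_variance": st.circular_variance,
                "preferred_orientation": st.preferred_orientation,
                "gabor_r2": fit.r2,
                "sigma_parallel": fit.sigma_parallel,
                "sigma_orthogonal": fit.sigma_orthogonal,
                "period": fit.period,
            }
        )
    units = pd.DataFrame(rows)
    units.to_csv(OUT / f"05_units_{method}.csv", index=False)
    hists = orientation_histograms(stats, bins=18)
    hists["circular_variance"].to_csv(OUT / f"05_cv_hist_{method}.csv", index=False)
    hists["preferred_orientation"].to_csv(OUT / f"05_orientation_{method}.csv", index=False)
    shapes = shape_table(fits, r2_min=0.6)
    shapes.to_csv(OUT / f"05_shapes_{method}.csv", index=False)

    po = hists["preferred_orientation"]
    peak_bin = po.loc[po.proportion.idxmax()]
    print(f"{method:9s} median CV {units.circular_variance.median():.3f}  "
          f"{len(shapes)}/{n} units pass the r^2>=0.6 Gabor filter  "
          f"orientation peak at [{peak_bin.bin_left:.2f}, {peak_bin.bin_right:.2f}) rad")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        side = int(np.ceil(np.sqrt(min(n, 64))))
        fig, axes = plt.subplots(side, side, figsize=(side, side))
        for ax in np.ravel(axes):
            ax.axis("off")
        for i, ax in enumerate(np.ravel(axes)[: min(n, 64)]):
            rf = dictionary.phi[:, i].reshape(patch, patch)
            ax.imshow(rf, cmap="gray")
        fig.suptitle(f"{method} receptive fields")
        fig.savefig(OUT / f"05_mosaic_{method}.png", dpi=80)
        plt.close(fig)
    except ImportError:
        print("  (matplotlib unavailable; skipping mosaic)")
print("wrote per-method unit tables, histograms, shapes and mosaics under results/")
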