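"""Train one dictionary per thresholding method on pink-noise patches.

Desk-scale version of the training regime the regularizers are compared
under: 8x8 patches, 128 units (2x overcomplete), 250-patch batches.  Pass
``--full`` for the full-scale setting (16x16 patches, 500 units, 4000
batches) — expect hours rather than minutes.

Writes per-method training traces (results/02_trace_<method>.csv), the
learned dictionaries (results/02_dict_<method>.h5) and a summary table
(results/02_training_summary.csv).
"""

import argparse
from pathlib import Path

import pandas as pd

import v1sparse as v
from v1sparse import io
from v1sparse.coding import CodingConfig
from v1sparse.learning import TrainConfig, train
from v1sparse.operators import PenaltySpec

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--full", action="store_true", help="full-scale training run")
args = parser.parse_args()

OUT = Path("results")
OUT.mkdir(exist_ok=True)

if args.full:
    patch, units, batches, size, n_img = 16, 500, 4000, 512, 12
    lambdas = {"soft_l1": 0.12, "half_l12": 0.10, "hard_l0": 0.30, "cel0": 0.06}
else:
    patch, units, batches, size, n_img = 8, 128, 300, 256, 8
    lambdas = {"soft_l1": 0.10, "half_l12": 0.08, "hard_l0": 0.25, "cel0": 0.05}

raw = v.generate_pink_noise_images(v.PinkNoiseSpec(size, size, 1.0, seed=args.seed), n_img)
images = [v.preprocess_image(im) for im in raw]
print(f"training on {n_img} preprocessed pink-noise images "
      f"({patch}x{patch} patches, N={units}, {batches} batches)")

rows = []
for method, lam in lambdas.items():
    mu = 0.05 if method == "cel0" else None
    cfg = TrainConfig(
        penalty=PenaltySpec(method, lam, mu if mu else 1.0),
        eta=5e-3 if method == "cel0" else 1e-2,
        lr_schedule="time_decay" if method == "cel0" else "constant",
        batch_size=250,
        n_batches=batches,
        patch_size=patch,
        n_units=units,
        seed=args.seed,
        coding=CodingConfig(mu=mu, max_iters=150, record_energy=False),
    )
    dictionary, trace = train(images, cfg)
    trace.to_csv(OUT / f"02_trace_{method}.csv", index=False)
    io.save_dictionary(OUT / f"02_dict_{method}.h5", dictionary)
    tail = trace.tail(max(1, len(trace) // 4))
    rows.append(
        {
            "method": method,
            "lambda": lam,
            "mse_tail": tail.mse.mean(),
            "active_tail": tail.mean_active.mean(),
            "n_units": units,
        }
    )
    print(f"  {method:9s} lambda={lam:<5} tail MSE {tail.mse.mean():.4f}  "
          f"mean active {tail.mean_active.mean():6.1f} / {units}")

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "02_training_summary.csv", index=False)
print("wrote results/02_training_summary.csv (baseline zero-code MSE is 0.1)")
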