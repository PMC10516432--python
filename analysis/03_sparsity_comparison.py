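"""Sparsity frontier: active units needed by each method at matched MSE.

Codes a held-out pink-noise patch set against the soft-trained dictionary
from step 02 (training it here if absent), sweeping lambda per method, and
then calibrates each method to a common reconstruction error to compare the
number of active units — the frontier behind the headline claim that
non-convex thresholding codes are sparser at equal reconstruction quality.

Writes results/03_frontier.csv and results/03_matched_mse.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import v1sparse as v
from v1sparse import io
from v1sparse.coding import CodingConfig, sparse_code_batch
from v1sparse.operators import PenaltySpec

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--target-mse", type=float, default=0.02)
args = parser.parse_args()

OUT = Path("results")
OUT.mkdir(exist_ok=True)

dict_path = OUT / "02_dict_soft_l1.h5"
raw = v.generate_pink_noise_images(v.PinkNoiseSpec(256, 256, 1.0, seed=args.seed), 8)
images = [v.preprocess_image(im) for im in raw]
if dict_path.exists():
    dictionary = io.load_dictionary(dict_path)
    print(f"loaded dictionary from {dict_path} ({dictionary.m}x{dictionary.n})")
else:
    from v1sparse.learning import TrainConfig, train

    cfg = TrainConfig(
        penalty=PenaltySpec("soft_l1", 0.05, 1.0),
        eta=1e-2,
        batch_size=250,
        n_batches=250,
        patch_size=8,
        n_units=128,
        seed=args.seed,
        coding=CodingConfig(max_iters=150, record_energy=False),
    )
    dictionary, _ = train(images, cfg)
    print("trained a fresh soft-threshold dictionary (8x8 patches, N=128)")

patch = int(np.sqrt(dictionary.m))
patches = v.extract_patches(images, patch, 500, seed=args.seed + 735).patches

# frontier: MSE as a function of active units while lambda sweeps
rows = []
grids = {
    "soft_l1": (0.02, 0.05, 0.1, 0.2, 0.4),
    "half_l12": (0.01, 0.03, 0.08, 0.15, 0.3),
    "hard_l0": (0.05, 0.12, 0.25, 0.5, 1.0),
    "cel0": (0.005, 0.015, 0.04, 0.08, 0.15),
}
for method, lams in grids.items():
    mu = 0.05 if method == "cel0" else None
    cfg = CodingConfig(mu=mu, max_iters=200, record_energy=False)
    for lam in lams:
        pen = PenaltySpec(method, lam, mu if mu else 1.0)
        _, mse, active = sparse_code_batch(patches, dictionary.phi, pen, cfg)
        rows.append(
            {
                "method": method,
                "lambda": lam,
                "mse_mean": mse.mean(),
                "mse_sd": mse.std(),
                "active_mean": active.mean(),
                "active_sd": active.std(),
            }
        )
frontier = pd.DataFrame(rows)
frontier.to_csv(OUT / "03_frontier.csv", index=False)
print(f"swept {sum(len(g) for g in grids.values())} (method, lambda) cells "
      "-> results/03_frontier.csv")

matched = v.sparsity_at_matched_mse(
    dictionary, patches, target_mse=args.target_mse, coding_iters=200
)
matched.to_csv(OUT / "03_matched_mse.csv", index=False)
print(f"\nactive units at matched MSE = {args.target_mse}:")
for _, r in matched.sort_values("active_mean").iterrows():
    print(f"  {r.method:9s} lambda={r['lambda']:.4f}  mse={r.mse_mean:.4f}  "
          f"active={r.active_mean:6.2f} +- {r.active_sd:.2f}")
order = matched.set_index("method").active_mean
ok = order["cel0"] < min(order["half_l12"], order["hard_l0"]) and max(
    order["half_l12"], order["hard_l0"]
) < order["soft_l1"]
print(f"\nordering CEL0 < (half, hard) < soft at matched MSE: {ok}")
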