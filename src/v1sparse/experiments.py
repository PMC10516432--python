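"""Comparative experiments: sparsity vs reconstruction across regularizers.

Three experiment families, each returning a tidy table stamped with its
configuration so any row can be replayed:

* sparsity comparison — per (method, lambda): train (or code against a fixed
  dictionary) and report the reconstruction MSE and active-unit statistics
  of the final batches, the data behind the MSE-vs-active-units frontier;
* overcompleteness sweep — per (method, N): bisect lambda until the
  normalized proportion of active units (mean actives / N) lands in a
  configured window (default [0.0105, 0.0132]), then report MSE;
* matched instances — calibrate one method's lambda so its mean active count
  matches another's ("sparse" soft / "dense" CEL0 controls), then compare
  MSEs and RF shape tables.

Lambda calibration exploits that the mean active count is monotonically
decreasing (and MSE increasing) in lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CodingConfig, sparse_code_batch
from .learning import Dictionary, TrainConfig, train
from .operators import PenaltySpec
from .preprocess import PreprocessedImage
from .rf import fit_gabor, shape_table

__all__ = [
    "ExperimentSpec",
    "run_sparsity_comparison",
    "run_overcompleteness_sweep",
    "run_matched_instances",
    "code_statistics",
    "calibrate_lambda",
    "sparsity_at_matched_mse",
]

DEFAULT_SPARSITY_WINDOW = (0.0105, 0.0132)


@dataclass
class ExperimentSpec:
    """Methods, sizes and lambda grids of one comparative experiment.

    ``fixed_dictionary`` switches every method to coding against the given
    dictionary instead of training its own (the dictionary-invariance
    setting); ``tail_fraction`` controls which final fraction of the trace
    the summary statistics average over.
    """

    methods: tuple[str, ...] = ("soft_l1", "half_l12", "hard_l0", "cel0")
    dictionary_sizes: tuple[int, ...] = (100,)
    lambda_grid: dict[str, tuple[float, ...]] = field(default_factory=dict)
    mu: dict[str, float] | None = None
    patch_size: int = 16
    batch_size: int = 250
    n_batches: int = 400
    seed: int = 0
    sparsity_window: tuple[float, float] = DEFAULT_SPARSITY_WINDOW
    fixed_dictionary: Dictionary | None = None
    tail_fraction: float = 0.25
    coding_iters: int = 200

    def __post_init__(self) -> None:
        if len(self.methods) == 0 or len(self.dictionary_sizes) == 0:
            raise ValueError("methods and dictionary_sizes must be non-empty")
        for m in self.methods:
            if m not in ("soft_l1", "half_l12", "hard_l0", "cel0"):
                raise ValueError(f"unknown method {m!r}")

    def penalty(self, method: str, lam: float) -> PenaltySpec:
        mu = (self.mu or {}).get(method, 0.05 if method == "cel0" else None)
        # mu=None lets the coding step use 1/L; PenaltySpec requires a value,
        # so carry a placeholder replaced inside the coding loop.
        return PenaltySpec(method, lam, mu if mu is not None else 1.0)

    def coding_config(self, method: str) -> CodingConfig:
        mu = (self.mu or {}).get(method, 0.05 if method == "cel0" else None)
        return CodingConfig(mu=mu, max_iters=self.coding_iters, record_energy=False)

    def train_config(self, method: str, lam: float, n_units: int) -> TrainConfig:
        if method == "cel0":
            return TrainConfig(
                penalty=self.penalty(method, lam),
                eta=5e-3,
                lr_schedule="time_decay",
                decay_divisor=50.0,
                batch_size=self.batch_size,
                n_batches=self.n_batches,
                patch_size=self.patch_size,
                n_units=n_units,
                seed=self.seed,
                coding=self.coding_config(method),
            )
        return TrainConfig(
            penalty=self.penalty(method, lam),
            eta=1e-2,
            batch_size=self.batch_size,
            n_batches=self.n_batches,
            patch_size=self.patch_size,
            n_units=n_units,
            seed=self.seed,
            coding=self.coding_config(method),
        )


def code_statistics(
    patches: np.ndarray,
    dictionary: Dictionary,
    penalty: PenaltySpec,
    cfg: CodingConfig,
) -> dict[str, float]:
    """Mean/sd of MSE and active counts for one batch coded against a fixed dictionary."""
    _, mse, active = sparse_code_batch(patches, dictionary.phi, penalty, cfg)
    return {
        "mse_mean": float(mse.mean()),
        "mse_sd": float(mse.std()),
        "active_mean": float(active.mean()),
        "active_sd": float(active.std()),
    }


def calibrate_lambda(
    evaluate,
    target: float,
    bracket: tuple[float, float] = (1e-4, 10.0),
    tol: float = 0.02,
    max_iters: int = 40,
    increasing: bool = False,
) -> tuple[float, float]:
    """Bisection on lambda for a monotone response ``evaluate(lam)``.

    The response is decreasing in lambda by default (mean active count);
    pass ``increasing=True`` for responses such as the reconstruction MSE.
    Returns (lambda, achieved value) once the response is within ``tol``
    (relative) of ``target``.  Raises if the bracket does not straddle the
    target.
    """
    lo, hi = bracket
    v_lo, v_hi = evaluate(lo), evaluate(hi)
    straddles = (v_lo <= target <= v_hi) if increasing else (v_lo >= target >= v_hi)
    if not straddles:
        raise ValueError(
            f"bisection bracket does not straddle target {target}: "
            f"response({lo})={v_lo}, response({hi})={v_hi}"
        )
    lam, val = lo, v_lo
    for _ in range(max_iters):
        lam = np.sqrt(lo * hi)  # geometric midpoint: lambda spans decades
        val = evaluate(lam)
        if target > 0 and abs(val - target) / target <= tol:
            return lam, val
        if (val > target) != increasing:
            lo = lam
        else:
            hi = lam
    return lam, val


def sparsity_at_matched_mse(
    dictionary: Dictionary,
    patches: np.ndarray,
    target_mse: float,
    methods: tuple[str, ...] = ("soft_l1", "half_l12", "hard_l0", "cel0"),
    mu: dict[str, float] | None = None,
    bracket: tuple[float, float] = (1e-5, 50.0),
    tol: float = 0.02,
    coding_iters: int = 200,
) -> pd.DataFrame:
    """Mean active counts of each method once lambda is tuned to a common MSE.

    For each method, lambda is bisected so that coding ``patches`` against
    the (fixed) ``dictionary`` reaches ``target_mse`` within ``tol``; the
    returned table carries the calibrated lambda, the achieved MSE and the
    active-count statistics — the matched-reconstruction comparison behind
    the sparsity frontier.
    """
    mu = mu or {"cel0": 0.05}
    rows = []
    for method in methods:
        method_mu = mu.get(method)
        cfg = CodingConfig(mu=method_mu, max_iters=coding_iters, record_energy=False)

        def mse_of(lam: float) -> float:
            pen = PenaltySpec(method, lam, method_mu if method_mu is not None else 1.0)
            _, mse, _ = sparse_code_batch(patches, dictionary.phi, pen, cfg)
            return float(mse.mean())

        lam, _ = calibrate_lambda(mse_of, target_mse, bracket, tol=tol, increasing=True)
        pen = PenaltySpec(method, lam, method_mu if method_mu is not None else 1.0)
        _, mse, active = sparse_code_batch(patches, dictionary.phi, pen, cfg)
        rows.append(
            {
                "method": method,
                "lambda": lam,
                "mse_mean": float(mse.mean()),
                "active_mean": float(active.mean()),
                "active_sd": float(active.std()),
            }
        )
    return pd.DataFrame(rows)


def _method_stats(
    spec: ExperimentSpec,
    method: str,
    lam: float,
    n_units: int,
    images: list[PreprocessedImage] | None,
    eval_patches: np.ndarray | None,
) -> dict[str, float]:
    """Train-or-code statistics for one (method, lambda, N) cell."""
    if spec.fixed_dictionary is not None:
        stats = code_statistics(
            eval_patches,
            spec.fixed_dictionary,
            spec.penalty(method, lam),
            spec.coding_config(method),
        )
        stats["n_units"] = spec.fixed_dictionary.n
        return stats
    cfg = spec.train_config(method, lam, n_units)
    _, trace = train(images, cfg)
    tail = trace.iloc[-max(1, int(len(trace) * spec.tail_fraction)) :]
    return {
        "mse_mean": float(tail["mse"].mean()),
        "mse_sd": float(tail["mse"].std(ddof=0)),
        "active_mean": float(tail["mean_active"].mean()),
        "active_sd": float(tail["mean_active"].std(ddof=0)),
        "n_units": n_units,
    }


def run_sparsity_comparison(
    spec: ExperimentSpec,
    images: list[PreprocessedImage] | None = None,
    eval_patches: np.ndarray | None = None,
) -> pd.DataFrame:
    """MSE and active-count statistics per (method, lambda): the sparsity frontier."""
    n_units = spec.dictionary_sizes[0]
    rows = []
    for method in spec.methods:
        lams = spec.lambda_grid.get(method, (0.1,))
        for lam in lams:
            stats = _method_stats(spec, method, lam, n_units, images, eval_patches)
            rows.append({"method": method, "lambda": lam, "seed": spec.seed, **stats})
    return pd.DataFrame(rows)


def run_overcompleteness_sweep(
    spec: ExperimentSpec,
    images: list[PreprocessedImage],
    bracket: tuple[float, float] = (1e-3, 5.0),
) -> pd.DataFrame:
    """Per (method, N): calibrate lambda into the sparsity window, then report MSE."""
    if len(spec.dictionary_sizes) < 2:
        raise ValueError("overcompleteness sweep needs at least two dictionary sizes")
    lo_w, hi_w = spec.sparsity_window
    target = 0.5 * (lo_w + hi_w)
    rows = []
    for method in spec.methods:
        for n_units in spec.dictionary_sizes:

            def proportion(lam: float) -> float:
                stats = _method_stats(spec, method, lam, n_units, images, None)
                return stats["active_mean"] / n_units

            lam, prop = calibrate_lambda(
                proportion, target, bracket, tol=(hi_w - lo_w) / (lo_w + hi_w)
            )
            if not (lo_w <= prop <= hi_w):
                raise RuntimeError(
                    f"{method}, N={n_units}: calibrated proportion {prop:.4f} "
                    f"outside window [{lo_w}, {hi_w}]"
                )
            stats = _method_stats(spec, method, lam, n_units, images, None)
            rows.append(
                {
                    "method": method,
                    "n_units": n_units,
                    "lambda": lam,
                    "active_proportion": prop,
                    "seed": spec.seed,
                    **stats,
                }
            )
    return pd.DataFrame(rows)


def run_matched_instances(
    spec: ExperimentSpec,
    images: list[PreprocessedImage],
    reference: str = "cel0",
    adjusted: str = "soft_l1",
    reference_lambda: float = 0.1,
    bracket: tuple[float, float] = (1e-4, 10.0),
    fit_restarts: int = 6,
    fit_max_nfev: int = 800,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Calibrate ``adjusted``'s lambda to match ``reference``'s mean active count.

    Trains both methods, compares MSEs at matched sparsity, and runs the
    Gabor shape analysis on both dictionaries.  Returns (summary table,
    {method: shape table}).
    """
    n_units = spec.dictionary_sizes[0]
    ref_cfg = spec.train_config(reference, reference_lambda, n_units)
    ref_dict, ref_trace = train(images, ref_cfg)
    tail = ref_trace.iloc[-max(1, int(len(ref_trace) * spec.tail_fraction)) :]
    target_active = float(tail["mean_active"].mean())

    trained: dict[str, tuple[Dictionary, float, float, float]] = {
        reference: (
            ref_dict,
            reference_lambda,
            float(tail["mse"].mean()),
            target_active,
        )
    }

    def active_of(lam: float) -> float:
        cfg = spec.train_config(adjusted, lam, n_units)
        _, tr = train(images, cfg)
        tl = tr.iloc[-max(1, int(len(tr) * spec.tail_fraction)) :]
        return float(tl["mean_active"].mean())

    lam_adj, achieved = calibrate_lambda(active_of, target_active, bracket, tol=0.05)
    adj_cfg = spec.train_config(adjusted, lam_adj, n_units)
    adj_dict, adj_trace = train(images, adj_cfg)
    tl = adj_trace.iloc[-max(1, int(len(adj_trace) * spec.tail_fraction)) :]
    trained[adjusted] = (adj_dict, lam_adj, float(tl["mse"].mean()), float(tl["mean_active"].mean()))

    rows, shapes = [], {}
    for method, (dct, lam, mse, active) in trained.items():
        fits = [
            fit_gabor(dct.phi[:, i], restarts=fit_restarts, seed=spec.seed, max_nfev=fit_max_nfev)
            for i in range(dct.n)
        ]
        shapes[method] = shape_table(fits)
        rows.append(
            {
                "method": method,
                "lambda": lam,
                "mse_mean": mse,
                "active_mean": active,
                "n_fits_kept": len(shapes[method]),
                "n_units": n_units,
                "seed": spec.seed,
            }
        )
    summary = pd.DataFrame(rows)
    summary["matched_within"] = abs(achieved - target_active) / target_active
    return summary, shapes
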