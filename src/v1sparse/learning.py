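"""The learning step: gradient dictionary updates with unit-norm columns.

Training alternates the coding step (fixed Phi, see :mod:`v1sparse.coding`)
with a gradient step on the dictionary,

    Phi <- Phi + eta * mean_batch[ (I - Phi r) r^T ],

followed by rescaling every column to unit norm.  Columns that never
activate and collapse to zero are re-randomized (and logged) so the unit
count N stays meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coding import CodingConfig, sparse_code_batch
from .operators import PenaltySpec
from .preprocess import PreprocessedImage, extract_patches
from .synthetic import PlantedModel, random_unit_dictionary, sample_planted_patches

__all__ = [
    "Dictionary",
    "TrainConfig",
    "dictionary_update",
    "train",
    "train_on_planted",
    "time_decay_rate",
    "best_match_correlations",
]

logger = logging.getLogger(__name__)


@dataclass
class Dictionary:
    """M x N matrix of unit-norm feature columns (the model receptive fields)."""

    phi: np.ndarray
    created_by: str = ""

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValueError("phi must be an M x N matrix")

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def n(self) -> int:
        return self.phi.shape[1]

    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.phi, axis=0)


@dataclass
class TrainConfig:
    """Hyperparameters of the alternating training loop.

    ``lr_schedule`` is either "constant" or "time_decay"; with time decay
    the learning rates eta and mu shrink as lr0 / (1 + (lr0/decay_divisor) * t)
    (divisor 50), the schedule used for CEL0; lambda stays fixed.  Defaults
    for batch size (250) follow the training regime the models were compared
    under; ``n_batches`` defaults to a desk-scale 400 (full scale: 4000).

    Columns that stay inactive for ``dead_patience`` consecutive batches, or
    that duplicate a more-used column beyond ``max_coherence``, are replaced
    by the batch's worst-reconstructed patch (normalized) during the first
    ``replace_frac`` of training — the standard dictionary-learning guard
    against dead and duplicated atoms; set ``max_coherence=None`` and
    ``dead_patience=0`` to disable.
    """

    penalty: PenaltySpec
    eta: float = 1e-2
    batch_size: int = 250
    n_batches: int = 400
    patch_size: int = 16
    n_units: int = 100
    lr_schedule: str = "constant"
    decay_divisor: float = 50.0
    seed: int = 0
    coding: CodingConfig = field(default_factory=CodingConfig)
    dead_patience: int = 10
    max_coherence: float | None = 0.95
    replace_frac: float = 0.6

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_schedule not in ("constant", "time_decay"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


def time_decay_rate(lr0: float, divisor: float, t: int) -> float:
    """Time-based decay lr0 / (1 + (lr0/divisor) * t); equals lr0 at t = 0."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return lr0 / (1.0 + (lr0 / divisor) * t)


def dictionary_update(
    dictionary: Dictionary,
    patches: np.ndarray,
    codes: np.ndarray,
    eta: float,
    rng: np.random.Generator | None = None,
) -> Dictionary:
    """One gradient step on Phi from a coded batch, then column renormalization.

    ``patches`` is B x M and ``codes`` B x N (computed against ``dictionary``).
    The update is the batch mean of the residual-code outer products.
    """
    patches = np.atleast_2d(patches)
    codes = np.atleast_2d(codes)
    phi = dictionary.phi
    resid = patches - codes @ phi.T  # B x M
    phi = phi + eta * (resid.T @ codes) / patches.shape[0]
    norms = np.linalg.norm(phi, axis=0)
    dead = norms == 0.0
    if np.any(dead):
        rng = rng or np.random.default_rng(0)
        logger.warning("re-randomizing %d zero-norm dictionary columns", int(dead.sum()))
        fresh = rng.standard_normal((phi.shape[0], int(dead.sum())))
        phi[:, dead] = fresh
        norms = np.linalg.norm(phi, axis=0)
    return Dictionary(phi / norms, created_by=dictionary.created_by)


def _replace_degenerate_columns(
    dictionary: Dictionary,
    patches: np.ndarray,
    codes: np.ndarray,
    usage: np.ndarray,
    inactive: np.ndarray,
    cfg: TrainConfig,
) -> None:
    """Swap dead or duplicated columns for the batch's worst-coded patches, in place."""
    mask = (cfg.dead_patience > 0) & (inactive >= cfg.dead_patience)
    if cfg.max_coherence is not None:
        gram = np.abs(dictionary.phi.T @ dictionary.phi)
        np.fill_diagonal(gram, 0.0)
        partner = np.argmax(gram, axis=1)
        coh = gram[np.arange(dictionary.n), partner]
        dup = (coh > cfg.max_coherence) & (usage <= usage[partner])
        mask = mask | dup
    if not np.any(mask):
        return
    # at most one replacement per patch in the batch
    cols = np.flatnonzero(mask)[: patches.shape[0]]
    logger.info("replacing %d degenerate dictionary columns", cols.size)
    resid = patches - codes @ dictionary.phi.T
    worst = np.argsort(np.linalg.norm(resid, axis=1))[::-1][: cols.size]
    fresh = patches[worst].T
    norms = np.linalg.norm(fresh, axis=0)
    ok = norms > 0
    dictionary.phi[:, cols[ok]] = fresh[:, ok] / norms[ok]
    inactive[cols] = 0


def _train_loop(sample_batch, cfg: TrainConfig, m: int) -> tuple[Dictionary, pd.DataFrame]:
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    phi = random_unit_dictionary(m, cfg.n_units, seed=cfg.seed)
    dictionary = Dictionary(phi, created_by=f"{cfg.penalty.kind}/seed={cfg.seed}")
    rows = []
    inactive = np.zeros(cfg.n_units, dtype=int)
    mu0 = cfg.coding.mu
    for t in range(cfg.n_batches):
        if cfg.lr_schedule == "time_decay":
            eta_t = time_decay_rate(cfg.eta, cfg.decay_divisor, t)
            coding_t = replace(
                cfg.coding,
                mu=None if mu0 is None else time_decay_rate(mu0, cfg.decay_divisor, t),
            )
        else:
            eta_t, coding_t = cfg.eta, cfg.coding
        patches = sample_batch(t)
        codes, mse, active = sparse_code_batch(patches, dictionary.phi, cfg.penalty, coding_t)
        if not np.all(np.isfinite(mse)):
            raise FloatingPointError(f"non-finite batch MSE at batch {t}; aborting training")
        usage = np.count_nonzero(codes, axis=0)
        inactive = np.where(usage == 0, inactive + 1, 0)
        dictionary = dictionary_update(dictionary, patches, codes, eta_t, rng)
        if t < cfg.n_batches * cfg.replace_frac:
            _replace_degenerate_columns(dictionary, patches, codes, usage, inactive, cfg)
        rows.append(
            {
                "batch": t,
                "mse": float(mse.mean()),
                "mean_active": float(active.mean()),
                "sd_active": float(active.std()),
                "lambda": cfg.penalty.lam,
                "eta": eta_t,
            }
        )
    trace = pd.DataFrame(rows, columns=["batch", "mse", "mean_active", "sd_active", "lambda", "eta"])
    return dictionary, trace


def train(images: list[PreprocessedImage], cfg: TrainConfig) -> tuple[Dictionary, pd.DataFrame]:
    """Alternating sparse coding / dictionary learning on preprocessed images.

    Each batch extracts ``batch_size`` random patches (seeded per batch),
    codes them against the current dictionary, and applies one dictionary
    update.  Deterministic for a given config: the same seed reproduces the
    final dictionary bit for bit.
    """
    if len(images) == 0:
        raise ValueError("empty image list")
    m = cfg.patch_size**2
    batch_seeds = np.random.SeedSequence(cfg.seed).generate_state(max(cfg.n_batches, 1)) % (2**31)

    def sample_batch(t: int) -> np.ndarray:
        return extract_patches(images, cfg.patch_size, cfg.batch_size, int(batch_seeds[t])).patches

    return _train_loop(sample_batch, cfg, m)


def train_on_planted(model: PlantedModel, cfg: TrainConfig) -> tuple[Dictionary, pd.DataFrame]:
    """Train on patches drawn from a planted sparse model (recovery experiments)."""
    batch_seeds = np.random.SeedSequence(cfg.seed).generate_state(max(cfg.n_batches, 1)) % (2**31)

    def sample_batch(t: int) -> np.ndarray:
        batch_model = replace(model, seed=int(batch_seeds[t]))
        patches, _ = sample_planted_patches(batch_model, cfg.batch_size)
        return patches

    return _train_loop(sample_batch, cfg, model.m)


def best_match_correlations(learned: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Greedy matching of learned columns to planted ones by |inner product|.

    Returns, for each true column, the |cosine| of its greedily assigned
    learned column (both sets unit-norm).  Used as the recovery score of
    planted-model experiments.
    """
    sim = np.abs(true.T @ learned)  # n_true x n_learned
    sim = sim.copy()
    scores = np.zeros(true.shape[1])
    for _ in range(min(sim.shape)):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        scores[i] = sim[i, j]
        sim[i, :] = -1.0
        sim[:, j] = -1.0
    return scores
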