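"""The coding step: proximal-gradient search for sparse coefficients.

Given a patch I and a fixed dictionary Phi with unit-norm columns, the code
r minimizes the energy

    E(r, Phi) = 1/2 * ||I - Phi r||^2 + lambda * sum_i c(r_i)

by alternating a gradient step on the quadratic data term with the
component-wise thresholding operator of the chosen penalty:

    r <- T( r - mu * Phi^T (Phi r - I) ),   r_0 = 0.

Activities charge up from zero; the step size mu must lie in (0, 1/L] with
L the largest eigenvalue of Phi^T Phi for the descent guarantees to hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import PenaltySpec, effective_penalty_weight, penalty_value, threshold

__all__ = [
    "CodingConfig",
    "SparseCode",
    "sparse_code",
    "sparse_code_batch",
    "energy",
    "lipschitz_bound",
]


@dataclass
class CodingConfig:
    """Step size, iteration budget and the active-coefficient tolerance.

    ``mu = None`` means "use 1/L computed from the dictionary".  All four
    thresholding operators produce exact zeros, so ``active_tol`` defaults to
    exactly 0.
    """

    mu: float | None = None
    max_iters: int = 200
    active_tol: float = 0.0
    record_energy: bool = True

    def __post_init__(self) -> None:
        if self.mu is not None and self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class SparseCode:
    """Final coefficients with the active count, per-iteration energy and MSE."""

    r: np.ndarray
    active_count: int
    energy_trace: np.ndarray
    final_mse: float


def lipschitz_bound(phi: np.ndarray) -> float:
    """Largest singular value of Phi squared: Lipschitz constant of the data-term gradient."""
    return float(np.linalg.norm(phi, 2) ** 2)


def energy(patch: np.ndarray, phi: np.ndarray, r: np.ndarray, penalty: PenaltySpec,
           weight: float | None = None) -> float:
    """E(r, Phi) = 1/2 ||I - Phi r||^2 + w * C(r).

    By default w = lambda for soft/half/hard and w = 1 for CEL0 (whose
    penalty carries lambda internally).  Pass ``weight`` explicitly to
    evaluate the effective energy the proximal iteration descends (see
    :func:`v1sparse.operators.effective_penalty_weight`).
    """
    resid = patch - phi @ r
    if weight is None:
        weight = 1.0 if penalty.kind == "cel0" else penalty.lam
    elif penalty.kind == "cel0":
        weight = weight / penalty.lam  # CEL0 penalty already carries lambda
    return float(0.5 * resid @ resid + weight * penalty_value(r, penalty))


def _resolve_mu(cfg: CodingConfig, phi: np.ndarray) -> float:
    return 1.0 / lipschitz_bound(phi) if cfg.mu is None else cfg.mu


def sparse_code(
    patch: np.ndarray,
    phi: np.ndarray,
    penalty: PenaltySpec,
    cfg: CodingConfig | None = None,
) -> SparseCode:
    """Code one patch against a fixed dictionary; returns the full energy trace."""
    cfg = cfg or CodingConfig()
    patch = np.asarray(patch, dtype=float)
    if patch.shape[0] != phi.shape[0]:
        raise ValueError(f"patch length {patch.shape[0]} != dictionary rows {phi.shape[0]}")
    mu = _resolve_mu(cfg, phi)
    spec = PenaltySpec(penalty.kind, penalty.lam, mu, penalty.column_norms)
    gram = phi.T @ phi
    drive = phi.T @ patch
    r = np.zeros(phi.shape[1])
    trace = np.empty(cfg.max_iters) if cfg.record_energy else np.empty(0)
    for t in range(cfg.max_iters):
        r = threshold(r - mu * (gram @ r - drive), spec)
        if cfg.record_energy:
            e = energy(patch, phi, r, spec)
            if not np.isfinite(e):
                raise FloatingPointError(
                    f"energy diverged at iteration {t}: step size mu={mu} violates the "
                    f"mu <= 1/L contract (1/L = {1.0 / lipschitz_bound(phi):.3g})"
                )
            trace[t] = e
    resid = patch - phi @ r
    return SparseCode(
        r=r,
        active_count=int(np.sum(np.abs(r) > cfg.active_tol)),
        energy_trace=trace,
        final_mse=float(np.mean(resid**2)),
    )


def sparse_code_batch(
    patches: np.ndarray,
    phi: np.ndarray,
    penalty: PenaltySpec,
    cfg: CodingConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Code a B x M batch at once; returns (codes B x N, mse per patch, active counts).

    Vectorized twin of :func:`sparse_code` (no per-iteration energy trace);
    used by the training loop and the experiment drivers.
    """
    cfg = cfg or CodingConfig()
    patches = np.atleast_2d(np.asarray(patches, dtype=float))
    mu = _resolve_mu(cfg, phi)
    spec = PenaltySpec(penalty.kind, penalty.lam, mu, penalty.column_norms)
    gram = phi.T @ phi
    drive = patches @ phi  # B x N
    codes = np.zeros((patches.shape[0], phi.shape[1]))
    for _ in range(cfg.max_iters):
        codes = threshold(codes - mu * (codes @ gram - drive), spec)
    if not np.all(np.isfinite(codes)):
        raise FloatingPointError(
            f"codes diverged: step size mu={mu} violates the mu <= 1/L contract "
            f"(1/L = {1.0 / lipschitz_bound(phi):.3g})"
        )
    resid = patches - codes @ phi.T
    mse = np.mean(resid**2, axis=1)
    active = np.sum(np.abs(codes) > cfg.active_tol, axis=1)
    return codes, mse, active


def effective_energy(patch, phi, r, penalty: PenaltySpec) -> float:
    """Energy with the operator's effective penalty weight (monotone under coding)."""
    return energy(patch, phi, r, penalty, weight=effective_penalty_weight(penalty))
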