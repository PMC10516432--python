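"""Sparsity penalties and their component-wise thresholding (proximal) operators.

Four penalties c(.) are supported, each paired with the closed-form
thresholding rule applied after every gradient step of the coding loop:

``soft_l1``
    c(r) = |r|; soft thresholding (ISTA).
``half_l12``
    c(r) = |r|^(1/2); half thresholding.
``hard_l0``
    c(r) = 1{r != 0}; hard thresholding.
``cel0``
    the continuous exact relaxation of the l0 pseudo-norm, whose penalty
    saturates at lambda once a coefficient clears sqrt(2*lambda)/||phi_i||;
    its prox preserves the global minimizers of the ideal l2-l0 problem.

Each operator is the exact scalar proximal map

    T(z) = argmin_y  w * c(y) + (1/(2*mu)) * (y - z)^2

for a documented *effective* weight w (see :func:`effective_penalty_weight`):
soft and CEL0 use w = lambda; half and hard follow the conventional
closed forms of the literature, which correspond to w = lambda/2 and
w = lambda^2 * mu / 2 respectively.  ``prox_oracle`` is a brute-force grid
minimizer used in the test-suite to certify every closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PenaltySpec",
    "soft_threshold",
    "half_threshold",
    "hard_threshold",
    "cel0_threshold",
    "threshold",
    "penalty_value",
    "effective_penalty_weight",
    "thresholding_region",
    "prox_oracle",
]

PENALTY_KINDS = ("soft_l1", "half_l12", "hard_l0", "cel0")

# threshold below which the half operator returns 0: (54^(1/3)/4) * theta^(2/3)
_HALF_KNEE = 54.0 ** (1.0 / 3.0) / 4.0


@dataclass
class PenaltySpec:
    """Penalty kind plus the regularization weight lambda and step size mu.

    ``column_norms`` (length-N, all positive) is consulted by the CEL0
    operator only; dictionaries in this package keep unit-norm columns, so
    the default of ``None`` means "all ones".
    """

    kind: str
    lam: float
    mu: float
    column_norms: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in PENALTY_KINDS:
            raise ValueError(f"unknown penalty kind {self.kind!r}; expected one of {PENALTY_KINDS}")
        if not (self.lam > 0 and self.mu > 0):
            raise ValueError(f"lam and mu must be positive, got lam={self.lam}, mu={self.mu}")
        if self.column_norms is not None:
            self.column_norms = np.asarray(self.column_norms, dtype=float)
            if np.any(self.column_norms <= 0):
                raise ValueError("column_norms must all be positive")

    @property
    def theta(self) -> float:
        """Thresholding parameter theta = lambda * mu."""
        return self.lam * self.mu

    def with_lam(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(self.kind, lam, self.mu, self.column_norms)


def soft_threshold(z, theta: float):
    """Soft thresholding: shrink towards zero by theta, clip to 0 inside [-theta, theta]."""
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - theta, 0.0)


def half_threshold(z, theta: float):
    """Half thresholding for the l1/2 penalty, theta = lambda * mu.

    Returns 0 for |z| <= (54^(1/3)/4) * theta^(2/3); above the knee,

        f(z) = (2/3) * z * (1 + cos(2*pi/3 - (2/3) * psi(z))),
        psi(z) = arccos((theta/8) * (|z|/3)^(-3/2)).

    This is the exact prox of w*|y|^(1/2) + (y-z)^2/(2*mu) at the effective
    weight w = lambda/2 (certified against the grid oracle in the tests).
    """
    z = np.asarray(z, dtype=float)
    knee = _HALF_KNEE * theta ** (2.0 / 3.0)
    out = np.zeros_like(z)
    m = np.abs(z) > knee
    if np.any(m):
        zz = z[m]
        arg = (theta / 8.0) * (np.abs(zz) / 3.0) ** (-1.5)
        # above the knee arg < 1; clip guards the boundary against fp round-off
        psi = np.arccos(np.clip(arg, -1.0, 1.0))
        out[m] = (2.0 / 3.0) * zz * (1.0 + np.cos(2.0 * np.pi / 3.0 - (2.0 / 3.0) * psi))
    return out


def hard_threshold(z, theta: float):
    """Hard thresholding: zero for |z| <= theta, identity above (tie resolves to 0)."""
    z = np.asarray(z, dtype=float)
    return np.where(np.abs(z) > theta, z, 0.0)


def cel0_threshold(z, lam: float, mu: float, col_norm=1.0):
    """CEL0 thresholding, the exact prox of the CEL0 penalty with step mu.

    With a = ||phi_i||^2 * mu < 1 the map is

        sign(z) * min(|z|, (|z| - mu*sqrt(2*lam)*||phi_i||)_+ / (1 - a)),

    i.e. a soft-like shrinkage with knee mu*sqrt(2*lam)*||phi_i|| that joins
    the identity at |z| = sqrt(2*lam)/||phi_i|| where the penalty saturates.
    For a >= 1 the map is hard-like with knee sqrt(2*mu*lam) (exact at a = 1;
    unreachable with unit-norm columns and mu < 1). Ties resolve to 0.
    """
    z = np.asarray(z, dtype=float)
    norms = np.broadcast_to(np.asarray(col_norm, dtype=float), z.shape)
    a = mu * norms**2
    # a < 1 branch
    knee = mu * np.sqrt(2.0 * lam) * norms
    shrunk = np.maximum(np.abs(z) - knee, 0.0) / np.where(a < 1, 1.0 - a, 1.0)
    soft_like = np.sign(z) * np.minimum(np.abs(z), shrunk)
    # a >= 1 branch
    hard_like = np.where(np.abs(z) > np.sqrt(2.0 * mu * lam), z, 0.0)
    return np.where(a < 1, soft_like, hard_like)


def threshold(z, spec: PenaltySpec):
    """Apply the thresholding operator selected by ``spec`` component-wise."""
    if spec.kind == "soft_l1":
        return soft_threshold(z, spec.theta)
    if spec.kind == "half_l12":
        return half_threshold(z, spec.theta)
    if spec.kind == "hard_l0":
        return hard_threshold(z, spec.theta)
    norms = 1.0 if spec.column_norms is None else spec.column_norms
    return cel0_threshold(z, spec.lam, spec.mu, norms)


def penalty_value(r, spec: PenaltySpec) -> float:
    """Total penalty C(r) = sum_i c(r_i) for the given spec.

    For soft/half/hard this is the raw penalty (the energy multiplies it by
    lambda); for CEL0 lambda lives inside the penalty and the outer weight
    is 1:  c_i(r) = lam - (||phi_i||^2/2) * (sqrt(2*lam)/||phi_i|| - |r|)_+^2,
    which is 0 at r = 0 and saturates at lam.
    """
    r = np.asarray(r, dtype=float)
    if spec.kind == "soft_l1":
        return float(np.sum(np.abs(r)))
    if spec.kind == "half_l12":
        return float(np.sum(np.sqrt(np.abs(r))))
    if spec.kind == "hard_l0":
        return float(np.count_nonzero(r))
    norms = np.ones_like(r) if spec.column_norms is None else np.broadcast_to(spec.column_norms, r.shape)
    gap = np.maximum(np.sqrt(2.0 * spec.lam) / norms - np.abs(r), 0.0)
    return float(np.sum(spec.lam - 0.5 * norms**2 * gap**2))


def effective_penalty_weight(spec: PenaltySpec) -> float:
    """Weight w for which the operator is the exact prox of w * c(.).

    soft and cel0: w = lambda.  half (conventional closed form): w = lambda/2.
    hard (knee at theta = lambda*mu rather than the exact-prox sqrt(2*lambda*mu)):
    w = lambda^2 * mu / 2.  The coding iteration therefore monotonically
    decreases the energy built with this weight.
    """
    if spec.kind in ("soft_l1", "cel0"):
        return spec.lam
    if spec.kind == "half_l12":
        return spec.lam / 2.0
    return spec.lam**2 * spec.mu / 2.0


def thresholding_region(spec: PenaltySpec, col_norm: float = 1.0) -> float:
    """Half-width of the symmetric interval around 0 mapped exactly to 0."""
    if spec.kind == "soft_l1":
        return spec.theta
    if spec.kind == "half_l12":
        return _HALF_KNEE * spec.theta ** (2.0 / 3.0)
    if spec.kind == "hard_l0":
        return spec.theta
    a = spec.mu * col_norm**2
    if a < 1:
        return spec.mu * np.sqrt(2.0 * spec.lam) * col_norm
    return float(np.sqrt(2.0 * spec.mu * spec.lam))


def _scalar_penalty(y, spec: PenaltySpec, weight: float, col_norm: float):
    """Vectorized scalar penalty w*c(y) used by the grid oracle."""
    y = np.asarray(y, dtype=float)
    if spec.kind == "soft_l1":
        return weight * np.abs(y)
    if spec.kind == "half_l12":
        return weight * np.sqrt(np.abs(y))
    if spec.kind == "hard_l0":
        return weight * (y != 0.0)
    gap = np.maximum(np.sqrt(2.0 * spec.lam) / col_norm - np.abs(y), 0.0)
    return spec.lam - 0.5 * col_norm**2 * gap**2


def prox_oracle(
    z: float,
    spec: PenaltySpec,
    grid_halfwidth: float,
    grid_points: int = 100_001,
    weight: float | None = None,
    col_norm: float = 1.0,
) -> float:
    """Brute-force scalar prox: dense-grid minimizer of w*c(y) + (y-z)^2/(2*mu).

    A test oracle, independent of every closed form above: dense grid over
    [-grid_halfwidth, +grid_halfwidth], then bounded local refinement between
    the neighbours of the grid argmin, with y = 0 always kept as a candidate
    (the objective is non-smooth there).  ``weight`` defaults to the
    operator's effective weight so the oracle certifies the implemented
    convention.
    """
    if grid_points < 10_000:
        raise ValueError("grid_points must be at least 10^4 for a trustworthy oracle")
    if grid_halfwidth < abs(z):
        raise ValueError("grid too narrow to bracket |z|")
    w = effective_penalty_weight(spec) if weight is None else weight

    def obj(y: float) -> float:
        return float(_scalar_penalty(y, spec, w, col_norm)) + (float(y) - z) ** 2 / (2.0 * spec.mu)

    grid = np.linspace(-grid_halfwidth, grid_halfwidth, grid_points)
    vals = _scalar_penalty(grid, spec, w, col_norm) + (grid - z) ** 2 / (2.0 * spec.mu)
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid_points - 1)]
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    candidates = [float(res.x), 0.0, float(grid[i])]
    return min(candidates, key=obj)
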