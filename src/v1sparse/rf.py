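"""Receptive-field analysis: orientation tuning, circular variance, Gabor fits.

A learned dictionary column phi_i is treated as a model neuron's linear
receptive field.  Orientation selectivity is probed with a bank of
sinusoidal gratings: the grating with the highest inner product fixes the
unit's optimal spatial frequency, and the tuning curve alpha_k is the
maximum inner product over phases at each orientation theta_k (K = 36
equidistant orientations in [0, pi)).  Selectivity is summarized by the
circular variance

    V = 1 - |R|,   R = sum_k alpha_k exp(i 2 theta_k) / sum_k alpha_k,

(V = 0: responds to a single orientation; V = 1: untuned), and RF shape by a
least-squares Gabor fit whose envelope widths, normalized by the carrier
period, populate the shape scatter used to compare regularizers with
cortical subunits (fits with r^2 < 0.6 are excluded).

Orientation convention: theta is the angle of the grating's carrier wave
vector (the normal to the stripes), measured from the horizontal x-axis,
increasing counterclockwise; a unit preferring "vertical" stripes has its
carrier along x.  Preferred orientations are reported in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GratingBank",
    "make_grating_bank",
    "TuningCurve",
    "OrientationStats",
    "GaborFit",
    "tuning_curve",
    "circular_variance",
    "orientation_histograms",
    "gabor",
    "fit_gabor",
    "shape_table",
]


@dataclass
class GratingBank:
    """Precomputed gratings: array (n_sf, n_orient, n_phase, P*P), unit L2 norm each."""

    gratings: np.ndarray
    spatial_frequencies: np.ndarray
    orientations: np.ndarray
    phases: np.ndarray
    patch_size: int


def make_grating_bank(
    patch_size: int,
    n_orientations: int = 36,
    n_phases: int = 8,
    spatial_frequencies: np.ndarray | None = None,
) -> GratingBank:
    """Bank of L2-normalized sinusoidal gratings.

    Spatial frequencies default to 16 log-spaced values between 0.5 and P/4
    cycles per patch; orientations are theta_k = k*pi/K, phases equidistant
    in [0, 2*pi).
    """
    if n_orientations < 1 or n_phases < 1:
        raise ValueError("bank must contain at least one orientation and one phase")
    p = patch_size
    if spatial_frequencies is None:
        spatial_frequencies = np.geomspace(0.5, p / 4.0, 16)
    sfs = np.asarray(spatial_frequencies, dtype=float)
    orientations = np.arange(n_orientations) * np.pi / n_orientations
    phases = np.arange(n_phases) * 2.0 * np.pi / n_phases
    y, x = np.mgrid[0:p, 0:p].astype(float)
    x -= (p - 1) / 2.0
    y -= (p - 1) / 2.0
    bank = np.empty((len(sfs), n_orientations, n_phases, p * p))
    for i, sf in enumerate(sfs):
        for j, th in enumerate(orientations):
            carrier = (x * np.cos(th) + y * np.sin(th)) * (2.0 * np.pi * sf / p)
            for k, ph in enumerate(phases):
                g = np.cos(carrier + ph).ravel()
                bank[i, j, k] = g / np.linalg.norm(g)
    return GratingBank(bank, sfs, orientations, phases, p)


@dataclass
class TuningCurve:
    """Responses alpha_k over orientations theta_k at the unit's optimal spatial frequency."""

    alpha: np.ndarray
    theta: np.ndarray
    optimal_sf: float


@dataclass
class OrientationStats:
    """Circular variance V = 1 - |R|, the resultant R, and the preferred orientation."""

    circular_variance: float
    resultant: complex
    preferred_orientation: float


def tuning_curve(unit: np.ndarray, bank: GratingBank) -> TuningCurve:
    """Two-stage probe: argmax grating fixes optimal SF, then max-over-phase per orientation."""
    unit = np.asarray(unit, dtype=float).ravel()
    if unit.size != bank.patch_size**2:
        raise ValueError(
            f"unit length {unit.size} does not match bank patch size {bank.patch_size}^2"
        )
    if bank.gratings.size == 0:
        raise ValueError("empty grating bank")
    responses = bank.gratings @ unit  # (n_sf, n_orient, n_phase)
    flat_idx = np.argmax(responses)
    sf_idx = np.unravel_index(flat_idx, responses.shape)[0]
    alpha = responses[sf_idx].max(axis=1)
    return TuningCurve(alpha, bank.orientations.copy(), float(bank.spatial_frequencies[sf_idx]))


def circular_variance(curve: TuningCurve) -> OrientationStats:
    """V = 1 - |R| with the doubled-angle resultant; preferred orientation = arg(R)/2."""
    alpha = np.asarray(curve.alpha, dtype=float)
    total = alpha.sum()
    if total <= 0:
        raise ValueError("all-zero tuning curve: circular variance undefined")
    resultant = complex(np.sum(alpha * np.exp(2j * curve.theta)) / total)
    preferred = (np.angle(resultant) / 2.0) % np.pi
    return OrientationStats(1.0 - abs(resultant), resultant, float(preferred))


def orientation_histograms(
    stats: list[OrientationStats], bins: int = 18
) -> dict[str, pd.DataFrame]:
    """Population summaries: CV histogram, preferred-orientation proportions, CV-by-orientation.

    The circular-variance histogram is normalized to sum to 1; preferred
    orientations are binned over [0, pi).
    """
    if len(stats) == 0:
        raise ValueError("empty statistics list")
    cv = np.array([s.circular_variance for s in stats])
    pref = np.array([s.preferred_orientation for s in stats])
    cv_counts, cv_edges = np.histogram(cv, bins=bins, range=(0.0, 1.0))
    cv_hist = pd.DataFrame(
        {"bin_left": cv_edges[:-1], "bin_right": cv_edges[1:], "mass": cv_counts / len(stats)}
    )
    po_edges = np.linspace(0.0, np.pi, bins + 1)
    which = np.clip(np.digitize(pref, po_edges) - 1, 0, bins - 1)
    counts = np.bincount(which, minlength=bins)
    mean_cv = np.full(bins, np.nan)
    for b in range(bins):
        if counts[b]:
            mean_cv[b] = cv[which == b].mean()
    po_hist = pd.DataFrame(
        {
            "bin_left": po_edges[:-1],
            "bin_right": po_edges[1:],
            "proportion": counts / len(stats),
            "mean_circular_variance": mean_cv,
        }
    )
    return {"circular_variance": cv_hist, "preferred_orientation": po_hist}


@dataclass
class GaborFit:
    """Fitted Gabor parameters and the goodness of fit r^2.

    ``sigma_parallel`` is the Gaussian envelope SD along the stripes (the
    axis parallel to the grating), ``sigma_orthogonal`` across them (along
    the carrier).  ``orientation`` follows the bank convention (carrier
    angle), reduced to [0, pi); ``phase`` to [0, 2*pi).
    """

    amplitude: float
    center: tuple[float, float]
    orientation: float
    period: float
    phase: float
    sigma_parallel: float
    sigma_orthogonal: float
    r2: float


def gabor(
    patch_size: int,
    amplitude: float,
    center: tuple[float, float],
    orientation: float,
    period: float,
    phase: float,
    sigma_parallel: float,
    sigma_orthogonal: float,
) -> np.ndarray:
    """Render the 8-parameter Gabor on a P x P grid (flattened row-major).

    u is the coordinate along the carrier (orthogonal to the stripes), v
    along the stripes:
        g = A * exp(-u^2/(2*sigma_orth^2) - v^2/(2*sigma_par^2)) * cos(2*pi*u/period + phase)
    """
    y, x = np.mgrid[0:patch_size, 0:patch_size].astype(float)
    u = (x - center[0]) * np.cos(orientation) + (y - center[1]) * np.sin(orientation)
    v = -(x - center[0]) * np.sin(orientation) + (y - center[1]) * np.cos(orientation)
    env = np.exp(-(u**2) / (2 * sigma_orthogonal**2) - (v**2) / (2 * sigma_parallel**2))
    return (amplitude * env * np.cos(2 * np.pi * u / period + phase)).ravel()


def _canonicalize(params: np.ndarray) -> np.ndarray:
    a, x0, y0, th, period, ph, sp, so = params
    sp, so = abs(sp), abs(so)
    if period < 0:  # cos(2*pi*u/(-T) + ph) = cos(2*pi*u/T - ph)
        period, ph = -period, -ph
    if a < 0:  # fold the sign into the phase
        a, ph = -a, ph + np.pi
    # theta -> theta + pi flips the carrier direction; compensate with phase
    th_mod = th % (2 * np.pi)
    if th_mod >= np.pi:
        th_mod -= np.pi
        ph = -ph  # cos(-2pi u/T + ph) = cos(2pi u/T - ph)
    return np.array([a, x0, y0, th_mod, period, ph % (2 * np.pi), sp, so])


def fit_gabor(unit: np.ndarray, restarts: int = 8, seed: int = 0, max_nfev: int = 1500) -> GaborFit:
    """Least-squares (Gaussian-noise maximum likelihood) Gabor fit with multistart.

    Starts combine a grid of orientations with jittered centers around the
    peak-magnitude pixel and a few candidate periods; the best r^2 is kept.
    ``max_nfev`` bounds the function evaluations per start (non-Gabor-like
    units otherwise exhaust large optimizer budgets without improving).
    """
    unit = np.asarray(unit, dtype=float).ravel()
    p = int(round(np.sqrt(unit.size)))
    if p * p != unit.size:
        raise ValueError("unit length is not a perfect square")
    rng = np.random.default_rng(seed)
    peak = int(np.argmax(np.abs(unit)))
    cy, cx = divmod(peak, p)
    ss_tot = float(np.sum((unit - unit.mean()) ** 2))
    amp0 = float(np.abs(unit).max())

    def residuals(params: np.ndarray) -> np.ndarray:
        a, x0, y0, th, period, ph, sp, so = params
        return gabor(p, a, (x0, y0), th, max(period, 1e-3), ph, max(sp, 1e-3), max(so, 1e-3)) - unit

    best = None
    best_cost = np.inf
    thetas = np.linspace(0, np.pi, restarts, endpoint=False)
    periods = [p / 2.0, p / 4.0]
    for i, th0 in enumerate(thetas):
        for period0 in periods:
            x0 = cx + rng.uniform(-1, 1)
            y0 = cy + rng.uniform(-1, 1)
            start = np.array([amp0, x0, y0, th0, period0, 0.0, p / 6.0, p / 6.0])
            try:
                res = least_squares(residuals, start, method="lm", max_nfev=max_nfev)
            except (ValueError, FloatingPointError):
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            if res.cost < best_cost:
                best_cost, best = res.cost, res.x
    if best is None:
        raise RuntimeError("all Gabor fit starts failed")
    a, x0, y0, th, period, ph, sp, so = _canonicalize(np.asarray(best))
    ss_res = float(np.sum(residuals(np.array([a, x0, y0, th, period, ph, sp, so])) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    return GaborFit(
        amplitude=float(a),
        center=(float(x0), float(y0)),
        orientation=float(th),
        period=float(period),
        phase=float(ph),
        sigma_parallel=float(sp),
        sigma_orthogonal=float(so),
        r2=float(r2),
    )


def shape_table(fits: list[GaborFit], r2_min: float = 0.6) -> pd.DataFrame:
    """Envelope widths normalized by the period, for fits passing the r^2 filter.

    Columns: sigma_par_norm, sigma_orth_norm (both sigma/period) and the
    aspect ratio sigma_parallel / sigma_orthogonal.
    """
    rows = []
    for i, f in enumerate(fits):
        if f.r2 >= r2_min:
            rows.append(
                {
                    "unit": i,
                    "sigma_par_norm": f.sigma_parallel / f.period,
                    "sigma_orth_norm": f.sigma_orthogonal / f.period,
                    "aspect_ratio": f.sigma_parallel / f.sigma_orthogonal,
                    "r2": f.r2,
                }
            )
    return pd.DataFrame(rows, columns=["unit", "sigma_par_norm", "sigma_orth_norm", "aspect_ratio", "r2"])
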