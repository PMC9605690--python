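"""Spatial density of encoding classes across the cervical connective.

Gaussian kernel density estimates of ROI positions (x = medial-lateral,
z = dorsal-ventral, micrometres), with the kernel bandwidth selected by
leave-one-out cross-validation (maximizing the summed log-likelihood of
each left-out sample) and densities of an encoding subset normalized by
the density of all annotated ROIs to correct for the uneven distribution
of neurons across the connective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DensityMap", "loo_log_likelihood", "select_bandwidth_loo", "kde_on_grid", "normalized_density"]

DEFAULT_BANDWIDTHS = tuple(float(b) for b in np.logspace(np.log10(0.5), np.log10(50.0), 25))
REFERENCE_FLOOR = 0.01  # fraction of the reference density's max


@dataclass
class DensityMap:
    """KDE of a subset, its reference, and their ratio on a grid."""

    grid: np.ndarray  # (n_points, d) evaluation points
    density: np.ndarray
    reference_density: np.ndarray
    ratio: np.ndarray  # NaN where the reference is below the floor
    bandwidth: float


def _as_points(a) -> np.ndarray:
    """Coerce to an (n, d) point array; 1-D input becomes (n, 1)."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        return a[:, None]
    if a.ndim != 2:
        raise ValueError("points must be 1-D or (n, d)")
    return a


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)


def loo_log_likelihood(points: np.ndarray, bandwidth: float) -> float:
    """Summed leave-one-out log-likelihood under a Gaussian KDE."""
    pts = _as_points(points)
    n, d = pts.shape
    if n < 3:
        raise ValueError("need at least 3 points")
    d2 = _sq_dists(pts, pts)
    np.fill_diagonal(d2, np.inf)  # exclude each point from its own estimate
    logk = -d2 / (2.0 * bandwidth**2)
    norm = -0.5 * d * np.log(2.0 * np.pi * bandwidth**2) - np.log(n - 1)
    m = logk.max(axis=1)
    m = np.where(np.isfinite(m), m, -np.inf)
    with np.errstate(divide="ignore"):
        ll = m + np.log(np.exp(logk - m[:, None]).sum(axis=1)) + norm
    return float(ll.sum())


def select_bandwidth_loo(
    points: np.ndarray, candidates=DEFAULT_BANDWIDTHS
) -> float:
    """Bandwidth maximizing the leave-one-out log-likelihood.

    Pool positions from all flies before calling when a shared bandwidth is
    wanted.  Raises on fewer than 3 points or an all-identical cloud.
    """
    pts = _as_points(points)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to select a bandwidth")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate point cloud (all positions identical)")
    cands = np.asarray(candidates, dtype=float)
    if np.any(cands <= 0):
        raise ValueError("candidate bandwidths must be positive")
    lls = [loo_log_likelihood(pts, h) for h in cands]
    return float(cands[int(np.argmax(lls))])


def kde_on_grid(points: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE evaluated on grid points (normalized density)."""
    pts = _as_points(points)
    g = _as_points(grid)
    if g.shape[1] != pts.shape[1]:
        g = g.T
    d = pts.shape[1]
    d2 = _sq_dists(g, pts)
    norm = (2.0 * np.pi * bandwidth**2) ** (d / 2.0)
    return np.exp(-d2 / (2.0 * bandwidth**2)).sum(axis=1) / (pts.shape[0] * norm)


def normalized_density(
    subset: np.ndarray,
    reference: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | None = None,
    floor: float = REFERENCE_FLOOR,
) -> DensityMap:
    """KDE of an encoding subset normalized by the all-ROI density.

    The ratio KDE(subset)/KDE(reference) is evaluated on the grid and
    masked (NaN) where the reference density falls below ``floor`` times
    its maximum.  When no bandwidth is given it is selected by LOO on the
    reference set.
    """
    subset = _as_points(subset)
    if subset.size == 0:
        raise ValueError("empty subset")
    if bandwidth is None:
        bandwidth = select_bandwidth_loo(reference)
    dens = kde_on_grid(subset, grid, bandwidth)
    ref = kde_on_grid(reference, grid, bandwidth)
    ratio = np.full_like(dens, np.nan)
    ok = ref > floor * ref.max()
    ratio[ok] = dens[ok] / ref[ok]
    return DensityMap(
        grid=_as_points(grid),
        density=dens,
        reference_density=ref,
        ratio=ratio,
        bandwidth=float(bandwidth),
    )
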