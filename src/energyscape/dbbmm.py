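"""Dynamic Brownian bridge movement model (dBBMM) utilization distributions.

The Brownian bridge between consecutive fixes z_i (time t_i) and z_{i+1} has,
at interior fraction alpha, mean linearly interpolated between the fixes and
isotropic variance

    s(alpha) = T * alpha * (1 - alpha) * sigma2_m
               + (1 - alpha)^2 * delta^2 + alpha^2 * delta^2

with T the segment duration, sigma2_m the Brownian motion variance (m^2/s)
and delta the telemetry location error (m).  The *dynamic* model lets
sigma2_m vary along the track: in a sliding window every odd-indexed fix is
left out and predicted from its neighbours, sigma2_m maximizes the product of
those bridge densities, and a candidate structural breakpoint (outside the
window margins) replaces the single estimate with a two-piece estimate when
BIC favours it.  Per-segment sigma2_m is the mean of the window estimates
covering it (window margins excluded).

The UD integrates the bridge density over time on a grid and normalizes to 1;
the 95% contour (home range) is the smallest set of highest-density cells
whose mass reaches the level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geometry import GridGeometry

__all__ = [
    "UDRaster",
    "estimate_motion_variance",
    "build_ud",
    "ud_contour",
    "ud_at",
]

DEFAULT_WINDOW = 31
DEFAULT_MARGIN = 11
DEFAULT_LOC_ERROR = 20.0
DEFAULT_CELL = 30.0
DEFAULT_TIME_STEP = 60.0

_SIGMA2_BOUNDS = (1e-10, 1e8)  # m^2/s, log-scale search bounds


@dataclass
class UDRaster:
    probabilities: np.ndarray
    geometry: GridGeometry
    motion_variance_series: np.ndarray  # sigma2_m per inter-fix segment
    location_error: float

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"UD probabilities sum to {total}, not 1")


def _bridge_terms(t: np.ndarray, xy: np.ndarray):
    """Leave-one-out bridge geometry for odd-indexed fixes.

    Returns (sq_dev, Tw, alpha): squared deviation of each odd fix from its
    interpolated mean, the enclosing duration, and the interior fraction.
    """
    odd = np.arange(1, len(t) - 1, 2)
    T = t[odd + 1] - t[odd - 1]
    alpha = (t[odd] - t[odd - 1]) / T
    mu = xy[odd - 1] + alpha[:, None] * (xy[odd + 1] - xy[odd - 1])
    sq = ((xy[odd] - mu) ** 2).sum(axis=1)
    return sq, T, alpha


def _neg_loglik(log_s2: float, sq, T, alpha, delta2) -> float:
    s2 = np.exp(log_s2)
    var = T * alpha * (1 - alpha) * s2 + ((1 - alpha) ** 2 + alpha**2) * delta2
    # bivariate isotropic normal
    return float(np.sum(np.log(2 * np.pi * var) + sq / (2 * var)))


def _fit_sigma2(sq, T, alpha, delta2) -> tuple[float, float]:
    """Maximize the odd-fix bridge likelihood over sigma2; returns
    (sigma2_hat, max loglik)."""
    res = minimize_scalar(
        _neg_loglik,
        bounds=np.log(_SIGMA2_BOUNDS),
        args=(sq, T, alpha, delta2),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x)), -float(res.fun)


def estimate_motion_variance(
    track: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    margin: int = DEFAULT_MARGIN,
    loc_error: float = DEFAULT_LOC_ERROR,
) -> np.ndarray:
    """Per-segment Brownian motion variance sigma2_m (m^2/s).

    Windows slide one fix at a time; within each, a single sigma2 is fitted
    to the leave-one-out odd-fix likelihood, candidate breakpoints outside
    the margins are screened, and a two-piece fit replaces the single one
    when BIC prefers it.  Fix-level estimates (margins excluded) are averaged
    across overlapping windows and assigned to the segment starting at each
    fix.  Tracks shorter than one window fall back to a single global
    estimate.
    """
    if window % 2 == 0 or window < 2 * margin + 1:
        raise ValueError("window must be odd and >= 2*margin + 1")
    track = track.sort_values("timestamp")
    t = (
        pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 1e9
    )
    xy = track[["x", "y"]].to_numpy(dtype=float)
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 fixes")
    delta2 = loc_error**2

    if n < window:
        warnings.warn("track shorter than window: single global motion variance")
        sq, T, alpha = _bridge_terms(t, xy)
        s2, _ = _fit_sigma2(sq, T, alpha, delta2)
        return np.full(n - 1, s2)

    acc = np.zeros(n)
    cnt = np.zeros(n)
    for w0 in range(0, n - window + 1):
        w1 = w0 + window
        tw, zw = t[w0:w1], xy[w0:w1]
        sq, T, alpha = _bridge_terms(tw, zw)
        m = len(sq)
        s2_single, ll_single = _fit_sigma2(sq, T, alpha, delta2)
        best = (ll_single * 2 - 1 * np.log(2 * m), None)  # BIC with sign flipped
        # candidate breakpoints: split the odd-fix set, margins respected
        for b in range(1, m):
            # breakpoint at fix index w0 + 2b; require margin fixes each side
            if 2 * b < margin or window - 2 * b < margin:
                continue
            sa, la = _fit_sigma2(sq[:b], T[:b], alpha[:b], delta2)
            sb, lb = _fit_sigma2(sq[b:], T[b:], alpha[b:], delta2)
            score = (la + lb) * 2 - 2 * np.log(2 * m)
            if score > best[0]:
                best = (score, (b, sa, sb))
        core = np.arange(w0 + margin, w1 - margin)  # fixes this window informs
        if best[1] is None:
            acc[core] += s2_single
        else:
            b, sa, sb = best[1]
            cut = w0 + 2 * b
            acc[core] += np.where(core < cut, sa, sb)
        cnt[core] += 1

    fix_s2 = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    # margins at the track ends: extend the nearest informed estimate
    valid = np.flatnonzero(cnt > 0)
    fix_s2[: valid[0]] = fix_s2[valid[0]]
    fix_s2[valid[-1] + 1 :] = fix_s2[valid[-1]]
    return fix_s2[:-1]  # segment i spans fixes i..i+1


def default_geometry(
    track: pd.DataFrame,
    sigma2: np.ndarray,
    loc_error: float,
    cell_size: float = DEFAULT_CELL,
) -> GridGeometry:
    """Grid covering the track bounding box plus a 3-sigma bridge buffer."""
    t = pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 1e9
    dt_max = np.diff(t).max()
    buf = 3 * np.sqrt(np.max(sigma2) * dt_max / 4 + loc_error**2)
    xmin, xmax = track["x"].min() - buf, track["x"].max() + buf
    ymin, ymax = track["y"].min() - buf, track["y"].max() + buf
    nx = int(np.ceil((xmax - xmin) / cell_size))
    ny = int(np.ceil((ymax - ymin) / cell_size))
    return GridGeometry(x0=float(xmin), y0=float(ymin), cell_size=cell_size, nx=nx, ny=ny)


def build_ud(
    track: pd.DataFrame,
    sigma2: np.ndarray,
    geometry: GridGeometry | None = None,
    time_step: float = DEFAULT_TIME_STEP,
    loc_error: float = DEFAULT_LOC_ERROR,
    cell_size: float = DEFAULT_CELL,
) -> UDRaster:
    """Integrate the bridge density over time onto a grid and normalize.

    Each inter-fix segment is sampled at midpoint times spaced <= time_step;
    the isotropic normal factorizes, so each time slice is an outer product
    of 1-D Gaussians over cell centers.
    """
    track = track.sort_values("timestamp").reset_index(drop=True)
    t = pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 1e9
    xy = track[["x", "y"]].to_numpy(dtype=float)
    if len(sigma2) != len(t) - 1:
        raise ValueError("sigma2 must have one value per inter-fix segment")
    if geometry is None:
        geometry = default_geometry(track, sigma2, loc_error, cell_size)
    else:
        xmin, xmax, ymin, ymax = geometry.extent
        if (
            track["x"].min() < xmin
            or track["x"].max() > xmax
            or track["y"].min() < ymin
            or track["y"].max() > ymax
        ):
            raise ValueError("grid does not cover the track bounding box")
    ys, xs = geometry.cell_centers()
    dens = np.zeros(geometry.shape)
    delta2 = loc_error**2
    total_time = t[-1] - t[0]
    for i in range(len(t) - 1):
        T = t[i + 1] - t[i]
        if T <= 0:
            raise ValueError("non-increasing timestamps")
        k = max(1, int(np.ceil(T / time_step)))
        dt = T / k
        alphas = (np.arange(k) + 0.5) / k
        for a in alphas:
            mu = xy[i] + a * (xy[i + 1] - xy[i])
            var = T * a * (1 - a) * sigma2[i] + ((1 - a) ** 2 + a**2) * delta2
            gx = np.exp(-((xs - mu[0]) ** 2) / (2 * var))
            gy = np.exp(-((ys - mu[1]) ** 2) / (2 * var))
            dens += (dt / (2 * np.pi * var)) * np.outer(gy, gx)
    dens /= total_time
    prob = dens * geometry.cell_size**2
    prob /= prob.sum()
    return UDRaster(
        probabilities=prob,
        geometry=geometry,
        motion_variance_series=np.asarray(sigma2, dtype=float),
        location_error=loc_error,
    )


def ud_contour(ud: UDRaster, level: float = 0.95) -> np.ndarray:
    """Smallest highest-density cell set with mass >= level (ties included)."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    p = ud.probabilities.ravel()
    # stable sort: ties resolved deterministically in flat-index order
    order = np.argsort(-p, kind="stable")
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, min(level, csum[-1]) - 1e-12) + 1)
    k = min(k, len(p))
    mask = np.zeros(p.size, dtype=bool)
    mask[order[:k]] = True
    mask &= p > 0
    return mask.reshape(ud.probabilities.shape)


def ud_at(ud: UDRaster, x, y) -> np.ndarray:
    """Nearest-cell UD probability at world coordinates (raster extraction
    semantics); raises outside the grid."""
    iy, ix = ud.geometry.world_to_cell(x, y)
    return ud.probabilities[iy, ix]
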