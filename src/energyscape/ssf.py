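"""Step-selection habitat-suitability estimation and validation.

Observed movement steps (consecutive GPS fixes) are contrasted with K random
steps per stratum that share the observed step's start point.  Random
(speed, turning-angle) pairs are drawn from a bivariate normal fitted to the
empirical joint distribution of the individual's observed steps, speeds are
converted to step lengths with the observed step's duration, and habitat
preference is estimated by conditional logistic regression on the step
endpoints' environmental attributes (land cover vs a reference class, the
four continuous covariates, plus step length and turning angle as movement
controls).

Suitability maps evaluate the fitted linear predictor per cell with step
length and turning angle held at one seeded draw from the movement kernel,
then min-max normalize within the home range to [0, 1].  Validation fits the
model on the chronological first 75% of locations and compares predicted
suitability at the held-out locations with uniform random in-home-range
points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import CONTINUOUS_COVARIATES, LandscapeStack

__all__ = [
    "SsfFit",
    "make_steps",
    "draw_random_steps",
    "fit_conditional_logit",
    "predict_suitability",
    "validate_split",
]

DEFAULT_K = 5


def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


@dataclass
class SsfFit:
    betas: pd.Series
    ses: pd.Series
    loglik: float
    converged: bool
    reference_class: str
    dropped: list[str] = field(default_factory=list)
    kernel_mean: np.ndarray | None = None  # (speed, angle) MVN mean
    kernel_cov: np.ndarray | None = None


def make_steps(track: pd.DataFrame) -> pd.DataFrame:
    """Observed steps from consecutive fixes of one individual.

    Turning angle is relative to the previous step's bearing; the first step
    has none (NaN) and is excluded from angle-dependent draws and strata.
    """
    track = track.sort_values("timestamp").reset_index(drop=True)
    if len(track) < 3:
        raise ValueError("need at least 3 fixes to build steps")
    t = pd.to_datetime(track["timestamp"])
    dt = t.diff().dt.total_seconds().to_numpy()[1:]
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    dx = track["x"].diff().to_numpy()[1:]
    dy = track["y"].diff().to_numpy()[1:]
    length = np.hypot(dx, dy)
    bearing = np.arctan2(dy, dx)
    turn = np.full(len(dt), np.nan)
    turn[1:] = _wrap_angle(np.diff(bearing))
    return pd.DataFrame(
        {
            "start_x": track["x"].to_numpy()[:-1],
            "start_y": track["y"].to_numpy()[:-1],
            "end_x": track["x"].to_numpy()[1:],
            "end_y": track["y"].to_numpy()[1:],
            "t_start": t.to_numpy()[:-1],
            "dt": dt,
            "step_length": length,
            "speed": length / dt,
            "bearing": bearing,
            "prev_bearing": np.concatenate([[np.nan], bearing[:-1]]),
            "turning_angle": turn,
        }
    )


def estimate_kernel(steps: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of (speed, turning angle) over observed steps."""
    ok = steps.dropna(subset=["turning_angle"])
    if len(ok) < 10:
        raise ValueError("need >= 10 observed steps to estimate the movement kernel")
    sv = ok[["speed", "turning_angle"]].to_numpy(dtype=float)
    mean = sv.mean(axis=0)
    cov = np.cov(sv.T)
    if np.linalg.det(cov) < 1e-12:
        warnings.warn("singular speed/angle covariance; jitter added")
        cov = cov + np.eye(2) * 1e-8
    return mean, cov


def _draw_pairs(rng: np.random.Generator, mean, cov, size: int) -> np.ndarray:
    """MVN (speed, angle) pairs; negative speeds resampled, angles wrapped."""
    out = rng.multivariate_normal(mean, cov, size=size)
    bad = out[:, 0] <= 0
    while bad.any():
        out[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()))
        bad = out[:, 0] <= 0
    out[:, 1] = _wrap_angle(out[:, 1])
    return out


def draw_random_steps(
    steps: pd.DataFrame, K: int = DEFAULT_K, seed: int = 0
) -> pd.DataFrame:
    """Strata: each observed step plus K random steps sharing its start.

    Random endpoints are start + L * (cos, sin)(previous bearing + drawn
    angle) with L = drawn speed * observed dt.
    """
    mean, cov = estimate_kernel(steps)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 11])))
    obs = steps.dropna(subset=["turning_angle"]).reset_index(drop=True)
    n = len(obs)
    pairs = _draw_pairs(rng, mean, cov, n * K).reshape(n, K, 2)
    rows = [
        pd.DataFrame(
            {
                "stratum_id": np.arange(n),
                "observed": True,
                "end_x": obs["end_x"],
                "end_y": obs["end_y"],
                "step_length": obs["step_length"],
                "turning_angle": obs["turning_angle"],
                "dt": obs["dt"],
            }
        )
    ]
    for k in range(K):
        sp = pairs[:, k, 0]
        ang = pairs[:, k, 1]
        L = sp * obs["dt"].to_numpy()
        head = obs["prev_bearing"].to_numpy() + ang
        rows.append(
            pd.DataFrame(
                {
                    "stratum_id": np.arange(n),
                    "observed": False,
                    "end_x": obs["start_x"].to_numpy() + L * np.cos(head),
                    "end_y": obs["start_y"].to_numpy() + L * np.sin(head),
                    "step_length": L,
                    "turning_angle": ang,
                    "dt": obs["dt"].to_numpy(),
                }
            )
        )
    strata = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["stratum_id", "observed"], ascending=[True, False], kind="stable")
        .reset_index(drop=True)
    )
    strata.attrs["kernel_mean"] = mean
    strata.attrs["kernel_cov"] = cov
    return strata


def attach_endpoint_covariates(
    strata: pd.DataFrame, stack: LandscapeStack
) -> pd.DataFrame:
    """Sample landscape covariates at (clipped-to-grid) step endpoints."""
    xmin, xmax, ymin, ymax = stack.geometry.extent
    eps = stack.geometry.cell_size * 1e-6
    x = np.clip(strata["end_x"].to_numpy(), xmin + eps, xmax - eps)
    y = np.clip(strata["end_y"].to_numpy(), ymin + eps, ymax - eps)
    out = strata.copy()
    for name, vals in stack.covariates_at(x, y).items():
        out[name] = vals
    return out


def _design(
    strata: pd.DataFrame,
    covariates: tuple[str, ...],
    reference_class: str | None,
) -> tuple[pd.DataFrame, str, list[str]]:
    cols = {}
    ref = ""
    if "land_cover" in covariates and "land_cover" in strata.columns:
        levels = sorted(strata["land_cover"].astype(str).unique())
        if reference_class is None:
            ref = "developed_high" if "developed_high" in levels else levels[0]
        else:
            ref = reference_class
        for lev in levels:
            if lev != ref:
                cols[f"land_cover[{lev}]"] = (
                    strata["land_cover"].astype(str) == lev
                ).astype(float)
    for c in covariates:
        if c == "land_cover":
            continue
        cols[c] = strata[c].to_numpy(dtype=float)
    cols["step_length"] = strata["step_length"].to_numpy(dtype=float)
    cols["turning_angle"] = strata["turning_angle"].to_numpy(dtype=float)
    X = pd.DataFrame(cols)

    # drop covariates with no within-stratum variation anywhere: conditioning
    # on the stratum removes them from the likelihood
    dropped = []
    gid = strata["stratum_id"].to_numpy()
    for c in list(X.columns):
        v = X[c].to_numpy()
        within = pd.Series(v).groupby(gid).nunique()
        if (within <= 1).all():
            warnings.warn(f"{c!r} constant within every stratum; dropped")
            X = X.drop(columns=[c])
            dropped.append(c)
    return X, ref, dropped


def fit_conditional_logit(
    strata: pd.DataFrame,
    covariates: tuple[str, ...] = ("land_cover",) + CONTINUOUS_COVARIATES,
    reference_class: str | None = None,
) -> SsfFit:
    """Conditional logistic regression of observed vs random step endpoints.

    Maximizes sum over strata of x_obs*beta - log(sum_j exp(x_j*beta)).
    """
    from statsmodels.discrete.conditional_models import ConditionalLogit

    if strata["stratum_id"].nunique() < 30:
        warnings.warn("fewer than 30 strata: estimates may be unstable")
    X, ref, dropped = _design(strata, covariates, reference_class)
    y = strata["observed"].astype(int).to_numpy()
    groups = strata["stratum_id"].to_numpy()
    # fit on unit-scaled columns for optimizer conditioning; back-transform
    scale = X.to_numpy().std(axis=0)
    scale[scale == 0] = 1.0
    model = ConditionalLogit(y, X.to_numpy() / scale, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False, maxiter=200, method="newton")
            if not np.isfinite(res.params).all():
                raise ValueError("non-finite estimates")
        except Exception:
            res = model.fit(disp=False, maxiter=500, method="bfgs", gtol=1e-9)
    retvals = getattr(res, "mle_retvals", None) or {}
    converged = bool(retvals.get("converged", True)) and bool(
        np.isfinite(res.params).all()
    )
    if not converged:
        warnings.warn("conditional logit did not converge (separation?)")
    return SsfFit(
        betas=pd.Series(res.params / scale, index=X.columns),
        ses=pd.Series(res.bse / scale, index=X.columns),
        loglik=float(res.llf),
        converged=converged,
        reference_class=ref,
        dropped=dropped,
        kernel_mean=strata.attrs.get("kernel_mean"),
        kernel_cov=strata.attrs.get("kernel_cov"),
    )


def predict_suitability(
    fit: SsfFit,
    stack: LandscapeStack,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell habitat suitability in [0, 1].

    The linear predictor is evaluated with step length and turning angle held
    constant at one seeded draw from the fitted movement kernel (a cell-
    constant offset; it does not affect the min-max normalized surface).
    """
    geom = stack.geometry
    if mask is None:
        mask = np.ones(geom.shape, dtype=bool)
    iy, ix = np.nonzero(mask)
    ys, xs = geom.cell_centers()
    frame = pd.DataFrame(
        {
            "land_cover": np.asarray(stack.class_names, dtype=object)[
                stack.land_cover[iy, ix]
            ]
        }
    )
    for name in CONTINUOUS_COVARIATES:
        frame[name] = stack.layers[name][iy, ix]

    if fit.kernel_mean is not None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 13])))
        pair = _draw_pairs(rng, fit.kernel_mean, fit.kernel_cov, 1)[0]
        dt_ref = 600.0
        step_length, angle = pair[0] * dt_ref, pair[1]
    else:
        step_length, angle = 0.0, 0.0

    eta = np.zeros(len(iy))
    for name, b in fit.betas.items():
        if name.startswith("land_cover["):
            lev = name[len("land_cover[") : -1]
            eta += b * (frame["land_cover"].astype(str) == lev).to_numpy(float)
        elif name == "step_length":
            eta += b * step_length
        elif name == "turning_angle":
            eta += b * angle
        else:
            eta += b * frame[name].to_numpy(dtype=float)

    lo, hi = eta.min(), eta.max()
    grid = np.full(geom.shape, np.nan)
    grid[iy, ix] = (eta - lo) / (hi - lo) if hi > lo else 0.5
    return grid


def validate_split(
    track: pd.DataFrame,
    stack: LandscapeStack,
    mask: np.ndarray | None = None,
    train_frac: float = 0.75,
    K: int = DEFAULT_K,
    seed: int = 0,
    covariates: tuple[str, ...] = ("land_cover",) + CONTINUOUS_COVARIATES,
) -> dict:
    """Chronological 75/25 split validation of the suitability model.

    Fits on the first ``train_frac`` of fixes, maps suitability, and compares
    its values at held-out observed locations against an equal number of
    uniform random in-home-range points (Welch two-sample t test).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    track = track.sort_values("timestamp").reset_index(drop=True)
    n_train = int(round(len(track) * train_frac))
    held = track.iloc[n_train:]
    if len(held) < 20:
        warnings.warn(f"only {len(held)} held-out locations")
    if len(held) == 0:
        raise ValueError("degenerate split: no held-out locations")

    steps = make_steps(track.iloc[:n_train])
    strata = draw_random_steps(steps, K=K, seed=seed)
    strata = attach_endpoint_covariates(strata, stack)
    fit = fit_conditional_logit(strata, covariates=covariates)
    geom = stack.geometry
    if mask is None:
        mask = np.ones(geom.shape, dtype=bool)
    suit = predict_suitability(fit, stack, mask=mask, seed=seed)

    xmin, xmax, ymin, ymax = geom.extent
    eps = geom.cell_size * 1e-6
    hx = np.clip(held["x"].to_numpy(), xmin + eps, xmax - eps)
    hy = np.clip(held["y"].to_numpy(), ymin + eps, ymax - eps)
    iy, ix = geom.world_to_cell(hx, hy)
    obs_vals = suit[iy, ix]
    obs_vals = obs_vals[np.isfinite(obs_vals)]

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 17])))
    my, mx = np.nonzero(mask & np.isfinite(suit))
    pick = rng.choice(len(my), size=len(obs_vals), replace=True)
    rand_vals = suit[my[pick], mx[pick]]

    tstat, pval = stats.ttest_ind(obs_vals, rand_vals, equal_var=False)
    return {
        "fit": fit,
        "suitability": suit,
        "n_heldout": int(len(obs_vals)),
        "observed_mean": float(np.mean(obs_vals)),
        "observed_sd": float(np.std(obs_vals, ddof=1)),
        "random_mean": float(np.mean(rand_vals)),
        "random_sd": float(np.std(rand_vals, ddof=1)),
        "t": float(tstat),
        "p": float(pval),
    }
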