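"""ODBA valleys and peaks: extraction, time budgets, and compositional tests.

Valleys (peaks) are the home-range cells at or below (above) the 5% (95%)
quantile of the predicted energy landscape, grouped into 8-connected
components.  Each hot spot carries its area, the summed utilization-
distribution probability (time share), and an environmental profile (means
of continuous covariates plus land-cover composition fractions).

Time budgets are compared with an ordinary least-squares model of time share
on hot-spot type, area and individual.  Environmental composition is
compared with a distance-based permutation MANOVA (McArdle-Anderson pseudo-F
on Euclidean distances of standardized profiles), permuting type labels
within individuals only (strata), 999 permutations by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import CONTINUOUS_COVARIATES, LandscapeStack

__all__ = [
    "Hotspot",
    "extract_hotspots",
    "hotspot_table",
    "compare_time_budget",
    "compositional_permutation_test",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class Hotspot:
    type: str  # "valley" | "peak"
    cells: tuple[np.ndarray, np.ndarray]  # (iy, ix) arrays
    area: float  # m^2
    time_share: float  # summed UD probability
    env_profile: dict[str, float]
    individual_id: str = ""


def extract_hotspots(
    prediction: np.ndarray,
    ud_probabilities: np.ndarray,
    mask: np.ndarray,
    stack: LandscapeStack,
    q: float = 0.05,
    individual_id: str = "",
) -> list[Hotspot]:
    """Connected components of extreme predicted-ODBA cells within the mask.

    Quantile ties are included on the hot-spot side.  A constant prediction
    surface has coinciding quantiles (every cell would be both valley and
    peak); that degenerate case warns and returns no hot spots.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    mask = np.asarray(mask, dtype=bool) & np.isfinite(prediction)
    if not mask.any():
        raise ValueError("empty home-range mask")
    vals = prediction[mask]
    lo = np.quantile(vals, q)
    hi = np.quantile(vals, 1.0 - q)
    if lo >= hi:
        warnings.warn("prediction quantiles coincide; no hot spots defined")
        return []
    out: list[Hotspot] = []
    cell_area = stack.geometry.cell_size**2
    for typ, sel in (
        ("valley", mask & (prediction <= lo)),
        ("peak", mask & (prediction >= hi)),
    ):
        labels, n_comp = ndimage.label(sel, structure=EIGHT_CONN)
        for c in range(1, n_comp + 1):
            iy, ix = np.nonzero(labels == c)
            profile: dict[str, float] = {}
            for name in CONTINUOUS_COVARIATES:
                profile[name] = float(np.nanmean(stack.layers[name][iy, ix]))
            codes = stack.land_cover[iy, ix]
            for code, cname in enumerate(stack.class_names):
                profile[f"frac_{cname}"] = float(np.mean(codes == code))
            out.append(
                Hotspot(
                    type=typ,
                    cells=(iy, ix),
                    area=float(len(iy) * cell_area),
                    time_share=float(ud_probabilities[iy, ix].sum()),
                    env_profile=profile,
                    individual_id=individual_id,
                )
            )
    return out


def hotspot_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = []
    for h in hotspots:
        row = {
            "individual_id": h.individual_id,
            "type": h.type,
            "area": h.area,
            "time_share": h.time_share,
            "n_cells": len(h.cells[0]),
        }
        row.update(h.env_profile)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_time_budget(hotspots: list[Hotspot]) -> pd.DataFrame:
    """OLS of time share on hot-spot type + area + individual.

    Returns the coefficient table; the ``type[valley]`` row estimates how
    much more UD time valleys hold than peaks at equal area.
    """
    import statsmodels.formula.api as smf

    tab = hotspot_table(hotspots)
    if tab["type"].nunique() < 2:
        raise ValueError("need both valley and peak hot spots")
    by_ind = tab.groupby("individual_id")["type"].nunique()
    if (by_ind >= 2).sum() < 2 and tab["individual_id"].nunique() > 1:
        warnings.warn("fewer than 2 individuals contribute both hot-spot types")
    tab = tab.copy()
    tab["is_valley"] = (tab["type"] == "valley").astype(float)
    formula = "time_share ~ is_valley + area"
    if tab["individual_id"].nunique() > 1:
        formula += " + C(individual_id)"
    fit = smf.ols(formula, data=tab).fit()
    out = pd.DataFrame(
        {
            "est": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    out.attrs["f"] = float(fit.fvalue)
    out.attrs["df"] = (int(fit.df_model), int(fit.df_resid))
    out.attrs["r2_adj"] = float(fit.rsquared_adj)
    return out


# -- distance-based permutation MANOVA ------------------------------------


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = len(d2)
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _pseudo_f(G: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray) -> tuple[float, int, int]:
    n = len(G)
    H1, H0 = _hat(X_full), _hat(X_reduced)
    df_num = int(round(np.trace(H1) - np.trace(H0)))
    df_den = int(round(n - np.trace(H1)))
    ss_num = np.trace((H1 - H0) @ G)
    ss_den = np.trace((np.eye(n) - H1) @ G)
    return float((ss_num / df_num) / (ss_den / df_den)), df_num, df_den


def compositional_permutation_test(
    hotspots: list[Hotspot],
    n_perm: int = 999,
    seed: int = 0,
    include_area: bool = True,
) -> dict:
    """Permutation MANOVA of environmental composition by hot-spot type.

    Euclidean distances on z-scored environmental profiles; the pseudo-F for
    the type partition (after an optional area covariate) is compared with
    its distribution under permutations of type labels restricted to within-
    individual exchanges.  p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    tab = hotspot_table(hotspots)
    for typ in ("valley", "peak"):
        if (tab["type"] == typ).sum() < 5:
            warnings.warn(f"fewer than 5 {typ} hot spots; test may lack power")
    prof_cols = [c for c in tab.columns if c in CONTINUOUS_COVARIATES or c.startswith("frac_")]
    P = tab[prof_cols].to_numpy(dtype=float)
    sd = P.std(axis=0)
    keep = sd > 0
    Z = (P[:, keep] - P[:, keep].mean(axis=0)) / sd[keep]
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    G = _gower_center(d2)

    n = len(tab)
    is_valley = (tab["type"] == "valley").to_numpy(float)
    area = tab["area"].to_numpy(float)
    area_z = (area - area.mean()) / (area.std() if area.std() > 0 else 1.0)
    ones = np.ones(n)

    def design(v):
        cols = [ones]
        if include_area:
            cols.append(area_z)
        red = np.column_stack(cols)
        return np.column_stack(cols + [v]), red

    X1, X0 = design(is_valley)
    f_obs, df_num, df_den = _pseudo_f(G, X1, X0)

    groups = tab["individual_id"].to_numpy()
    idx_by_group = {g: np.flatnonzero(groups == g) for g in pd.unique(groups)}
    for g, idx in idx_by_group.items():
        if len(idx) < 2:
            warnings.warn(f"individual {g!r} has one hot spot: no permutations within")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 23])))
    count = 0
    for _ in range(n_perm):
        perm = is_valley.copy()
        for idx in idx_by_group.values():
            perm[idx] = perm[rng.permutation(idx)]
        Xp, X0p = design(perm)
        f_p, _, _ = _pseudo_f(G, Xp, X0p)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {
        "pseudo_f": f_obs,
        "df": (df_num, df_den),
        "p": float(p),
        "n_perm": n_perm,
        "n_hotspots": n,
    }
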