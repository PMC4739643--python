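"""Spatial, spatio-temporal and environmental models of standardized ODBA.

Per individual, the cube root of standardized ODBA is modeled with a Gaussian
penalized-spline regression: a bivariate thin-plate smooth of position (basis
dimension 100), a cyclic cubic smooth of time of day (period 86 400 s, basis
dimension 10), and optional linear/categorical environmental terms.
Smoothing parameters are selected by REML with a double-penalty shrinkage so
terms can leave the model entirely.  Candidate environmental subsets (all
2^5 combinations of land cover, distance to forest edge, heterogeneity,
proportion urban, distance to roads on top of the fixed spatio-temporal base)
are ranked by AICc; models within 4 AICc of the best form the confidence set
over which Akaike-weighted averaged prediction surfaces are computed.
Mapped predictions marginalize time of day by excluding the (centered) cyclic
term, and are reported on the cube-root scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .landscape import CONTINUOUS_COVARIATES, LandscapeStack
from .rgam import GamFit, GamSpec, fit_gams

__all__ = [
    "ENV_VARIABLES",
    "aicc",
    "akaike_weights",
    "fit_energy_model",
    "CandidateSet",
    "fit_candidate_set",
    "select_and_average",
    "fit_covariate_gamm",
    "landscape_heterogeneity_stats",
    "build_model_frame",
    "cell_covariate_frame",
]

ENV_VARIABLES = ("land_cover",) + CONTINUOUS_COVARIATES

DAY_SECONDS = 86400.0
DELTA_AICC_CUTOFF = 4.0


# -- model frame construction ----------------------------------------------


def build_model_frame(records: pd.DataFrame, stack: LandscapeStack | None = None) -> pd.DataFrame:
    """Assemble the modeling frame: cube-root response, seconds-of-day, and
    (optionally) landscape covariates sampled at the joined fix locations."""
    out = records.copy()
    if "odba_std" not in out.columns:
        raise ValueError("records must carry standardized ODBA (odba_std)")
    out["odba_cr"] = np.cbrt(out["odba_std"].to_numpy(dtype=float))
    ts = pd.to_datetime(out["timestamp"])
    out["tod"] = (ts - ts.dt.normalize()).dt.total_seconds()
    if stack is not None:
        cov = stack.covariates_at(out["x"].to_numpy(), out["y"].to_numpy())
        for name, vals in cov.items():
            out[name] = vals
    return out


def cell_covariate_frame(stack: LandscapeStack, mask: np.ndarray) -> pd.DataFrame:
    """Covariate rows for every masked grid cell (time of day set to 0; the
    cyclic smooth is excluded from mapped predictions anyway)."""
    iy, ix = np.nonzero(mask)
    ys, xs = stack.geometry.cell_centers()
    frame = pd.DataFrame(
        {
            "x": xs[ix],
            "y": ys[iy],
            "tod": 0.0,
            "land_cover": np.asarray(stack.class_names, dtype=object)[
                stack.land_cover[iy, ix]
            ],
        }
    )
    for name in CONTINUOUS_COVARIATES:
        frame[name] = stack.layers[name][iy, ix]
    frame.attrs["cells"] = (iy, ix)
    return frame


# -- information criteria --------------------------------------------------


def aicc(fit: GamFit, n: int | None = None) -> float:
    """Small-sample corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1), with k
    the effective parameter count (total edf + scale)."""
    n = fit.n if n is None else n
    k = fit.k_effective
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1:.1f}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    delta = aicc_values - np.min(aicc_values)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# -- formula construction --------------------------------------------------


def _base_terms(k_space: int, k_time: int, include_time: bool) -> list[str]:
    terms = [f"s(x,y,bs='tp',k={k_space})"]
    if include_time:
        terms.append(f"s(tod,bs='cc',k={k_time})")
    return terms


def _usable_env_terms(records: pd.DataFrame, env_vars) -> list[str]:
    """Drop constant covariates (unidentifiable after centering) with a warning."""
    usable = []
    for v in env_vars:
        vals = records[v]
        if vals.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {v!r} is constant; dropped from the model")
        else:
            usable.append(v)
    return usable


def _formula(response: str, terms: list[str]) -> str:
    return f"{response} ~ " + " + ".join(terms)


def _align_prediction_factors(
    predict: pd.DataFrame | None, records: pd.DataFrame
) -> pd.DataFrame | None:
    """Map land-cover classes absent from the training data to the modal
    training class so mapped predictions stay defined everywhere."""
    if predict is None or "land_cover" not in predict.columns or "land_cover" not in records.columns:
        return predict
    seen = set(records["land_cover"].astype(str))
    unseen = ~predict["land_cover"].astype(str).isin(seen)
    if unseen.any():
        modal = records["land_cover"].astype(str).mode().iloc[0]
        warnings.warn(
            f"{int(unseen.sum())} prediction cells have land-cover classes unseen "
            f"in training; predicted at the modal class {modal!r}"
        )
        predict = predict.copy()
        predict.loc[unseen, "land_cover"] = modal
    return predict


def _factor_levels(records: pd.DataFrame) -> dict[str, list[str]]:
    factors = {}
    if "land_cover" in records.columns:
        factors["land_cover"] = sorted(records["land_cover"].astype(str).unique())
    return factors


def fit_energy_model(
    records: pd.DataFrame,
    env_vars: tuple[str, ...] = (),
    k_space: int = 100,
    k_time: int = 10,
    include_time: bool = True,
    predict: pd.DataFrame | None = None,
    marginalize_time: bool = True,
    seed: int = 1,
) -> GamFit:
    """Fit one penalized spatio-temporal(-environmental) ODBA model.

    An exactly constant response admits only the trivial intercept fit (the
    REML criterion is undefined at zero scale), which is returned directly
    with every smooth at zero effective df.
    """
    resp = records["odba_cr"].to_numpy(dtype=float)
    if np.ptp(resp) == 0:
        warnings.warn("constant response: returning the trivial intercept fit")
        return GamFit(
            name="m",
            formula="odba_cr ~ 1",
            n=len(records),
            loglik=np.nan,
            edf_total=0.0,
            r2_adj=0.0,
            scale=0.0,
            converged=True,
            coef=pd.DataFrame(
                {"est": [resp[0]], "se": [0.0], "t": [np.nan], "p": [np.nan]},
                index=["(Intercept)"],
            ),
            smooth_edf={"s(x,y)": 0.0, "s(tod)": 0.0},
            predictions=(
                np.full(len(predict), resp[0]) if predict is not None else None
            ),
        )
    env = _usable_env_terms(records, env_vars)
    predict = _align_prediction_factors(predict, records)
    terms = _base_terms(k_space, k_time, include_time) + list(env)
    spec = GamSpec(
        name="m",
        formula=_formula("odba_cr", terms),
        predict=predict is not None,
        exclude=(f"s(tod)",) if (include_time and marginalize_time) else (),
    )
    fits = fit_gams(
        records,
        [spec],
        predict=predict,
        factors=_factor_levels(records),
        knots={"tod": [0.0, DAY_SECONDS]} if include_time else None,
        seed=seed,
    )
    return fits["m"]


# -- candidate set ---------------------------------------------------------


@dataclass
class CandidateSet:
    """All environmental-subset fits for one individual, ranked by AICc."""

    fits: dict[str, GamFit]
    table: pd.DataFrame  # name, terms, edf, aicc, delta_aicc, weight, retained

    @property
    def retained(self) -> pd.DataFrame:
        return self.table.loc[self.table["retained"]]


def fit_candidate_set(
    records: pd.DataFrame,
    env_vars: tuple[str, ...] = ENV_VARIABLES,
    k_space: int = 100,
    k_time: int = 10,
    predict: pd.DataFrame | None = None,
    seed: int = 1,
) -> CandidateSet:
    """Fit every environmental subset on top of the spatio-temporal base."""
    env = _usable_env_terms(records, env_vars)
    predict = _align_prediction_factors(predict, records)
    base = _base_terms(k_space, k_time, include_time=True)
    specs = []
    subsets = []
    for r in range(len(env) + 1):
        for combo in combinations(env, r):
            name = "base" if not combo else "+".join(combo)
            subsets.append((name, combo))
            specs.append(
                GamSpec(
                    name=name,
                    formula=_formula("odba_cr", base + list(combo)),
                    predict=predict is not None,
                    exclude=("s(tod)",),
                )
            )
    fits = fit_gams(
        records,
        specs,
        predict=predict,
        factors=_factor_levels(records),
        knots={"tod": [0.0, DAY_SECONDS]},
        seed=seed,
    )
    rows = []
    for name, combo in subsets:
        f = fits[name]
        rows.append(
            {
                "name": name,
                "terms": ", ".join(combo) if combo else "(base)",
                "edf": f.edf_total,
                "aicc": aicc(f),
                "r2_adj": f.r2_adj,
            }
        )
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["retained"] = table["delta_aicc"] < DELTA_AICC_CUTOFF
    w = np.zeros(len(table))
    ret = table["retained"].to_numpy()
    w[ret] = akaike_weights(table.loc[ret, "aicc"].to_numpy())
    table["weight"] = w
    return CandidateSet(fits=fits, table=table)


def select_and_average(
    cands: CandidateSet, stack: LandscapeStack, mask: np.ndarray
) -> np.ndarray:
    """Akaike-weighted averaged prediction surface over masked cells.

    Requires the candidate set to have been fitted with ``predict`` set to
    the cell covariate frame for ``mask``.  Returns a grid (NaN outside the
    mask) on the cube-root ODBA scale.
    """
    iy, ix = np.nonzero(mask)
    grid = np.full(stack.geometry.shape, np.nan)
    avg = np.zeros(len(iy))
    for _, row in cands.retained.iterrows():
        f = cands.fits[row["name"]]
        if f.predictions is None:
            raise ValueError("candidate set was fitted without predictions")
        avg += row["weight"] * f.predictions
    grid[iy, ix] = avg
    return grid


# -- cross-individual GAMMs ------------------------------------------------


def fit_covariate_gamm(
    records: pd.DataFrame,
    covariate: str,
    k_space: int = 100,
    k_time: int = 10,
    seed: int = 1,
) -> tuple[GamFit, pd.Series]:
    """ODBA as a function of space, time and one covariate (UD value or
    habitat suitability) across individuals, with a per-individual random
    intercept.

    Returns the fit and the covariate's coefficient row (est, se, t, p).
    """
    if records["individual_id"].nunique() < 3:
        raise ValueError("need at least 3 individuals for the mixed model")
    if records[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    terms = _base_terms(k_space, k_time, include_time=True) + [
        covariate,
        "s(individual_id,bs='re')",
    ]
    factors = {"individual_id": sorted(records["individual_id"].astype(str).unique())}
    fits = fit_gams(
        records,
        [GamSpec(name="gamm", formula=_formula("odba_cr", terms))],
        factors=factors,
        knots={"tod": [0.0, DAY_SECONDS]},
        seed=seed,
    )
    fit = fits["gamm"]
    row = fit.coef.loc[covariate]
    return fit, row


def landscape_heterogeneity_stats(
    spatiotemporal_fits: dict[str, GamFit],
    prediction_surfaces: dict[str, np.ndarray],
    pct_urban: pd.Series,
) -> pd.DataFrame:
    """Per-individual energy-landscape heterogeneity vs urbanization.

    Heterogeneity measures: the adjusted R^2 of the spatio-temporal model and
    the spatial variance of its predicted surface; both are correlated
    (Pearson) with the proportion of urban area in the home range.
    """
    from scipy import stats

    ids = sorted(spatiotemporal_fits)
    if len(ids) < 3:
        raise ValueError("need at least 3 individuals")
    r2 = np.array([spatiotemporal_fits[i].r2_adj for i in ids])
    pvar = np.array(
        [float(np.nanvar(prediction_surfaces[i])) for i in ids]
    )
    urb = pct_urban.loc[ids].to_numpy(dtype=float)
    if urb.std() == 0:
        raise ValueError("zero variance in % urban across individuals")
    out = pd.DataFrame(
        {"individual_id": ids, "r2_adj": r2, "prediction_variance": pvar, "pct_urban": urb}
    )
    r1, p1 = stats.pearsonr(urb, r2)
    r2_, p2 = stats.pearsonr(urb, pvar)
    out.attrs["r_r2adj_vs_urban"] = (float(r1), float(p1))
    out.attrs["r_predvar_vs_urban"] = (float(r2_), float(p2))
    return out
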