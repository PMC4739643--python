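"""Subprocess bridge to the mgcv penalized-spline fitter.

All smooth-model fitting (thin-plate spatial smooths, cyclic time-of-day
smooths, random-effect smooths) runs through mgcv with REML smoothing-
parameter selection and double-penalty shrinkage (``select=TRUE``), which is
the reference implementation for this model class.  Jobs are batched: one R
process fits any number of models on a shared training frame, which keeps the
interpreter start-up cost constant per batch.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GamSpec", "GamFit", "fit_gams"]


@dataclass(frozen=True)
class GamSpec:
    """One model to fit: a name and an R model formula."""

    name: str
    formula: str
    predict: bool = False
    exclude: tuple[str, ...] = ()  # smooth labels excluded from predictions


@dataclass
class GamFit:
    """Fitted penalized regression: coefficients, effective df, fit stats."""

    name: str
    formula: str
    n: int
    loglik: float
    edf_total: float
    r2_adj: float
    scale: float
    converged: bool
    coef: pd.DataFrame  # parametric terms: est, se, t, p (index = term)
    smooth_edf: dict[str, float] = field(default_factory=dict)
    predictions: np.ndarray | None = None

    @property
    def k_effective(self) -> float:
        """Effective parameter count for AICc: total edf + 1 for the scale."""
        return self.edf_total + 1.0


def _rscript_path() -> Path:
    return Path(resources.files("energyscape") / "rscripts" / "fit_gam.R")


def fit_gams(
    train: pd.DataFrame,
    specs: list[GamSpec],
    predict: pd.DataFrame | None = None,
    factors: dict[str, list[str]] | None = None,
    knots: dict[str, list[float]] | None = None,
    seed: int = 1,
    timeout: float = 1800.0,
) -> dict[str, GamFit]:
    """Fit a batch of models with mgcv on a shared training frame.

    ``factors`` maps column names to their level order (first level is the
    reference); ``knots`` passes boundary knots (e.g. the 0/86400 s endpoints
    of the cyclic time-of-day smooth).
    """
    if not specs:
        raise ValueError("no model specs given")
    with tempfile.TemporaryDirectory(prefix="energyscape_gam_") as tmp:
        tmpd = Path(tmp)
        train.to_csv(tmpd / "train.csv", index=False)
        if predict is not None:
            predict.to_csv(tmpd / "predict.csv", index=False)
        jobs = {
            "seed": int(seed),
            "factors": factors or {},
            "knots": knots or {},
            "models": [
                {
                    "name": s.name,
                    "formula": s.formula,
                    "predict": bool(s.predict and predict is not None),
                    "exclude": list(s.exclude) or None,
                }
                for s in specs
            ],
        }
        (tmpd / "jobs.json").write_text(json.dumps(jobs))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_rscript_path()), str(tmpd)],
            capture_output=True,
            text=True,
            timeout=timeout,
            env=_r_env(),
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"mgcv fit failed (exit {proc.returncode}):\n{proc.stderr[-4000:]}"
            )
        results = json.loads((tmpd / "result.json").read_text())

    fits: dict[str, GamFit] = {}
    for s in specs:
        r = results[s.name]
        coef_raw = r["coef"]
        names = coef_raw["names"] if isinstance(coef_raw["names"], list) else [coef_raw["names"]]
        coef = pd.DataFrame(
            {
                "est": np.atleast_1d(coef_raw["est"]),
                "se": np.atleast_1d(coef_raw["se"]),
                "t": np.atleast_1d(coef_raw["t"]),
                "p": np.atleast_1d(coef_raw["p"]),
            },
            index=names,
        )
        fits[s.name] = GamFit(
            name=s.name,
            formula=s.formula,
            n=int(r["n"]),
            loglik=float(r["loglik"]),
            edf_total=float(r["edf_total"]),
            r2_adj=float(r["r2_adj"]),
            scale=float(r["scale"]),
            converged=bool(r["converged"]),
            coef=coef,
            smooth_edf={k: float(v) for k, v in (r.get("smooth_edf") or {}).items()},
            predictions=(
                np.asarray(r["predictions"], dtype=float)
                if r.get("predictions") is not None
                else None
            ),
        )
    return fits


def _r_env() -> dict[str, str]:
    import os

    env = dict(os.environ)
    # deterministic, single-threaded linear algebra
    env.setdefault("OMP_NUM_THREADS", "1")
    env.setdefault("OPENBLAS_NUM_THREADS", "1")
    return env
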