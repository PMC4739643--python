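"""Staged pipeline: simulate -> ODBA -> tracks -> UD -> energy -> SSF ->
hot spots -> report.

Each stage reads its inputs from, and writes its artifacts to, a single run
directory, so stages can be executed individually (the CLI exposes them as
subcommands) or chained by :func:`run_pipeline`, which also writes a manifest
(package version, configuration, seeds, per-stage record counts) sufficient
to reproduce the run.  Given the same configuration and seed a rerun is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acceleration import (
    AccBurst,
    join_bursts_to_fixes,
    odba,
    read_burst_csv,
    standardize,
    write_burst_csv,
)
from .dbbmm import UDRaster, build_ud, estimate_motion_variance, ud_at, ud_contour
from .energy import (
    build_model_frame,
    cell_covariate_frame,
    fit_candidate_set,
    fit_covariate_gamm,
    fit_energy_model,
    landscape_heterogeneity_stats,
    select_and_average,
)
from .geometry import read_ascii_grid, write_ascii_grid
from .hotspots import (
    compare_time_budget,
    compositional_permutation_test,
    extract_hotspots,
    hotspot_table,
)
from .landscape import pct_urban_in_homerange, read_landscape, write_landscape
from .ssf import (
    attach_endpoint_covariates,
    draw_random_steps,
    fit_conditional_logit,
    make_steps,
    predict_suitability,
    validate_split,
)
from .synthetic import (
    SimConfig,
    generate_landscape,
    read_track_csv,
    simulate_population,
    write_track_csv,
)
from .tracks import (
    activity_metrics,
    activity_score,
    detect_rest_bouts,
    label_records,
    regularize,
    trim_deployment,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """Flat configuration for a full run; YAML-serializable."""

    seed: int = 1
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    # acceleration / tracks
    max_gap: float = 60.0
    trim_hours: float = 48.0
    rest_min_duration: float = 4 * 3600.0
    rest_threshold: str = "otsu"
    day_window: tuple[int, int] = (6 * 3600, 18 * 3600)

    # dBBMM
    dbbmm_window: int = 31
    dbbmm_margin: int = 11
    dbbmm_loc_error: float = 20.0
    dbbmm_time_step: float = 60.0
    ud_level: float = 0.95

    # energy models
    k_space: int = 100
    k_time: int = 10
    env_vars: tuple[str, ...] = (
        "land_cover",
        "dist_forest_edge",
        "heterogeneity",
        "prop_urban_240",
        "dist_roads",
    )

    # SSF
    ssf_K: int = 5
    train_frac: float = 0.75

    # hot spots
    hotspot_q: float = 0.05
    n_perm: int = 999

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.env_vars = tuple(cfg.env_vars)
        cfg.day_window = tuple(cfg.day_window)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["env_vars"] = list(self.env_vars)
        d["day_window"] = list(self.day_window)
        return d

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _read_grid(path):
    grid, _ = read_ascii_grid(path)
    return grid


def _manifest_update(outdir: Path, stage: str, info: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = info
    path.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")


# -- stages ----------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = cfg.sim_config()
    land, truth = generate_landscape(sim)
    tracks, bursts, burst_truth = simulate_population(sim, land, truth)
    write_landscape(outdir / "landscape", land)
    tdir = outdir / "truth"
    tdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(tdir / "true_odba_surface.asc", truth.true_odba_surface, land.geometry)
    write_ascii_grid(
        tdir / "true_suitability.asc", truth.true_suitability_surface, land.geometry
    )
    (tdir / "rest_intervals.json").write_text(
        json.dumps(
            {
                k: [[s.isoformat(), e.isoformat()] for s, e in v]
                for k, v in sorted(truth.true_rest_intervals.items())
            },
            sort_keys=True,
        )
        + "\n"
    )
    write_track_csv(outdir / "tracks.csv", tracks)
    all_bursts = [b for ind in sorted(bursts) for b in bursts[ind]]
    write_burst_csv(outdir / "bursts.csv", all_bursts)
    bt = burst_truth.copy()
    bt["timestamp"] = bt["timestamp"].map(lambda t: t.isoformat())
    bt.to_csv(outdir / "truth" / "burst_truth.csv", index=False)
    return {"n_fixes": int(len(tracks)), "n_bursts": int(len(all_bursts))}


def stage_odba(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = cfg.sim_config()
    bursts = read_burst_csv(outdir / "bursts.csv", calib=sim.calib)
    rows = [
        {
            "individual_id": b.individual_id,
            "timestamp": b.timestamp.isoformat(),
            "odba": odba(b),
            "score": activity_score(b),
        }
        for b in bursts
    ]
    pd.DataFrame(rows).to_csv(outdir / "odba.csv", index=False)
    return {"n_bursts": len(rows)}


def stage_tracks(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = cfg.sim_config()
    tracks = read_track_csv(outdir / "tracks.csv")
    odba_df = pd.read_csv(outdir / "odba.csv")
    odba_df["timestamp"] = pd.to_datetime(odba_df["timestamp"], format="ISO8601")

    recs, regs, bout_rows, metric_rows = [], [], [], []
    for ind, otr in odba_df.groupby("individual_id", sort=True):
        otr = otr.sort_values("timestamp").reset_index(drop=True)
        bouts = detect_rest_bouts(
            otr,
            otr["score"].to_numpy(),
            day_window=cfg.day_window,
            min_duration=cfg.rest_min_duration,
            threshold=cfg.rest_threshold,
            burst_period=sim.burst_period,
        )
        tr = tracks.loc[tracks["individual_id"] == ind].reset_index(drop=True)
        t0 = min(tr["timestamp"].min(), otr["timestamp"].min())
        labeled = label_records(otr, bouts)
        labeled = trim_deployment(labeled, cfg.trim_hours, start=t0)
        tr_trim = trim_deployment(tr, cfg.trim_hours, start=t0)
        reg = regularize(tr_trim)
        regs.append(reg)

        active = labeled.loc[labeled["activity"] == "active"].reset_index(drop=True)
        active = standardize(active)
        joined = join_bursts_to_fixes(active, tr_trim, max_gap=cfg.max_gap)
        recs.append(joined)

        for b in bouts:
            bout_rows.append(
                {
                    "individual_id": ind,
                    "start": b.start.isoformat(),
                    "end": b.end.isoformat(),
                    "state": b.state,
                    "duration": b.duration,
                }
            )
        met = activity_metrics(reg, bouts, day_boundary=sim.activity_day_boundary)
        met.insert(0, "individual_id", ind)
        metric_rows.append(met)

    records = pd.concat(recs, ignore_index=True)
    records["timestamp"] = records["timestamp"].map(lambda t: t.isoformat())
    records.to_csv(outdir / "records.csv", index=False)
    reg_all = pd.concat(regs, ignore_index=True)
    write_track_csv(outdir / "tracks_regularized.csv", reg_all)
    pd.DataFrame(bout_rows).to_csv(outdir / "bouts.csv", index=False)
    metrics = pd.concat(metric_rows, ignore_index=True)
    metrics["day"] = metrics["day"].map(lambda t: t.isoformat())
    metrics.to_csv(outdir / "daily_metrics.csv", index=False)
    return {"n_active_records": int(len(records)), "n_regularized_fixes": int(len(reg_all))}


def stage_ud(cfg: PipelineConfig, outdir: Path) -> dict:
    land = read_landscape(outdir / "landscape")
    reg = read_track_csv(outdir / "tracks_regularized.csv")
    uddir = outdir / "ud"
    uddir.mkdir(parents=True, exist_ok=True)
    info = {}
    for ind, tr in reg.groupby("individual_id", sort=True):
        s2 = estimate_motion_variance(
            tr,
            window=cfg.dbbmm_window,
            margin=cfg.dbbmm_margin,
            loc_error=cfg.dbbmm_loc_error,
        )
        ud = build_ud(
            tr,
            s2,
            geometry=land.geometry,
            time_step=cfg.dbbmm_time_step,
            loc_error=cfg.dbbmm_loc_error,
        )
        mask = ud_contour(ud, cfg.ud_level)
        write_ascii_grid(uddir / f"{ind}_ud.asc", ud.probabilities, land.geometry)
        write_ascii_grid(uddir / f"{ind}_mask.asc", mask.astype(float), land.geometry)
        pd.DataFrame({"sigma2_m": s2}).to_csv(uddir / f"{ind}_sigma2.csv", index=False)
        info[ind] = {
            "median_sigma2": float(np.median(s2)),
            "n_hr_cells": int(mask.sum()),
            "pct_urban": pct_urban_in_homerange(land, mask),
        }
    (uddir / "summary.json").write_text(json.dumps(info, sort_keys=True) + "\n")
    return {"individuals": len(info)}


def _load_records(outdir: Path, land) -> pd.DataFrame:
    records = pd.read_csv(outdir / "records.csv")
    records["timestamp"] = pd.to_datetime(records["timestamp"], format="ISO8601")
    return build_model_frame(records, land)


def stage_energy(cfg: PipelineConfig, outdir: Path) -> dict:
    land = read_landscape(outdir / "landscape")
    frame = _load_records(outdir, land)
    edir = outdir / "energy"
    edir.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for ind, rec in frame.groupby("individual_id", sort=True):
        rec = rec.reset_index(drop=True)
        mask = _read_grid(outdir / "ud" / f"{ind}_mask.asc").astype(bool)
        cells = cell_covariate_frame(land, mask)
        spatial = fit_energy_model(
            rec, k_space=cfg.k_space, k_time=cfg.k_time, include_time=False, seed=cfg.seed
        )
        st = fit_energy_model(
            rec, k_space=cfg.k_space, k_time=cfg.k_time, predict=cells, seed=cfg.seed
        )
        cands = fit_candidate_set(
            rec,
            env_vars=cfg.env_vars,
            k_space=cfg.k_space,
            k_time=cfg.k_time,
            predict=cells,
            seed=cfg.seed,
        )
        pred = select_and_average(cands, land, mask)
        st_grid = np.full(land.geometry.shape, np.nan)
        st_grid[np.nonzero(mask)] = st.predictions
        write_ascii_grid(edir / f"{ind}_prediction.asc", pred, land.geometry)
        write_ascii_grid(edir / f"{ind}_prediction_st.asc", st_grid, land.geometry)
        tab = cands.table.copy()
        tab.insert(0, "individual_id", ind)
        tab.to_csv(edir / f"{ind}_model_table.csv", index=False)
        summary_rows.append(
            {
                "individual_id": ind,
                "r2_spatial": spatial.r2_adj,
                "r2_spatiotemporal": st.r2_adj,
                "r2_best_env": float(cands.table["r2_adj"].iloc[0]),
                "n_retained": int(cands.table["retained"].sum()),
                "prediction_variance": float(np.nanvar(st_grid)),
            }
        )
    pd.DataFrame(summary_rows).to_csv(edir / "gam_summary.csv", index=False)
    return {"individuals": len(summary_rows)}


def stage_ssf(cfg: PipelineConfig, outdir: Path) -> dict:
    land = read_landscape(outdir / "landscape")
    reg = read_track_csv(outdir / "tracks_regularized.csv")
    sdir = outdir / "ssf"
    sdir.mkdir(parents=True, exist_ok=True)
    beta_rows, val_rows = [], []
    for ind, tr in reg.groupby("individual_id", sort=True):
        active = tr.loc[tr["activity"] == "active"].reset_index(drop=True)
        mask = _read_grid(outdir / "ud" / f"{ind}_mask.asc").astype(bool)
        steps = make_steps(active)
        strata = draw_random_steps(steps, K=cfg.ssf_K, seed=cfg.seed)
        strata = attach_endpoint_covariates(strata, land)
        fit = fit_conditional_logit(strata)
        suit = predict_suitability(fit, land, mask=mask, seed=cfg.seed)
        write_ascii_grid(sdir / f"{ind}_suitability.asc", suit, land.geometry)
        for name in fit.betas.index:
            beta_rows.append(
                {
                    "individual_id": ind,
                    "term": name,
                    "beta": float(fit.betas[name]),
                    "se": float(fit.ses[name]),
                    "reference_class": fit.reference_class,
                }
            )
        val = validate_split(
            active,
            land,
            mask=mask,
            train_frac=cfg.train_frac,
            K=cfg.ssf_K,
            seed=cfg.seed,
        )
        val_rows.append(
            {
                "individual_id": ind,
                **{
                    k: val[k]
                    for k in (
                        "n_heldout",
                        "observed_mean",
                        "observed_sd",
                        "random_mean",
                        "random_sd",
                        "t",
                        "p",
                    )
                },
            }
        )
    pd.DataFrame(beta_rows).to_csv(sdir / "ssf_fits.csv", index=False)
    pd.DataFrame(val_rows).to_csv(sdir / "validation.csv", index=False)
    return {"individuals": len(val_rows)}


def stage_gamm(cfg: PipelineConfig, outdir: Path) -> dict:
    land = read_landscape(outdir / "landscape")
    frame = _load_records(outdir, land)
    gdir = outdir / "gamm"
    gdir.mkdir(parents=True, exist_ok=True)
    # per-record UD and suitability covariates
    parts = []
    for ind, rec in frame.groupby("individual_id", sort=True):
        ud = _read_grid(outdir / "ud" / f"{ind}_ud.asc")
        suit = _read_grid(outdir / "ssf" / f"{ind}_suitability.asc")
        iy, ix = land.geometry.world_to_cell(rec["x"].to_numpy(), rec["y"].to_numpy())
        rec = rec.copy()
        rec["ud"] = ud[iy, ix]
        rec["suitability"] = suit[iy, ix]
        parts.append(rec)
    allrec = pd.concat(parts, ignore_index=True)
    allrec = allrec.dropna(subset=["ud", "suitability"]).reset_index(drop=True)
    out = {}
    for cov in ("ud", "suitability"):
        fit, row = fit_covariate_gamm(
            allrec, cov, k_space=cfg.k_space, k_time=cfg.k_time, seed=cfg.seed
        )
        out[cov] = {
            "estimate": float(row["est"]),
            "se": float(row["se"]),
            "t": float(row["t"]),
            "p": float(row["p"]),
            "r2_adj": fit.r2_adj,
            "n": fit.n,
        }
    (gdir / "gamm.json").write_text(json.dumps(out, sort_keys=True, indent=1) + "\n")
    return {"n_records": int(len(allrec))}


def stage_hotspots(cfg: PipelineConfig, outdir: Path) -> dict:
    land = read_landscape(outdir / "landscape")
    hdir = outdir / "hotspots"
    hdir.mkdir(parents=True, exist_ok=True)
    hotspots = []
    inds = sorted(
        p.name.split("_prediction.asc")[0]
        for p in (outdir / "energy").glob("*_prediction.asc")
    )
    for ind in inds:
        pred = _read_grid(outdir / "energy" / f"{ind}_prediction.asc")
        ud = _read_grid(outdir / "ud" / f"{ind}_ud.asc")
        mask = _read_grid(outdir / "ud" / f"{ind}_mask.asc").astype(bool)
        hotspots.extend(
            extract_hotspots(pred, ud, mask, land, q=cfg.hotspot_q, individual_id=ind)
        )
    tab = hotspot_table(hotspots)
    tab.to_csv(hdir / "hotspots.csv", index=False)
    results: dict = {"n_hotspots": int(len(tab))}
    if len(tab) and tab["type"].nunique() == 2:
        tb = compare_time_budget(hotspots)
        results["time_budget"] = {
            "valley_coef": float(tb.loc["is_valley", "est"]),
            "valley_se": float(tb.loc["is_valley", "se"]),
            "valley_t": float(tb.loc["is_valley", "t"]),
            "valley_p": float(tb.loc["is_valley", "p"]),
            "f": tb.attrs["f"],
        }
        perm = compositional_permutation_test(hotspots, n_perm=cfg.n_perm, seed=cfg.seed)
        results["composition"] = {
            "pseudo_f": perm["pseudo_f"],
            "p": perm["p"],
            "n_perm": perm["n_perm"],
        }
    (hdir / "tests.json").write_text(json.dumps(results, sort_keys=True, indent=1) + "\n")
    return {"n_hotspots": int(len(tab))}


def stage_report(cfg: PipelineConfig, outdir: Path) -> dict:
    from scipy import stats

    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    ud_info = json.loads((outdir / "ud" / "summary.json").read_text())
    pct_urban = pd.Series({k: v["pct_urban"] for k, v in ud_info.items()})

    metrics = pd.read_csv(outdir / "daily_metrics.csv")
    per_ind = metrics.groupby("individual_id").agg(
        n_active_bouts=("n_active_bouts", "mean"),
        mean_bout_duration=("mean_bout_duration", "mean"),
        cumulative_distance=("cumulative_distance", "mean"),
    )
    from .tracks import urbanization_correlations

    corr = urbanization_correlations(per_ind, pct_urban)
    corr.to_csv(rdir / "activity_urbanization.csv", index=False)

    gam_summary = pd.read_csv(outdir / "energy" / "gam_summary.csv").set_index(
        "individual_id"
    )
    urb = pct_urban.loc[gam_summary.index].to_numpy(dtype=float)
    het_rows = []
    for col in ("r2_spatiotemporal", "prediction_variance"):
        r, p = stats.pearsonr(urb, gam_summary[col].to_numpy(dtype=float))
        het_rows.append({"measure": col, "pearson_r": r, "p": p})
    pd.DataFrame(het_rows).to_csv(rdir / "heterogeneity_urbanization.csv", index=False)
    return {"individuals": int(len(per_ind))}


STAGES = {
    "simulate": stage_simulate,
    "odba": stage_odba,
    "tracks": stage_tracks,
    "ud": stage_ud,
    "energy": stage_energy,
    "ssf": stage_ssf,
    "gamm": stage_gamm,
    "hotspots": stage_hotspots,
    "report": stage_report,
}


def run_pipeline(
    cfg: PipelineConfig, outdir, stages: list[str] | None = None
) -> dict:
    """Run the requested stages (default: all, in order) and write the
    manifest.  Any stage failure raises with the stage name attached."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_info = {
        "package": "energyscape",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    path = outdir / "manifest.json"
    existing = json.loads(path.read_text()) if path.exists() else {}
    existing.update(manifest_info)
    existing.setdefault("stages", {})
    path.write_text(json.dumps(existing, sort_keys=True, indent=1) + "\n")

    results = {}
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        try:
            info = STAGES[name](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        results[name] = info
        _manifest_update(outdir, name, info)
    return results
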