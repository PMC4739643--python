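"""Synthetic landscapes, movement tracks and raw accelerometer bursts.

The generator emulates the study conditions of a biologging deployment on a
nocturnal, forest-associated mesocarnivore along an urbanization gradient:

* a patchy categorical landscape (two developed classes, two forest classes,
  open classes, plus roads) whose developed fraction is controlled;
* individuals occupying home ranges spread along the urbanization gradient,
  moving as a habitat-biased correlated random walk (candidate headings
  weighted by exp(strength * suitability), plus a weak home-center pull);
* one diurnal resting bout per day (> 4 h) with near-zero dynamic
  acceleration, and active behavior otherwise;
* GPS fixes on either a fixed schedule or a dynamic activity-keyed schedule
  (2 / 10 / 60 min for high / moderate / resting activity);
* tri-axial bursts of raw integer counts every ``burst_period`` whose dynamic
  amplitude encodes an intended ODBA that is a monotone function of the local
  "true" ODBA surface, produced by inverting the calibration equation so that
  downstream decoding round-trips within quantization error.

Every stochastic piece derives from ``SimConfig.seed`` via
``numpy.random.SeedSequence`` so reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .acceleration import AccBurst, CalibrationParams
from .geometry import GridGeometry
from .landscape import CONTINUOUS_COVARIATES, LandscapeStack, derive_layers

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_landscape",
    "simulate_individual",
    "simulate_population",
    "simulate_ssf_track",
    "write_track_csv",
    "read_track_csv",
]

T0 = pd.Timestamp("2021-03-01 00:00:00+00:00")  # deployment epoch

CLASS_NAMES = [
    "developed_high",
    "developed_low",
    "deciduous_forest",
    "coniferous_forest",
    "grassland",
    "wetland",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Defaults mirror the emulated deployment: 12 individuals tracked ~20 days,
    30 m landscape cells, bursts of 54 samples (nominal 18.74 Hz for 3.5 s)
    every 3 minutes, and a dynamic 2/10/60-min GPS schedule keyed to activity.
    """

    seed: int = 0
    n_individuals: int = 12
    duration_days: float = 20.0
    grid_size: int = 128
    cell_size: float = 30.0
    urban_fraction_range: tuple[float, float] = (0.2, 0.3)
    activity_day_boundary: int = 64800  # seconds-of-day; stands in for sunset
    odba_env_effect: dict[str, float] = field(
        default_factory=lambda: {
            "dist_forest_edge": -0.4,
            "prop_urban_240": 0.9,
            "heterogeneity": 0.2,
            "dist_roads": -0.2,
        }
    )
    speed_regimes: dict[str, float] = field(
        default_factory=lambda: {"rest": 0.0, "moderate": 0.4, "high": 1.2}
    )
    burst_hz: float = 18.74
    burst_seconds: float = 3.5
    burst_period: float = 180.0
    burst_samples: int = 54  # the analyzed unit; hz/seconds kept as metadata

    # schedule: "dynamic", "fixed10", "fixed15", or "mixed" (alternating
    # dynamic / fixed10 across individuals, one fixed15 when n >= 6)
    schedule: str = "mixed"

    # behavior
    rest_start_s: int = 9 * 3600  # daily rest onset (seconds of day)
    rest_duration_s: int = int(6.5 * 3600)  # > 4 h, diurnal
    state_persistence: float = 0.97  # per-minute prob of keeping active sub-state
    ssf_strength: float = 3.0  # habitat bias on suitability in candidate choice
    home_scale_m: float = 700.0  # home-pull length scale
    turn_sd_rad: float = 0.6
    n_candidates: int = 7
    gps_error_m: float = 0.0

    # ODBA emission
    rest_odba: float = 0.0  # m/s^2; resting bursts are motionless
    active_odba_base: float = 2.0  # m/s^2
    odba_gain: float = 0.8  # log-scale gain of the environmental surface
    odba_noise_sd: float = 0.25  # lognormal sd of burst-level noise
    state_odba_factor: dict[str, float] = field(
        default_factory=lambda: {"moderate": 0.8, "high": 1.25}
    )
    calib: CalibrationParams = field(default_factory=CalibrationParams)

    def __post_init__(self) -> None:
        lo, hi = self.urban_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("urban_fraction_range must be ordered within [0, 1]")
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32 to host landscape patches")
        if self.burst_hz * self.burst_seconds < 2:
            raise ValueError("a burst must span at least 2 samples")
        if self.burst_samples < 2:
            raise ValueError("burst_samples must be >= 2")
        if self.schedule not in {"dynamic", "fixed10", "fixed15", "mixed"}:
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class GroundTruth:
    """Recoverable targets for every downstream stage."""

    true_odba_surface: np.ndarray  # expected standardized ODBA in [0, 1]
    true_suitability_surface: np.ndarray  # in [0, 1]
    true_env_betas: dict[str, float]
    true_rest_intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = field(
        default_factory=dict
    )


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.min()) / (f.max() - f.min() + 1e-300)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def _minmax(a: np.ndarray) -> np.ndarray:
    rng_ = a.max() - a.min()
    if rng_ <= 0:
        return np.full_like(a, 0.5)
    return (a - a.min()) / rng_


def generate_landscape(cfg: SimConfig) -> tuple[LandscapeStack, GroundTruth]:
    """Patchy categorical landscape + roads, derived layers, and ground truth.

    Urbanization follows a smooth west-to-east gradient so that individuals
    placed along x experience different proportions of urban area, as in the
    emulated study population.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, 0])))
    n = cfg.grid_size
    geom = GridGeometry(x0=0.0, y0=0.0, cell_size=cfg.cell_size, nx=n, ny=n)

    gradient = np.tile(np.linspace(0.0, 1.0, n), (n, 1))
    urban_field = 0.55 * gradient + 0.45 * _smooth_noise(rng, (n, n), sigma=n / 14)
    lo, hi = cfg.urban_fraction_range
    f_urban = float(rng.uniform(lo, hi))

    land = np.full((n, n), -1, dtype=int)
    if f_urban > 0:
        thr = np.quantile(urban_field, 1.0 - f_urban)
        dev = urban_field >= thr
        dev_hi = urban_field >= np.quantile(urban_field[dev], 0.6) if dev.any() else dev
        land[dev & dev_hi] = CLASS_NAMES.index("developed_high")
        land[dev & ~dev_hi] = CLASS_NAMES.index("developed_low")

    natural = land < 0
    nat_field = _smooth_noise(rng, (n, n), sigma=n / 18)
    vals = nat_field[natural]
    q = np.quantile(vals, [0.45, 0.65, 0.9])
    codes = np.select(
        [nat_field < q[0], nat_field < q[1], nat_field < q[2]],
        [
            CLASS_NAMES.index("deciduous_forest"),
            CLASS_NAMES.index("coniferous_forest"),
            CLASS_NAMES.index("grassland"),
        ],
        default=CLASS_NAMES.index("wetland"),
    )
    land[natural] = codes[natural]

    roads = np.zeros((n, n), dtype=bool)
    if f_urban > 0:
        k_roads = 1 + int(round(6 * f_urban))
        col_w = urban_field.mean(axis=0)
        col_w = col_w / col_w.sum()
        row_w = urban_field.mean(axis=1)
        row_w = row_w / row_w.sum()
        for j in range(k_roads):
            if j % 2 == 0:
                c = int(rng.choice(n, p=col_w))
                roads[:, c] = True
            else:
                r = int(rng.choice(n, p=row_w))
                roads[r, :] = True

    stack = LandscapeStack(geometry=geom, land_cover=land, class_names=list(CLASS_NAMES), roads=roads)
    derive_layers(stack)

    betas = dict(cfg.odba_env_effect)
    eta = np.zeros((n, n))
    for name in CONTINUOUS_COVARIATES:
        layer = stack.layers[name]
        if np.isnan(layer).all():
            continue
        eta += betas.get(name, 0.0) * _zscore(np.nan_to_num(layer))
    true_odba_surface = _minmax(eta)

    eta_s = 1.5 * stack.forest_mask.astype(float) - 1.0 * _zscore(
        stack.layers["prop_urban_240"]
    )
    true_suitability_surface = _minmax(ndimage.gaussian_filter(eta_s, 1.0))

    truth = GroundTruth(
        true_odba_surface=true_odba_surface,
        true_suitability_surface=true_suitability_surface,
        true_env_betas=betas,
    )
    return stack, truth


# -- burst encoding --------------------------------------------------------


def encode_burst(
    target_odba: float,
    n_samples: int,
    calib: CalibrationParams,
    gravity_axis: int = 2,
) -> np.ndarray:
    """Raw integer counts whose decoded ODBA equals ``target_odba`` up to
    quantization.

    Each axis carries an alternating +/-A square wave with A = target/3 (so
    the per-axis mean absolute deviation is exactly target/3); the z axis
    additionally carries the static 1-g offset.  Counts invert the
    calibration equation a = (n - zero_g) * c * g.
    """
    amp = target_odba / 3.0
    sign = np.where(np.arange(n_samples) % 2 == 0, 1.0, -1.0)
    a = np.empty((n_samples, 3))
    a[:, 0] = amp * sign
    a[:, 1] = -amp * sign
    a[:, 2] = amp * sign
    a[:, gravity_axis] += calib.gravity
    counts = np.rint(a / (calib.slope * calib.gravity) + calib.zero_g)
    return counts.astype(np.int64)


# -- individual simulation -------------------------------------------------


def _schedule_for(cfg: SimConfig, index: int) -> str:
    if cfg.schedule != "mixed":
        return cfg.schedule
    if cfg.n_individuals >= 6 and index == cfg.n_individuals - 1:
        return "fixed15"
    return "dynamic" if index % 2 == 0 else "fixed10"


_FIX_INTERVAL_MIN = {"high": 2, "moderate": 10, "rest": 60}


def simulate_individual(
    cfg: SimConfig,
    land: LandscapeStack,
    truth: GroundTruth,
    index: int,
) -> tuple[pd.DataFrame, list[AccBurst], pd.DataFrame]:
    """Simulate one individual.

    Returns (track, bursts, burst_truth): the GPS track as a Movebank-style
    frame, the raw bursts, and a per-burst table of the intended (pre-
    quantization) ODBA and behavioral state.
    """
    individual_id = f"S{index + 1:02d}"
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([cfg.seed, 1, index]))
    )
    geom = land.geometry
    xmin, xmax, ymin, ymax = geom.extent
    pad = 6 * geom.cell_size
    # home centers spread along the urbanization (x) gradient
    frac = (index + 0.5) / cfg.n_individuals
    home = np.array(
        [
            xmin + pad + frac * (xmax - xmin - 2 * pad),
            0.5 * (ymin + ymax) + rng.normal(0, (ymax - ymin) / 10),
        ]
    )
    home[1] = np.clip(home[1], ymin + pad, ymax - pad)

    n_min = int(round(cfg.duration_days * 1440))
    rest_onset = cfg.rest_start_s + int(rng.integers(-1800, 1801))
    rest_intervals = []
    for d in range(int(math.ceil(cfg.duration_days)) + 1):
        s = T0 + pd.Timedelta(days=d, seconds=rest_onset)
        e = s + pd.Timedelta(seconds=cfg.rest_duration_s)
        if s < T0 + pd.Timedelta(minutes=n_min):
            rest_intervals.append((s, e))
    truth.true_rest_intervals[individual_id] = rest_intervals

    sched = _schedule_for(cfg, index)
    suit = truth.true_suitability_surface
    surf = truth.true_odba_surface
    speeds = cfg.speed_regimes

    pos = home.copy()
    heading = rng.uniform(-np.pi, np.pi)
    sub_state = "moderate"

    fix_rows = []
    bursts: list[AccBurst] = []
    truth_rows = []
    minutes_since_fix = 10**9

    for m in range(n_min):
        t = T0 + pd.Timedelta(minutes=m)
        in_rest = any(s <= t < e for s, e in rest_intervals)
        if in_rest:
            state = "rest"
        else:
            if rng.uniform() > cfg.state_persistence:
                sub_state = "high" if sub_state == "moderate" else "moderate"
            state = sub_state

        # movement over this minute
        speed = speeds[state] * (math.exp(rng.normal(0, 0.3)) if speeds[state] > 0 else 0.0)
        if speed > 0:
            step = speed * 60.0
            turns = rng.normal(0.0, cfg.turn_sd_rad, cfg.n_candidates)
            cand_h = heading + turns
            cx = pos[0] + step * np.cos(cand_h)
            cy = pos[1] + step * np.sin(cand_h)
            inside = geom.contains(cx, cy)
            w = np.zeros(cfg.n_candidates)
            if inside.any():
                iy, ix = geom.world_to_cell(cx[inside], cy[inside])
                s_val = suit[iy, ix]
                d_home = np.hypot(cx[inside] - home[0], cy[inside] - home[1])
                logw = cfg.ssf_strength * s_val - d_home / cfg.home_scale_m
                w[inside] = np.exp(logw - logw.max())
            if w.sum() <= 0:
                heading = math.atan2(home[1] - pos[1], home[0] - pos[0])
                pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
            else:
                k = rng.choice(cfg.n_candidates, p=w / w.sum())
                heading = float(cand_h[k])
                pos = np.array([cx[k], cy[k]])
            pos[0] = np.clip(pos[0], xmin, np.nextafter(xmax, -np.inf))
            pos[1] = np.clip(pos[1], ymin, np.nextafter(ymax, -np.inf))

        # burst emission
        if (m * 60) % cfg.burst_period == 0:
            if state == "rest":
                target = cfg.rest_odba
            elif speeds[state] <= 0:
                target = 0.0  # immobile animal: no dynamic acceleration
            else:
                iy, ix = geom.world_to_cell(pos[0], pos[1])
                env = math.exp(cfg.odba_gain * (float(surf[iy, ix]) - 0.5))
                target = (
                    cfg.active_odba_base
                    * cfg.state_odba_factor[state]
                    * env
                    * math.exp(rng.normal(0, cfg.odba_noise_sd))
                )
            samples = encode_burst(target, cfg.burst_samples, cfg.calib)
            bursts.append(
                AccBurst(
                    timestamp=t, samples=samples, calib=cfg.calib, individual_id=individual_id
                )
            )
            truth_rows.append(
                {
                    "timestamp": t,
                    "true_odba": target,
                    "state": state,
                    "x": pos[0],
                    "y": pos[1],
                }
            )

        # GPS fix emission
        interval = (
            _FIX_INTERVAL_MIN[state]
            if sched == "dynamic"
            else (15 if sched == "fixed15" else 10)
        )
        if minutes_since_fix >= interval:
            fx, fy = pos
            if cfg.gps_error_m > 0:
                fx += rng.normal(0, cfg.gps_error_m)
                fy += rng.normal(0, cfg.gps_error_m)
            fix_rows.append(
                {
                    "individual_id": individual_id,
                    "timestamp": t,
                    "x": fx,
                    "y": fy,
                    "schedule_flag": sched,
                    "synthetic_flag": False,
                    "activity": "rest" if state == "rest" else "active",
                }
            )
            minutes_since_fix = 0
        minutes_since_fix += 1

    track = pd.DataFrame(fix_rows)
    burst_truth = pd.DataFrame(truth_rows)
    burst_truth["individual_id"] = individual_id
    return track, bursts, burst_truth


def simulate_population(
    cfg: SimConfig, land: LandscapeStack, truth: GroundTruth
) -> tuple[pd.DataFrame, dict[str, list[AccBurst]], pd.DataFrame]:
    """All individuals: concatenated tracks, bursts per individual, truth."""
    tracks, all_bursts, truths = [], {}, []
    for i in range(cfg.n_individuals):
        tr, bs, bt = simulate_individual(cfg, land, truth, i)
        tracks.append(tr)
        all_bursts[bt["individual_id"].iloc[0]] = bs
        truths.append(bt)
    return (
        pd.concat(tracks, ignore_index=True),
        all_bursts,
        pd.concat(truths, ignore_index=True),
    )


def simulate_ssf_track(
    land: LandscapeStack,
    beta_forest: float,
    n_steps: int,
    dt: float = 600.0,
    seed: int = 0,
    mean_speed: float = 0.5,
    sd_speed: float = 0.12,
    sd_angle: float = 0.9,
    n_choices: int = 20,
    individual_id: str = "SSF1",
) -> pd.DataFrame:
    """Discrete-choice track with a planted forest preference.

    At every step ``n_choices`` candidate (speed, turning-angle) pairs are
    drawn from the same bivariate normal kernel the step-selection fit
    assumes, and the realized step is selected with probability proportional
    to exp(beta_forest * forest(endpoint)).  A conditional logistic fit on
    forest at step endpoints is consistent for ``beta_forest``.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 7])))
    geom = land.geometry
    xmin, xmax, ymin, ymax = geom.extent
    forest = land.forest_mask
    pos = np.array([(xmin + xmax) / 2, (ymin + ymax) / 2])
    heading = rng.uniform(-np.pi, np.pi)
    rows = [
        {
            "individual_id": individual_id,
            "timestamp": T0,
            "x": pos[0],
            "y": pos[1],
            "schedule_flag": "fixed10",
            "synthetic_flag": False,
            "activity": "active",
        }
    ]
    for i in range(n_steps):
        sp = rng.normal(mean_speed, sd_speed, n_choices)
        ang = rng.normal(0.0, sd_angle, n_choices)
        resample = sp <= 0
        while resample.any():
            sp[resample] = rng.normal(mean_speed, sd_speed, int(resample.sum()))
            resample = sp <= 0
        hh = heading + ang
        ex = pos[0] + sp * dt * np.cos(hh)
        ey = pos[1] + sp * dt * np.sin(hh)
        inside = geom.contains(ex, ey)
        util = np.full(n_choices, -np.inf)
        if inside.any():
            iy, ix = geom.world_to_cell(ex[inside], ey[inside])
            util[inside] = beta_forest * forest[iy, ix].astype(float)
        if not np.isfinite(util).any():
            heading = math.atan2(
                (ymin + ymax) / 2 - pos[1], (xmin + xmax) / 2 - pos[0]
            )
            continue
        w = np.exp(util - np.nanmax(util[np.isfinite(util)]))
        w[~np.isfinite(util)] = 0.0
        k = rng.choice(n_choices, p=w / w.sum())
        pos = np.array([ex[k], ey[k]])
        heading = float(hh[k])
        rows.append(
            {
                "individual_id": individual_id,
                "timestamp": T0 + pd.Timedelta(seconds=(i + 1) * dt),
                "x": pos[0],
                "y": pos[1],
                "schedule_flag": "fixed10",
                "synthetic_flag": False,
                "activity": "active",
            }
        )
    return pd.DataFrame(rows)


def simulate_choice_steps(
    land: LandscapeStack,
    beta_forest: float,
    n_steps: int,
    dt: float = 600.0,
    seed: int = 0,
    mean_speed: float = 0.5,
    sd_speed: float = 0.12,
    sd_angle: float = 0.9,
    n_choices: int = 20,
) -> pd.DataFrame:
    """Independent choice situations with a planted forest preference.

    Unlike :func:`simulate_ssf_track`, every stratum has an independent
    random start point and bearing, so the realized (speed, angle)
    distribution of selected steps matches the proposal kernel and the
    conditional-logit estimate of ``beta_forest`` is unconfounded by
    sequential habitat autocorrelation.  Returns a steps frame compatible
    with :func:`energyscape.ssf.draw_random_steps`.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 9])))
    geom = land.geometry
    xmin, xmax, ymin, ymax = geom.extent
    forest = land.forest_mask
    pad = 3 * mean_speed * dt
    rows = []
    for s in range(n_steps):
        sx = rng.uniform(xmin + pad, xmax - pad)
        sy = rng.uniform(ymin + pad, ymax - pad)
        pb = rng.uniform(-np.pi, np.pi)
        sp = rng.normal(mean_speed, sd_speed, n_choices)
        bad = sp <= 0
        while bad.any():
            sp[bad] = rng.normal(mean_speed, sd_speed, int(bad.sum()))
            bad = sp <= 0
        ang = rng.normal(0.0, sd_angle, n_choices)
        hh = pb + ang
        ex = sx + sp * dt * np.cos(hh)
        ey = sy + sp * dt * np.sin(hh)
        inside = geom.contains(ex, ey)
        util = np.full(n_choices, -np.inf)
        if inside.any():
            iy, ix = geom.world_to_cell(ex[inside], ey[inside])
            util[inside] = beta_forest * forest[iy, ix].astype(float)
        if not np.isfinite(util).any():
            continue
        w = np.exp(util - util[np.isfinite(util)].max())
        w[~np.isfinite(util)] = 0.0
        k = rng.choice(n_choices, p=w / w.sum())
        rows.append(
            {
                "start_x": sx,
                "start_y": sy,
                "end_x": ex[k],
                "end_y": ey[k],
                "t_start": T0 + pd.Timedelta(seconds=s * dt),
                "dt": dt,
                "step_length": sp[k] * dt,
                "speed": sp[k],
                "bearing": hh[k],
                "prev_bearing": pb,
                "turning_angle": ang[k],
            }
        )
    return pd.DataFrame(rows)


# -- Movebank-style CSV ----------------------------------------------------

TRACK_CSV_COLUMNS = [
    "individual_id",
    "timestamp",
    "x",
    "y",
    "schedule_flag",
    "synthetic_flag",
    "activity",
]


def write_track_csv(path, track: pd.DataFrame) -> None:
    out = track.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(lambda t: t.isoformat())
    cols = [c for c in TRACK_CSV_COLUMNS if c in out.columns]
    out[cols].to_csv(Path(path), index=False)


def read_track_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df
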