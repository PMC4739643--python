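"""Track regularization, resting-bout detection, deployment trimming, and
per-day activity metrics.

Dynamic GPS schedules (2/10/60 min keyed to activity) bias any time-budget
quantity toward active periods, so dynamic tracks are regularized to a common
10-minute resolution: runs sampled faster than 10 min are greedily thinned,
and stationary (inactive) gaps are filled with synthetic fixes repeating the
last coordinate every 10 min.

Resting bouts are contiguous runs of low-variability bursts lasting more than
``min_duration`` (default 4 h) that intersect the configured daylight window;
they are excluded from all downstream energy analyses, as is the first 48 h
after collaring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acceleration import AccBurst, calibrate

__all__ = [
    "ActivityBout",
    "regularize",
    "activity_score",
    "detect_rest_bouts",
    "label_records",
    "trim_deployment",
    "activity_metrics",
    "urbanization_correlations",
]

TEN_MIN = pd.Timedelta(minutes=10)


@dataclass(frozen=True)
class ActivityBout:
    start: pd.Timestamp
    end: pd.Timestamp
    state: str  # "active" | "rest"

    @property
    def duration(self) -> float:
        return (self.end - self.start).total_seconds()


def regularize(track: pd.DataFrame) -> pd.DataFrame:
    """Regularize a dynamic-schedule track to >= 10-min spacing.

    Fixed-schedule tracks are returned unchanged.  Requires an ``activity``
    column; inserted fixes carry ``synthetic_flag=True``.
    """
    if len(track) and (track["schedule_flag"] != "dynamic").all():
        return track
    if "activity" not in track.columns or track["activity"].isna().any():
        raise ValueError("regularization requires activity labels on all fixes")
    track = track.sort_values("timestamp").reset_index(drop=True)

    # greedy thinning: keep first fix, then the next fix >= 10 min later
    keep = np.zeros(len(track), dtype=bool)
    last_kept = None
    for i, t in enumerate(track["timestamp"]):
        if last_kept is None or t - last_kept >= TEN_MIN:
            keep[i] = True
            last_kept = t
    thinned = track.loc[keep].reset_index(drop=True)

    # fill inactive gaps with stationary synthetic fixes every 10 min
    pieces = [thinned]
    for i in range(len(thinned) - 1):
        a = thinned.iloc[i]
        gap = thinned["timestamp"].iloc[i + 1] - a["timestamp"]
        if a["activity"] == "rest" and gap > TEN_MIN:
            n_insert = int(np.ceil(gap / TEN_MIN)) - 1
            times = [a["timestamp"] + (k + 1) * TEN_MIN for k in range(n_insert)]
            # keep >= 10 min clearance to the next real fix
            times = [t for t in times if t <= thinned["timestamp"].iloc[i + 1] - TEN_MIN]
            if times:
                pieces.append(
                    pd.DataFrame(
                        {
                            "individual_id": a["individual_id"],
                            "timestamp": times,
                            "x": a["x"],
                            "y": a["y"],
                            "schedule_flag": a["schedule_flag"],
                            "synthetic_flag": True,
                            "activity": "rest",
                        }
                    )
                )
    out = (
        pd.concat(pieces, ignore_index=True)
        .sort_values("timestamp", kind="stable")
        .reset_index(drop=True)
    )
    return out


def activity_score(burst: AccBurst) -> float:
    """Within-burst variability: per-axis standard deviation of calibrated
    samples, summed over axes.  A stand-in for the collar's activity measure."""
    return float(calibrate(burst).std(axis=0).sum())


def _otsu_threshold(scores: np.ndarray) -> float:
    """Two-class variance-maximizing split of log-scores (deterministic)."""
    z = np.log(np.asarray(scores) + 1e-12)
    lo, hi = z.min(), z.max()
    if hi <= lo:
        return -np.inf  # constant scores: nothing is "low"
    edges = np.linspace(lo, hi, 257)
    hist, _ = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_all * cum_w - cum_m) ** 2 / (cum_w * (total - cum_w))
    between[~np.isfinite(between)] = -1
    k = int(np.argmax(between))
    return float(np.exp(edges[k + 1]))


def detect_rest_bouts(
    records: pd.DataFrame,
    scores: np.ndarray,
    day_window: tuple[int, int] = (6 * 3600, 18 * 3600),
    min_duration: float = 4 * 3600.0,
    threshold: float | tuple[str, float] | str = "otsu",
    burst_period: float = 180.0,
) -> list[ActivityBout]:
    """Rest bouts: runs of low-score bursts longer than ``min_duration`` that
    intersect the daylight window (runs extending into the night included).

    ``threshold`` is either an absolute score, ``("quantile", q)`` on the
    per-individual score distribution, or ``"otsu"`` (default): a two-class
    split of the log-score distribution, robust to the rest/active mixture
    proportions.
    """
    records = records.sort_values("timestamp").reset_index(drop=True)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(records):
        raise ValueError("scores and records length mismatch")
    ts = pd.to_datetime(records["timestamp"])
    span = (ts.iloc[-1] - ts.iloc[0]).total_seconds() if len(ts) > 1 else 0.0
    if span < min_duration:
        warnings.warn("record shorter than min_duration: everything active")
        return [ActivityBout(ts.iloc[0], ts.iloc[-1], "active")] if len(ts) else []

    if threshold == "otsu":
        thr = _otsu_threshold(scores)
    elif isinstance(threshold, tuple) and threshold[0] == "quantile":
        thr = float(np.quantile(scores, threshold[1]))
    else:
        thr = float(threshold)
    low = scores < thr

    # contiguous runs of low-score bursts; a run "covers" up to the next burst
    bouts: list[ActivityBout] = []
    i = 0
    n = len(records)
    half = pd.Timedelta(seconds=burst_period / 2)
    while i < n:
        j = i
        while j + 1 < n and low[j + 1] == low[i]:
            j += 1
        start = ts.iloc[i] - half
        end = ts.iloc[j] + half
        state = "undetermined-low" if low[i] else "active"
        if low[i]:
            dur = (end - start).total_seconds()
            sod_start = (start - start.normalize()).total_seconds()
            sod_end = sod_start + dur
            w0, w1 = day_window
            # does [sod_start, sod_end) intersect the daylight window (mod 24h)?
            intersects_day = any(
                max(sod_start, w0 + k * 86400) < min(sod_end, w1 + k * 86400)
                for k in range(int(dur // 86400) + 2)
            )
            state = "rest" if (dur > min_duration and intersects_day) else "active"
        bouts.append(ActivityBout(start, end, state))
        i = j + 1

    # merge adjacent bouts of equal state
    merged: list[ActivityBout] = []
    for b in bouts:
        if merged and merged[-1].state == b.state:
            merged[-1] = ActivityBout(merged[-1].start, b.end, b.state)
        else:
            merged.append(b)
    return merged


def label_records(records: pd.DataFrame, bouts: list[ActivityBout]) -> pd.DataFrame:
    """Attach an ``activity`` column ('rest'/'active') from detected bouts."""
    ts = pd.to_datetime(records["timestamp"])
    lab = np.full(len(records), "active", dtype=object)
    for b in bouts:
        if b.state == "rest":
            lab[(ts >= b.start) & (ts < b.end)] = "rest"
    out = records.copy()
    out["activity"] = lab
    return out


def trim_deployment(
    frame: pd.DataFrame, hours: float = 48.0, start: pd.Timestamp | None = None
) -> pd.DataFrame:
    """Drop all rows within ``hours`` of the first timestamp (capture and
    handling effects)."""
    if len(frame) == 0 or hours <= 0:
        return frame
    ts = pd.to_datetime(frame["timestamp"])
    t0 = start if start is not None else ts.min()
    out = frame.loc[ts >= t0 + pd.Timedelta(hours=hours)].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("trim_deployment removed every record")
    return out


def activity_metrics(
    track: pd.DataFrame,
    bouts: list[ActivityBout],
    day_boundary: int = 64800,
) -> pd.DataFrame:
    """Per-day activity table.

    Days are delimited at ``day_boundary`` seconds-of-day (standing in for
    sunset-to-sunset).  Cumulative distance is the sum of Euclidean step
    lengths between consecutive fixes within a day; active bouts count toward
    the day containing their start.
    """
    off = pd.Timedelta(seconds=day_boundary)

    def day_of(ts: pd.Series) -> pd.Series:
        return (pd.to_datetime(ts) - off).dt.floor("D")

    tr = track.sort_values("timestamp").reset_index(drop=True)
    d = np.hypot(tr["x"].diff(), tr["y"].diff())
    step_day = day_of(tr["timestamp"]).iloc[1:]
    dist = (
        pd.DataFrame({"day": step_day, "dist": d.iloc[1:]})
        .groupby("day")["dist"]
        .sum()
    )

    active = [b for b in bouts if b.state == "active"]
    brows = pd.DataFrame(
        {
            "day": [day_of(pd.Series([b.start])).iloc[0] for b in active],
            "duration": [b.duration for b in active],
        }
    )
    if len(brows):
        grp = brows.groupby("day")["duration"]
        table = pd.DataFrame(
            {"n_active_bouts": grp.size(), "mean_bout_duration": grp.mean()}
        )
    else:
        table = pd.DataFrame(columns=["n_active_bouts", "mean_bout_duration"])
    table = table.join(dist.rename("cumulative_distance"), how="outer")
    table["cumulative_distance"] = table["cumulative_distance"].fillna(0.0)
    table.index.name = "day"
    return table.reset_index()


def urbanization_correlations(
    metrics: pd.DataFrame, pct_urban: pd.Series
) -> pd.DataFrame:
    """Pearson r and OLS slope of each per-individual metric against the
    proportion of urban area in the home range.

    ``metrics`` is indexed by individual with one column per metric;
    ``pct_urban`` is aligned on the same index.
    """
    import statsmodels.api as sm

    pct = pct_urban.loc[metrics.index].to_numpy(dtype=float)
    if len(metrics) < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(pct) == 0:
        raise ValueError("predictor (% urban) has zero variance")
    rows = []
    X = sm.add_constant(pct)
    for col in metrics.columns:
        y = metrics[col].to_numpy(dtype=float)
        r, p_r = stats.pearsonr(pct, y)
        fit = sm.OLS(y, X).fit()
        rows.append(
            {
                "metric": col,
                "pearson_r": r,
                "pearson_p": p_r,
                "slope": fit.params[1],
                "slope_se": fit.bse[1],
                "t": fit.tvalues[1],
                "df": int(fit.df_resid),
                "p": fit.pvalues[1],
            }
        )
    return pd.DataFrame(rows)
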