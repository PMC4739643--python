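"""Raw tri-axial accelerometer bursts to per-burst ODBA.

A burst is a short window (by default 54 samples per axis at nominal 18.74 Hz)
of raw integer counts from a collar accelerometer.  Processing steps:

1. calibrate counts to m/s^2 using the manufacturer equation
   ``a_i = (n_i - n_zerog) * c_i * g``;
2. overall dynamic body acceleration (ODBA) per burst: the mean over samples
   of the summed per-axis absolute deviations from the per-axis burst mean
   (the gravity/posture component is removed by the mean-centering);
3. per-individual min-max standardization of ODBA to [0, 1] for
   cross-individual comparability of sensors with different sensitivities;
4. association of each burst to the GPS fix closest in time, dropping bursts
   whose nearest fix is more than ``max_gap`` seconds away (default 60 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationParams",
    "AccBurst",
    "calibrate",
    "odba",
    "odba_records",
    "standardize",
    "join_bursts_to_fixes",
    "read_burst_csv",
    "write_burst_csv",
]

GRAVITY = 9.81  # m/s^2

#: manufacturer default slopes (g per count) for the two sensitivity settings
SLOPE_HIGH_SENSITIVITY = 0.001
SLOPE_LOW_SENSITIVITY = 0.00269
ZERO_G_COUNT = 2048.0


@dataclass(frozen=True)
class CalibrationParams:
    """Counts-to-acceleration calibration: a = (n - zero_g) * slope * gravity."""

    zero_g: float = ZERO_G_COUNT
    slope: float = SLOPE_HIGH_SENSITIVITY
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.gravity <= 0:
            raise ValueError("slope and gravity must be positive")


@dataclass
class AccBurst:
    """One burst of raw counts, shape (n_samples, 3) for axes x, y, z."""

    timestamp: pd.Timestamp
    samples: np.ndarray
    calib: CalibrationParams = field(default_factory=CalibrationParams)
    individual_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.samples.shape[0] < 2:
            raise ValueError("a burst needs at least 2 samples per axis")


def calibrate(burst: AccBurst) -> np.ndarray:
    """Per-sample accelerations in m/s^2, shape (n, 3)."""
    c = burst.calib
    if c is None:
        raise ValueError("burst has no calibration parameters")
    return (burst.samples.astype(float) - c.zero_g) * c.slope * c.gravity


def odba(burst: AccBurst) -> float:
    """Mean over samples of |x-x̄| + |y-ȳ| + |z-z̄| on calibrated samples."""
    a = calibrate(burst)
    dev = np.abs(a - a.mean(axis=0))
    return float(dev.sum(axis=1).mean())


def odba_array(calibrated: np.ndarray) -> np.ndarray:
    """Vectorized ODBA for a stack of equal-length bursts, shape (B, n, 3)."""
    a = np.asarray(calibrated, dtype=float)
    dev = np.abs(a - a.mean(axis=1, keepdims=True))
    return dev.sum(axis=2).mean(axis=1)


def odba_records(bursts: list[AccBurst]) -> pd.DataFrame:
    """ODBA table for a list of bursts (one row per burst)."""
    return pd.DataFrame(
        {
            "individual_id": [b.individual_id for b in bursts],
            "timestamp": [b.timestamp for b in bursts],
            "odba": [odba(b) for b in bursts],
        }
    )


def standardize(records: pd.DataFrame, column: str = "odba") -> pd.DataFrame:
    """Min-max standardize ODBA to [0, 1] within one individual.

    Requires at least two distinct values; a constant series has no dynamic
    range and is rejected rather than silently divided by zero.
    """
    vals = records[column].to_numpy(dtype=float)
    lo, hi = vals.min(), vals.max()
    if not hi > lo:
        raise ValueError("cannot standardize: all ODBA values are equal")
    out = records.copy()
    out["odba_std"] = (vals - lo) / (hi - lo)
    return out


def join_bursts_to_fixes(
    records: pd.DataFrame, track: pd.DataFrame, max_gap: float = 60.0
) -> pd.DataFrame:
    """Attach each burst to the GPS fix nearest in time.

    Ties (a burst exactly midway between two fixes) go to the earlier fix.
    Bursts whose nearest fix is more than ``max_gap`` seconds away are
    dropped; the returned frame carries ``joined_fix_id``, ``time_gap`` (s),
    the fix coordinates, and attrs ``n_dropped`` and ``median_gap``.
    """
    if len(track) == 0:
        raise ValueError("cannot join bursts to an empty track")
    bt = pd.to_datetime(records["timestamp"]).to_numpy()
    ft = pd.to_datetime(track["timestamp"]).to_numpy()
    order = np.argsort(ft, kind="stable")
    ft = ft[order]
    pos = np.searchsorted(ft, bt)
    left = np.clip(pos - 1, 0, len(ft) - 1)
    right = np.clip(pos, 0, len(ft) - 1)
    dl = np.abs((bt - ft[left]) / np.timedelta64(1, "s"))
    dr = np.abs((ft[right] - bt) / np.timedelta64(1, "s"))
    use_left = dl <= dr  # tie -> earlier fix
    idx = np.where(use_left, left, right)
    gap = np.where(use_left, dl, dr)

    out = records.copy()
    out["joined_fix_id"] = track.index.to_numpy()[order][idx]
    out["time_gap"] = gap
    out["x"] = track["x"].to_numpy()[order][idx]
    out["y"] = track["y"].to_numpy()[order][idx]
    keep = gap <= max_gap
    dropped = int((~keep).sum())
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    out.attrs["median_gap"] = float(np.median(out["time_gap"])) if len(out) else np.nan
    return out


# -- CSV interchange -------------------------------------------------------

BURST_CSV_COLUMNS = ["individual_id", "timestamp", "axis_id", "sample_index", "raw_count"]
_AXES = ["x", "y", "z"]


def write_burst_csv(path, bursts: list[AccBurst]) -> None:
    """Long-format burst file: one row per (axis, sample)."""
    rows = []
    for b in bursts:
        n = b.samples.shape[0]
        ts = pd.Timestamp(b.timestamp).isoformat()
        for ai, axis in enumerate(_AXES):
            rows.append(
                pd.DataFrame(
                    {
                        "individual_id": b.individual_id,
                        "timestamp": ts,
                        "axis_id": axis,
                        "sample_index": np.arange(n),
                        "raw_count": b.samples[:, ai],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(Path(path), index=False)


def read_burst_csv(path, calib: CalibrationParams | None = None) -> list[AccBurst]:
    df = pd.read_csv(path)
    missing = set(BURST_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"burst CSV missing columns: {sorted(missing)}")
    calib = calib or CalibrationParams()
    bursts = []
    for (ind, ts), grp in df.groupby(["individual_id", "timestamp"], sort=True):
        wide = grp.pivot(index="sample_index", columns="axis_id", values="raw_count")
        samples = wide[_AXES].to_numpy()
        bursts.append(
            AccBurst(
                timestamp=pd.Timestamp(ts),
                samples=samples,
                calib=calib,
                individual_id=str(ind),
            )
        )
    bursts.sort(key=lambda b: (b.individual_id, b.timestamp))
    return bursts
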