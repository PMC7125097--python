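"""Moving-correlation autoregulation indices (PRx, COx, HVx).

Each index is the Pearson correlation between slow ABP fluctuations and a
cerebral signal, computed over a trailing window of 30 ten-second means
(300 s) advanced every 10 s:

* PRx: ABP vs ICP (pressure reactivity),
* COx: ABP vs rSO2 (cerebral oximetry),
* HVx: ABP vs rTHb (hemoglobin volume, a blood-volume surrogate).

Negative or near-zero values indicate active vasoreactivity; values
approaching +1 indicate pressure passivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .preprocess import SlowWaveSeries

log = logging.getLogger(__name__)

#: index name -> (x channel, y channel)
INDEX_CHANNELS = {
    "PRx": ("abp", "icp"),
    "COx": ("abp", "rso2"),
    "HVx": ("abp", "rthb"),
    "wPRx": ("abp", "icp"),
    "wCOx": ("abp", "rso2"),
    "wHVx": ("abp", "rthb"),
}

CORRELATION_INDICES = ("PRx", "COx", "HVx")
WAVELET_INDICES = ("wPRx", "wCOx", "wHVx")


@dataclass
class IndexSeries:
    """One autoregulation index sampled on the 10-s epoch grid.

    Values lie in [-1, 1]; missing steps are NaN.
    """

    name: str
    time_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.values):
            raise InputError("time and value lengths differ")
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9):
            raise InputError(f"{self.name}: values outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, self.name: self.values})


def write_index_csv(path: str | Path, indices: list[IndexSeries]) -> None:
    """Write several aligned index series as one CSV (time_s + one column each)."""
    if not indices:
        raise InputError("no index series to write")
    df = pd.DataFrame({"time_s": indices[0].time_s})
    for idx in indices:
        if len(idx) != len(df):
            raise InputError("index series are not aligned")
        df[idx.name] = idx.values
    df.to_csv(path, index=False)


def read_index_csv(path: str | Path) -> list[IndexSeries]:
    df = pd.read_csv(path, comment="#")
    t = df["time_s"].to_numpy(float)
    return [
        IndexSeries(name=c, time_s=t, values=df[c].to_numpy(float))
        for c in df.columns
        if c != "time_s"
    ]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (logged) when either vector is constant.

    Inputs must be equal-length with at least 3 samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise InputError("need at least 3 paired samples")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0.0:
        log.debug("pearson_r: constant input vector, returning missing")
        return float("nan")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def moving_index(
    series: SlowWaveSeries,
    ch_x: str,
    ch_y: str,
    window_samples: int = 30,
    step_s: float = 10.0,
    name: str | None = None,
    max_missing_frac: float = 0.25,
) -> IndexSeries:
    """Trailing moving Pearson correlation of two channels.

    One value per ``step_s`` (one epoch), computed over the trailing
    ``window_samples`` epochs and timestamped at the window end.  A window
    whose fraction of missing epochs (NaN in either channel) exceeds
    ``max_missing_frac`` is missing; otherwise the correlation uses the valid
    pairs.  The first ``window_samples - 1`` steps are missing by
    construction.
    """
    x = series[ch_x]
    y = series[ch_y]
    step_epochs = int(round(step_s / series.block_s))
    if step_epochs != 1:
        raise InputError("step must equal one epoch (shared grid with wavelet indices)")
    n = len(series)
    if n < window_samples:
        raise InputError(f"need at least {window_samples} epochs, got {n}")
    min_valid = int(np.ceil((1.0 - max_missing_frac) * window_samples))

    sx = pd.Series(np.where(np.isfinite(y), x, np.nan))
    sy = pd.Series(np.where(np.isfinite(x), y, np.nan))
    r = sx.rolling(window_samples, min_periods=min_valid).corr(sy).to_numpy()
    r[: window_samples - 1] = np.nan
    r[~np.isfinite(r)] = np.nan  # zero-variance windows
    with np.errstate(invalid="ignore"):
        r = np.clip(r, -1.0, 1.0)
    return IndexSeries(
        name=name or f"corr({ch_x},{ch_y})", time_s=series.time_s.copy(), values=r
    )


def correlation_indices(
    series: SlowWaveSeries, window_samples: int = 30
) -> dict[str, IndexSeries]:
    """Compute PRx, COx and HVx from one slow-wave series."""
    return {
        nm: moving_index(
            series, *INDEX_CHANNELS[nm], window_samples=window_samples, name=nm
        )
        for nm in CORRELATION_INDICES
    }
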