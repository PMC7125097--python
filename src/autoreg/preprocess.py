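"""Reduction of raw sampled channels to consecutive 10-second means.

Ten-second block averaging removes pulse and respiratory waveforms and leaves
the slow vasogenic oscillations that all autoregulation indices are computed
from.  Blocks are consecutive and non-overlapping; a trailing partial block is
discarded; any invalid sample (NaN) inside a block marks that epoch missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError
from .simulate import RawRecording


@dataclass
class SlowWaveSeries:
    """Per-channel consecutive block means on a common 10-s epoch grid.

    ``time_s`` marks the *end* of each block.  Missing epochs are NaN.
    """

    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    block_s: float = 10.0

    def __post_init__(self) -> None:
        for ch, v in self.channels.items():
            if len(v) != len(self.time_s):
                raise InputError(f"channel {ch!r} length != epoch count")

    def __len__(self) -> int:
        return len(self.time_s)

    def __getitem__(self, ch: str) -> np.ndarray:
        try:
            return self.channels[ch]
        except KeyError:
            raise InputError(f"channel {ch!r} not present") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, **self.channels})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SlowWaveSeries":
        df = pd.read_csv(path, comment="#")
        if "time_s" not in df.columns:
            raise InputError(f"{path}: missing required column 'time_s'")
        t = df["time_s"].to_numpy(float)
        block = float(t[1] - t[0]) if len(t) > 1 else 10.0
        chans = {c: df[c].to_numpy(float) for c in df.columns if c != "time_s"}
        return cls(time_s=t, channels=chans, block_s=block)


def block_average(recording: RawRecording, block_s: float = 10.0) -> SlowWaveSeries:
    """Average every channel in consecutive non-overlapping ``block_s`` blocks.

    Raises :class:`InsufficientDataError` if the recording is shorter than one
    block.  NaN samples propagate: an epoch containing any invalid sample is
    NaN in the output.
    """
    per_block = int(round(block_s * recording.sample_rate_hz))
    if per_block < 1 or recording.n_samples < per_block:
        raise InsufficientDataError(
            f"recording shorter than one {block_s}-s block "
            f"({recording.n_samples} samples at {recording.sample_rate_hz} Hz)"
        )
    n_blocks = recording.n_samples // per_block
    out = {}
    for ch, x in recording.channels.items():
        out[ch] = (
            np.asarray(x[: n_blocks * per_block], dtype=float)
            .reshape(n_blocks, per_block)
            .mean(axis=1)  # plain mean: NaN anywhere in a block voids the epoch
        )
    time_s = (np.arange(n_blocks) + 1) * block_s
    return SlowWaveSeries(time_s=time_s, channels=out, block_s=block_s)
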