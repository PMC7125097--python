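"""Synthetic piglet-like multichannel recordings with known autoregulation limits.

The generator emulates the monitoring setup used in neonatal-swine
autoregulation experiments: arterial blood pressure (ABP) is slowly lowered
over a few hours across the animal's lower limit of autoregulation (LLA),
while intracranial pressure (ICP), NIRS cerebral oximetry (rSO2), NIRS
relative total hemoglobin (rTHb, a cerebral blood volume surrogate) and
laser-Doppler flux (LDF) are recorded continuously.

The physiological fiction, deliberately minimal:

* ABP = linear ramp + band-limited vasogenic slow waves (0.007-0.05 Hz)
  + white measurement noise.
* Cerebral blood flow follows a Lassen curve: constant (autoregulated)
  above the LLA, linearly pressure-passive below it.
* Vasoreactive coupling: above the LLA active vasoreactivity drives blood
  volume (rTHb, and ICP through the volume-pressure relation) *against* slow
  ABP fluctuations, with a first-order lag of a few tens of seconds (real
  vasomotor responses are not instantaneous, which leaves a
  frequency-dependent phase shift across the slow-wave band); below the LLA
  the vasculature is pressure-passive and pressure transmits immediately and
  in phase into volume.  The transition is smoothed with a logistic of
  configurable width so no discontinuity artifact sits exactly at the LLA.
* Vasoreactivity strength above the LLA is maximal at a configurable optimal
  ABP (``abpopt_true``) and decays with a Gaussian profile away from it;
  this plants the U-shaped index-vs-ABP curve whose vertex the multi-window
  ABPopt estimator must recover.

Everything is generated at 1 Hz and sample-held to the declared rate (all
downstream analysis consumes 10-s means, so sub-second structure is
irrelevant); pulse and respiratory waveforms are intentionally absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CHANNELS = ("abp", "icp", "rso2", "rthb", "ldf")

#: CSV column names for the on-disk recording format, in order.
CSV_COLUMNS = ("time_s", "abp_mmhg", "icp_mmhg", "rso2_pct", "rthb_au", "ldf_au")

_CH_TO_CSV = dict(zip(CHANNELS, CSV_COLUMNS[1:]))
_CSV_TO_CH = {v: k for k, v in _CH_TO_CSV.items()}


def _default_noise_sd() -> dict[str, float]:
    # White measurement noise per channel (units: mmHg, mmHg, %, a.u., a.u.).
    # Chosen so that windowed correlation indices sit near the moderately
    # negative / strongly positive regimes seen above/below the LLA in
    # piglet recordings, with above-LLA index SDs around 0.3-0.45.
    return {"abp": 1.5, "icp": 2.5, "rso2": 4.0, "rthb": 9.0, "ldf": 3.0}


def _default_slow_noise_sd() -> dict[str, float]:
    # Optional: independent in-band slow activity per channel (local
    # vasomotion, CO2 drifts) not driven by ABP.  Off by default.
    return {}


def _default_midband_noise_sd() -> dict[str, float]:
    # Optional: colored interference (residual respiratory/movement
    # activity) in ``midband_noise_band``; partially survives 10-s averaging
    # and aliases into the slow-wave band.  Off by default.
    return {}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    Defaults describe the study conditions the pipeline is exercised under:
    a 4-h recording whose ABP ramps from 80 to 30 mmHg (the 2-3 h decline
    crossing the LLA plus the baseline period), LLA at 45 mmHg, optimal ABP
    at 60 mmHg.
    """

    duration_s: float = 14400.0
    sample_rate_hz: float = 1.0
    abp_start: float = 80.0
    abp_end: float = 30.0
    lla_true: float = 45.0
    abpopt_true: float = 60.0
    plateau_flow: float = 100.0
    passive_slope: float = 2.0          # a.u. flow lost per mmHg below the LLA
    slow_wave_band: tuple[float, float] = (0.007, 0.05)
    slow_wave_amp: float = 4.5          # mmHg; RMS of the summed waves ≈ amp/√2
    n_slow_waves: int = 12
    # Slow-wave trains: vasogenic activity waxes and wanes.  The summed waves
    # are multiplied by a mean-one envelope (1-m) + m*w, where w is a squared
    # band-limited Gaussian (correlation time ~1/cutoff).  m=0 disables.
    slow_wave_modulation: float = 0.0
    slow_mod_cutoff_hz: float = 0.0015
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    slow_noise_sd: dict[str, float] = field(default_factory=_default_slow_noise_sd)
    midband_noise_sd: dict[str, float] = field(default_factory=_default_midband_noise_sd)
    midband_noise_band: tuple[float, float] = (0.03, 0.09)  # Hz at generation rate
    # Transient step artifacts (probe shifts, movement): Poisson-placed
    # constant-offset bursts, independent per channel.
    artifact_rate_hz: float = 0.0               # off by default
    artifact_amp: dict[str, float] = field(default_factory=lambda: {
        "abp": 6.0, "icp": 8.0, "rso2": 12.0, "rthb": 30.0, "ldf": 10.0})
    artifact_duration_s: float = 20.0           # mean burst length (exponential)
    reactivity_gain: float = 2.0        # rTHb a.u. per mmHg of slow ABP
    reactivity_width: float = 8.0       # mmHg; Gaussian decay of gain from ABPopt
    reactivity_tau_s: float = 20.0      # vasoreactive response lag (first-order)
    passive_gain_factor: float = 1.0    # coupling amplification below the LLA
    icp_gain: float = 0.6               # mmHg ICP per mmHg slow ABP
    rso2_flow_gain: float = 20.0        # % rSO2 per unit fractional flow change
    rso2_reactivity_gain: float = 1.0   # % rSO2 per mmHg slow ABP
    icp_baseline: float = 10.0          # mmHg (experimental cohorts: mean ICP ≤ 15)
    rso2_baseline: float = 50.0
    rthb_baseline: float = 50.0
    transition_width: float = 2.0       # mmHg; logistic width of the sign flip
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.slow_wave_band
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if not (0 < lo < hi):
            raise ConfigurationError("slow_wave_band must satisfy 0 < low < high")
        if hi > self.sample_rate_hz / 2:
            raise ConfigurationError(
                f"slow_wave_band high edge {hi} Hz exceeds Nyquist "
                f"{self.sample_rate_hz / 2} Hz"
            )
        if not (self.abp_end < self.lla_true < self.abp_start):
            raise ConfigurationError("need abp_end < lla_true < abp_start")
        if self.abpopt_true <= self.lla_true:
            raise ConfigurationError("abpopt_true must exceed lla_true")
        if any(sd < 0 for sd in self.noise_sd.values()) or any(
            sd < 0 for sd in self.midband_noise_sd.values()
        ):
            raise ConfigurationError("noise_sd values must be non-negative")
        if self.lla_true <= 0 or self.plateau_flow <= 0:
            raise ConfigurationError("lla_true and plateau_flow must be positive")


@dataclass
class GroundTruth:
    """Simulator-known truth against which estimators are scored."""

    lla_true: float
    abpopt_true: float
    time_of_lla_crossing: float          # s; when the noise-free ramp crosses the LLA
    epoch_above_lla: np.ndarray          # bool per 10-s epoch (noise-free ABP ≥ LLA)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "lla_true": self.lla_true,
            "abpopt_true": self.abpopt_true,
            "time_of_lla_crossing": self.time_of_lla_crossing,
            "epoch_above_lla": [bool(v) for v in self.epoch_above_lla],
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            lla_true=obj["lla_true"],
            abpopt_true=obj["abpopt_true"],
            time_of_lla_crossing=obj["time_of_lla_crossing"],
            epoch_above_lla=np.asarray(obj["epoch_above_lla"], dtype=bool),
        )


@dataclass
class RawRecording:
    """Multichannel sampled recording plus per-animal metadata.

    Channels are stored as equal-length float arrays; ``rso2`` is a
    percentage in [0, 100].
    """

    channels: dict[str, np.ndarray]
    sample_rate_hz: float
    animal_id: str = "sim-0"
    group: str = "arrest"                # arrest | sham
    temperature_arm: str = "normothermia"  # metadata only, never analyzed

    def __post_init__(self) -> None:
        lengths = {ch: len(a) for ch, a in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ConfigurationError(f"unequal channel lengths: {lengths}")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_s": self.time_s})
        for ch in CHANNELS:
            df[_CH_TO_CSV[ch]] = self.channels[ch]
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(
        cls, path: str | Path, sample_rate_hz: float | None = None, **meta
    ) -> "RawRecording":
        from .pipeline import load_recording_csv  # single schema authority

        return load_recording_csv(path, sample_rate_hz=sample_rate_hz, **meta)


def lassen_flow(
    abp: np.ndarray | float,
    lla: float,
    plateau: float,
    passive_slope: float,
) -> np.ndarray | float:
    """Lassen autoregulation curve: constant flow above the LLA, linearly
    pressure-passive below it, floored at zero.

    Continuous at ``abp == lla`` where both branches equal ``plateau``.
    """
    if lla <= 0 or plateau <= 0:
        raise ConfigurationError("lla and plateau must be positive")
    abp_arr = np.asarray(abp, dtype=float)
    flow = np.where(
        abp_arr >= lla,
        plateau,
        np.maximum(plateau - passive_slope * (lla - abp_arr), 0.0),
    )
    if np.isscalar(abp) or abp_arr.ndim == 0:
        return float(flow)
    return flow


def _slow_waves(cfg: SimulationConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of log-spaced in-band sinusoids with random phases.

    Per-component amplitude amp/√n keeps the summed RMS at amp/√2
    independent of the component count.
    """
    lo, hi = cfg.slow_wave_band
    freqs = np.geomspace(lo, hi, cfg.n_slow_waves)
    phases = rng.uniform(0, 2 * np.pi, cfg.n_slow_waves)
    amp = cfg.slow_wave_amp / np.sqrt(cfg.n_slow_waves)
    waves = amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    return waves.sum(axis=0)


def _bandlimited_noise(
    n: int,
    fs: float,
    band: tuple[float, float],
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise FFT-restricted to ``band`` and rescaled to ``sd``."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    y = np.fft.irfft(spec, n)
    s = y.std()
    return y * (sd / s) if s > 0 else y


def _activity_envelope(
    cfg: SimulationConfig, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean-one nonnegative envelope of slow-wave activity.

    ``(1-m) + m*w`` with ``w`` a normalized squared band-limited Gaussian:
    long quiet spells and wave trains, correlation time ~1/cutoff.
    """
    u = _bandlimited_noise(n, fs, (1e-6, cfg.slow_mod_cutoff_hz), 1.0, rng)
    w = u**2
    w = w / w.mean() if w.mean() > 0 else np.ones(n)
    m = cfg.slow_wave_modulation
    return (1.0 - m) + m * w


def _step_artifacts(
    n: int,
    fs: float,
    rate_hz: float,
    amp: float,
    mean_duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson-placed random-sign constant-offset bursts of exponential length."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_hz * n / fs)
    starts = rng.integers(0, n, size=n_events)
    durations = rng.exponential(mean_duration_s, size=n_events)
    signs = rng.choice([-1.0, 1.0], size=n_events)
    heights = amp * rng.uniform(0.5, 1.5, size=n_events)
    for s0, d, sg, h in zip(starts, durations, signs, heights):
        s1 = min(int(s0 + max(d * fs, 1)), n)
        out[s0:s1] += sg * h
    return out


def _first_order_lowpass(x: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    """Unit-DC-gain first-order response with time constant ``tau_s``."""
    if tau_s <= 0:
        return x
    from scipy.signal import lfilter, lfilter_zi

    alpha = 1.0 / (1.0 + tau_s * fs)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    zi = lfilter_zi(b, a) * x[0]
    y, _ = lfilter(b, a, x, zi=zi)
    return y


def generate_recording(cfg: SimulationConfig) -> tuple[RawRecording, GroundTruth]:
    """Synthesize one recording and its ground truth.

    Deterministic for a fixed ``cfg.seed``: identical configs give
    bit-identical arrays.
    """
    rng = np.random.default_rng(cfg.seed)

    # Generate at 1 Hz (or the declared rate when slower) and sample-hold up.
    if cfg.sample_rate_hz <= 1.0:
        gen_hz, hold = cfg.sample_rate_hz, 1
    else:
        hold = int(round(cfg.sample_rate_hz))
        if abs(hold - cfg.sample_rate_hz) > 1e-9:
            raise ConfigurationError("sample_rate_hz above 1 Hz must be an integer")
        gen_hz = 1.0
    n_gen = int(round(cfg.duration_s * gen_hz))
    if n_gen < 2:
        raise ConfigurationError("duration too short for the sample rate")
    t = np.arange(n_gen) / gen_hz

    ramp = cfg.abp_start + (cfg.abp_end - cfg.abp_start) * t / cfg.duration_s
    slow = _slow_waves(cfg, t, rng)
    if cfg.slow_wave_modulation > 0:
        slow = slow * _activity_envelope(cfg, n_gen, gen_hz, rng)
    abp_clean = ramp + slow

    ldf_clean = lassen_flow(abp_clean, cfg.lla_true, cfg.plateau_flow, cfg.passive_slope)

    # Active vasoreactivity responds with a first-order lag (tens of seconds,
    # giving a frequency-dependent phase lead/lag within the slow-wave band);
    # passive pressure transmission below the LLA is effectively immediate.
    slow_lagged = _first_order_lowpass(slow, cfg.reactivity_tau_s, gen_hz)
    p_below = 1.0 / (1.0 + np.exp((abp_clean - cfg.lla_true) / cfg.transition_width))
    g_opt = np.exp(-((abp_clean - cfg.abpopt_true) ** 2) / (2 * cfg.reactivity_width**2))

    def vaso(gain: float) -> np.ndarray:
        passive = cfg.passive_gain_factor * p_below * slow
        active = -(1.0 - p_below) * g_opt * slow_lagged
        return gain * (passive + active)

    rthb_clean = cfg.rthb_baseline + vaso(cfg.reactivity_gain)
    icp_clean = cfg.icp_baseline + vaso(cfg.icp_gain)
    rso2_clean = (
        cfg.rso2_baseline
        + cfg.rso2_flow_gain * (ldf_clean - cfg.plateau_flow) / cfg.plateau_flow
        + vaso(cfg.rso2_reactivity_gain)
    )

    clean = {
        "abp": abp_clean,
        "icp": icp_clean,
        "rso2": rso2_clean,
        "rthb": rthb_clean,
        "ldf": ldf_clean,
    }
    channels = {}
    for ch in CHANNELS:
        noisy = clean[ch].astype(float).copy()
        sd = cfg.noise_sd.get(ch, 0.0)
        if sd > 0:
            noisy += sd * rng.standard_normal(n_gen)
        ssd = cfg.slow_noise_sd.get(ch, 0.0)
        if ssd > 0:
            noisy += _bandlimited_noise(n_gen, gen_hz, cfg.slow_wave_band, ssd, rng)
        mb = cfg.midband_noise_sd.get(ch, 0.0)
        if mb > 0:
            noisy += _bandlimited_noise(n_gen, gen_hz, cfg.midband_noise_band, mb, rng)
        amp = cfg.artifact_amp.get(ch, 0.0)
        if amp > 0 and cfg.artifact_rate_hz > 0:
            noisy += _step_artifacts(n_gen, gen_hz, cfg.artifact_rate_hz, amp,
                                     cfg.artifact_duration_s, rng)
        channels[ch] = np.repeat(noisy, hold) if hold > 1 else noisy
    channels["rso2"] = np.clip(channels["rso2"], 0.0, 100.0)
    channels["ldf"] = np.maximum(channels["ldf"], 0.0)

    recording = RawRecording(channels=channels, sample_rate_hz=cfg.sample_rate_hz)

    # Ramp crossing time: solve ramp(t) = lla.
    frac = (cfg.abp_start - cfg.lla_true) / (cfg.abp_start - cfg.abp_end)
    t_cross = float(frac * cfg.duration_s)
    # Epoch regime labels from the noise-free slow ABP (10-s block means).
    per_block = max(int(round(10 * gen_hz)), 1)
    n_ep = n_gen // per_block
    abp_ep = abp_clean[: n_ep * per_block].reshape(n_ep, per_block).mean(axis=1)
    truth = GroundTruth(
        lla_true=cfg.lla_true,
        abpopt_true=cfg.abpopt_true,
        time_of_lla_crossing=t_cross,
        epoch_above_lla=abp_ep >= cfg.lla_true,
    )
    return recording, truth


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["slow_wave_band"] = list(d["slow_wave_band"])
    return d
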