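"""Coherence-gated wavelet-semblance autoregulation indices (wPRx, wCOx, wHVx).

The wavelet variant of each index replaces the windowed Pearson correlation
with the *semblance* — the cosine of the wavelet phase difference between ABP
and the cerebral signal — evaluated in the vasogenic slow-wave band
(0.007-0.05 Hz) and averaged over scale-time points whose wavelet coherence
reaches a reliability threshold (default 0.46).  Gating on coherence discards
phase estimates dominated by noise, which is what gives the wavelet indices
their lower variability.

Transform
---------
Complex Morlet continuous wavelet transform (center frequency ``omega0 = 6``)
of the 10-s-mean series, computed as a frequency-domain filter bank::

    W(s, t_n) = IFFT_n[ X(w_k) * pi**-0.25 * sqrt(2*pi*s) * exp(-(s*w_k - omega0)**2 / 2) ]

(positive frequencies only), which approximates the continuous transform
``s**-0.5 * integral x(u) psi*((u - t)/s) du`` with the unit-energy Morlet
``psi(eta) = pi**-0.25 * exp(1j*omega0*eta - eta**2/2)``.  This analytic form
remains exact down to scales of ~2 samples, where discretized time-domain
convolution of the wavelet breaks down (the band's upper edge sits at the
Nyquist frequency of the 0.1-Hz epoch rate).  Signals are linearly detrended
and zero-padded to the next power of two before transforming.

Coherence
---------
Magnitude-squared coherence of the smoothed cross-spectrum.  Smoothing is a
scale-proportional Gaussian in time (sigma = 0.2 scales by default, with an
optional boxcar across scales); some smoothing is required because
unsmoothed wavelet coherence is identically 1.  The default kernel is
deliberately light: it keeps the coherence gate a mild reliability filter
whose retained points still average phase noise away, rather than a hard
selector of only the strongest coherent events.  Phase is taken from the
smoothed cross-spectrum with the convention that a positively lagging second
signal gives positive phase.

Windowing
---------
Indices step every 10 s over trailing 800-s windows; the outer 250 s at each
end of every window are edge-rejected, leaving a central 300-s segment (the
same effective support as the 300-s correlation windows).  The transform
itself is computed once over the whole record; the per-window trim defines
which scale-time points contribute to each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import detrend

from .correlation import INDEX_CHANNELS, WAVELET_INDICES, IndexSeries
from .errors import ConfigurationError, InputError
from .preprocess import SlowWaveSeries


@dataclass
class WaveletConfig:
    """Parameters of the wavelet semblance estimator."""

    band: tuple[float, float] = (0.007, 0.05)   # Hz
    window_s: float = 800.0
    step_s: float = 10.0
    edge_reject_s: float = 500.0                # total, split symmetrically
    coherence_threshold: float = 0.46
    voices_per_octave: int = 12
    omega0: float = 6.0                         # Morlet center parameter
    scale_smoothing_octaves: float = 0.0        # boxcar across scales; 0 = none
    time_smoothing_scales: float = 0.2          # Gaussian sigma as multiple of scale
    max_missing_frac: float = 0.25
    scale_weighted: bool = False                # weight frequency average by scale

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ConfigurationError("band must satisfy 0 < low < high")
        if not (0 <= self.coherence_threshold <= 1):
            raise ConfigurationError("coherence_threshold must lie in [0, 1]")
        if self.window_s <= self.edge_reject_s:
            raise ConfigurationError("window_s must exceed edge_reject_s")

    @property
    def fourier_factor(self) -> float:
        """Period / scale for the Morlet wavelet."""
        w0 = self.omega0
        return 4 * np.pi / (w0 + np.sqrt(2 + w0**2))

    def frequencies(self) -> np.ndarray:
        """Descending in-band frequency grid at the configured voice density."""
        lo, hi = self.band
        n_oct = np.log2(hi / lo)
        n = int(np.ceil(n_oct * self.voices_per_octave)) + 1
        return hi * 2.0 ** (-np.arange(n) / self.voices_per_octave)


@dataclass
class ScaleTimePlane:
    """Scale-time arrays from one transform (or one pair of transforms)."""

    freqs: np.ndarray                      # Hz, one per scale row
    scales: np.ndarray                     # s
    dt: float                              # epoch spacing, s
    coeffs: np.ndarray | None = None       # complex CWT coefficients
    coherence: np.ndarray | None = None    # [0, 1]
    phase: np.ndarray | None = None        # (-pi, pi]
    coi_mask: np.ndarray = field(default=None)  # True where inside the cone

    @property
    def n_epochs(self) -> int:
        arr = self.coeffs if self.coeffs is not None else self.coherence
        return arr.shape[1]


def cwt_complex(epochs: np.ndarray, dt: float, config: WaveletConfig) -> ScaleTimePlane:
    """Complex Morlet CWT of one epoch series over the configured band.

    NaN epochs are linearly interpolated before transforming (missing-data
    accounting is done by the caller).  The cone-of-influence mask marks
    points farther than the e-folding time ``sqrt(2)*scale`` from both record
    ends.
    """
    x = np.asarray(epochs, dtype=float)
    n = len(x)
    freqs = config.frequencies()
    scales = 1.0 / (config.fourier_factor * freqs)
    if freqs[0] > 0.5 / dt + 1e-12:
        raise ConfigurationError(
            f"band upper edge {freqs[0]} Hz not representable at epoch rate {1/dt} Hz"
        )
    min_epochs = int(config.window_s / dt)
    if n < min(min_epochs, 4):
        raise InputError("too few epochs for a wavelet transform")

    bad = ~np.isfinite(x)
    if bad.all():
        raise InputError("all epochs missing")
    if bad.any():
        idx = np.arange(n)
        x = x.copy()
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    if n >= 3:
        x = detrend(x, type="linear")
    else:
        x = x - x.mean()

    npad = int(2 ** np.ceil(np.log2(max(n, 2))))
    X = np.fft.fft(x, npad)
    w = 2 * np.pi * np.fft.fftfreq(npad, dt)
    pos = w > 0
    coeffs = np.empty((len(scales), n), dtype=complex)
    for i, s in enumerate(scales):
        filt = np.zeros(npad)
        filt[pos] = (
            np.pi**-0.25 * np.sqrt(2 * np.pi * s) * np.exp(-((s * w[pos] - config.omega0) ** 2) / 2)
        )
        coeffs[i] = np.fft.ifft(X * filt)[:n]

    t = np.arange(n) * dt
    efold = np.sqrt(2.0) * scales
    coi_mask = (t[None, :] >= efold[:, None]) & ((t[-1] - t[None, :]) >= efold[:, None])
    return ScaleTimePlane(freqs=freqs, scales=scales, dt=dt, coeffs=coeffs, coi_mask=coi_mask)


def _smooth(plane_vals: np.ndarray, scales: np.ndarray, dt: float, cfg: WaveletConfig) -> np.ndarray:
    """Scale-proportional Gaussian smoothing in time, optional boxcar across
    scales."""
    out = np.empty_like(plane_vals)
    for i, s in enumerate(scales):
        sigma = cfg.time_smoothing_scales * s / dt
        if np.iscomplexobj(plane_vals):
            out[i] = gaussian_filter1d(plane_vals[i].real, sigma, mode="nearest") + 1j * gaussian_filter1d(
                plane_vals[i].imag, sigma, mode="nearest"
            )
        else:
            out[i] = gaussian_filter1d(plane_vals[i], sigma, mode="nearest")
    width = max(int(round(cfg.scale_smoothing_octaves * cfg.voices_per_octave)), 1)
    if np.iscomplexobj(out):
        out = uniform_filter1d(out.real, width, axis=0, mode="nearest") + 1j * uniform_filter1d(
            out.imag, width, axis=0, mode="nearest"
        )
    else:
        out = uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


def coherence_phase(
    x_plane: ScaleTimePlane, y_plane: ScaleTimePlane, config: WaveletConfig | None = None
) -> ScaleTimePlane:
    """Smoothed magnitude-squared wavelet coherence and phase difference.

    Phase is ``angle(<W_x * conj(W_y)>)``: positive when y lags x.
    """
    config = config or WaveletConfig()
    if x_plane.coeffs.shape != y_plane.coeffs.shape or not np.allclose(
        x_plane.scales, y_plane.scales
    ):
        raise InputError("scale/epoch grids of the two planes do not match")
    wx, wy = x_plane.coeffs, y_plane.coeffs
    scales, dt = x_plane.scales, x_plane.dt
    # 1/s weighting before smoothing (standard for scale-dependent bias)
    inv_s = 1.0 / scales[:, None]
    sxy = _smooth(wx * np.conj(wy) * inv_s, scales, dt, config)
    sxx = _smooth(np.abs(wx) ** 2 * inv_s, scales, dt, config)
    syy = _smooth(np.abs(wy) ** 2 * inv_s, scales, dt, config)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)
    phase = np.angle(sxy)
    coi = x_plane.coi_mask & y_plane.coi_mask
    return ScaleTimePlane(
        freqs=x_plane.freqs, scales=scales, dt=dt, coherence=coh, phase=phase, coi_mask=coi
    )


def semblance_index(
    series: SlowWaveSeries,
    ch_x: str,
    ch_y: str,
    config: WaveletConfig | None = None,
    name: str | None = None,
) -> IndexSeries:
    """Coherence-gated wavelet semblance index of two channels.

    For each 10-s step the trailing 800-s window is taken; within its central
    300 s (250 s edge-rejected at each end) the cosine of the wavelet phase
    difference is averaged over every in-band scale-time point whose
    coherence reaches the threshold.  Steps whose window has more than 25%
    missing epochs, overhangs the record, or retains no point, are missing.
    """
    config = config or WaveletConfig()
    dt = series.block_s
    x = series[ch_x]
    y = series[ch_y]
    n = len(series)
    nw = int(round(config.window_s / dt))
    if n < nw:
        return IndexSeries(
            name=name or f"semb({ch_x},{ch_y})",
            time_s=series.time_s.copy(),
            values=np.full(n, np.nan),
        )
    trim = int(round(config.edge_reject_s / (2 * dt)))
    central = nw - 2 * trim
    if central < 1:
        raise ConfigurationError("edge rejection leaves no central segment")

    missing = ~(np.isfinite(x) & np.isfinite(y))
    px = cwt_complex(x, dt, config)
    py = cwt_complex(y, dt, config)
    cp = coherence_phase(px, py, config)

    keep = (cp.coherence >= config.coherence_threshold) & ~missing[None, :]
    cosphase = np.cos(cp.phase)
    if config.scale_weighted:
        wgt = cp.scales[:, None] * np.ones_like(cosphase)
    else:
        wgt = np.ones_like(cosphase)
    num_t = np.sum(np.where(keep, cosphase * wgt, 0.0), axis=0)
    den_t = np.sum(np.where(keep, wgt, 0.0), axis=0)

    # Rolling sums over the central segment of each trailing window.
    kern = np.ones(central)
    num_roll = np.convolve(num_t, kern, mode="full")[: len(num_t)]
    den_roll = np.convolve(den_t, kern, mode="full")[: len(den_t)]
    miss_roll = np.convolve(missing.astype(float), np.ones(nw), mode="full")[: len(num_t)]

    values = np.full(n, np.nan)
    max_missing = config.max_missing_frac * nw
    for i in range(nw - 1, n):
        if miss_roll[i] > max_missing:
            continue
        j = i - trim  # end of the central segment (inclusive)
        den = den_roll[j]
        if den > 0:
            values[i] = num_roll[j] / den
    values = np.clip(values, -1.0, 1.0)
    return IndexSeries(
        name=name or f"semb({ch_x},{ch_y})", time_s=series.time_s.copy(), values=values
    )


def wavelet_indices(
    series: SlowWaveSeries, config: WaveletConfig | None = None
) -> dict[str, IndexSeries]:
    """Compute wPRx, wCOx and wHVx from one slow-wave series."""
    config = config or WaveletConfig()
    return {
        nm: semblance_index(series, *INDEX_CHANNELS[nm], config=config, name=nm)
        for nm in WAVELET_INDICES
    }


def dump_plane_hdf5(plane: ScaleTimePlane, path) -> None:
    """Debug dump of a scale-time plane to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("freqs", data=plane.freqs)
        f.create_dataset("scales", data=plane.scales)
        f.attrs["dt"] = plane.dt
        for nm in ("coeffs", "coherence", "phase", "coi_mask"):
            arr = getattr(plane, nm)
            if arr is not None:
                f.create_dataset(nm, data=arr)
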