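"""Autoregulation limits: LLA by piecewise regression, ABPopt by the
multi-window binned-curve method.

LLA
---
The lower limit of autoregulation is read from the laser-Doppler flux vs ABP
relation of the 10-s means: two linear segments are fitted with the lowest
combined squared error over an exhaustive 1-mmHg grid of candidate
breakpoints, and the LLA is the abscissa of the fitted lines' intersection.

ABPopt
------
The optimal ABP is the vertex of the U-shaped curve of a (Fisher-transformed)
autoregulation index against 5-mmHg ABP bins, assembled from 5-min
(median ABP, mean index) samples taken while ABP exceeded the LLA, and
combined across twelve 2-4-h trailing windows with weights favouring short
windows, small curve-fit error, and full U shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import IndexSeries
from .errors import DegenerateIntersectionError, InsufficientDataError
from .preprocess import SlowWaveSeries

FULL_U = "full-U"
HALF_U = "half-U"
NO_SHAPE = "none"


@dataclass
class LLAEstimate:
    """Two-segment regression result for one recording."""

    lla: float                     # mmHg; intersection of the two fitted lines
    left_slope: float
    left_intercept: float
    right_slope: float
    right_intercept: float
    sse: float                     # combined residual sum of squares
    n_left: int
    n_right: int
    breakpoint: float              # mmHg; grid split minimizing the SSE


@dataclass
class BinnedIndexCurve:
    """Fisher-z index means over half-open 5-mmHg ABP bins."""

    bin_edges: np.ndarray          # len nbins+1
    mean_z: np.ndarray             # NaN for empty bins
    sem_z: np.ndarray
    count: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return self.count > 0


@dataclass
class WindowFit:
    """Diagnostics for one multi-window ABPopt window."""

    window_s: float
    vertex: float | None
    fit_error: float | None
    shape: str
    weight: float                  # normalized over contributing windows


@dataclass
class ABPoptEstimate:
    abpopt: float | None
    windows: list[WindowFit] = field(default_factory=list)


def find_lla(
    series: SlowWaveSeries,
    abp_ch: str = "abp",
    flow_ch: str = "ldf",
    grid_mmhg: float = 1.0,
    min_points_per_side: int = 3,
    min_span_mmhg: float = 15.0,
    min_epochs: int = 20,
) -> LLAEstimate:
    """Two-segment piecewise regression of flow on ABP.

    Candidate breakpoints lie on a ``grid_mmhg`` grid across the observed ABP
    range; at each candidate the (ABP-sorted) pairs are split into a lower
    and an upper segment, each fitted by ordinary least squares, and the
    candidate with the lowest summed SSE wins (ties broken toward lower ABP).
    The LLA is where the two fitted lines intersect.
    """
    abp = series[abp_ch]
    flow = series[flow_ch]
    ok = np.isfinite(abp) & np.isfinite(flow)
    abp, flow = abp[ok], flow[ok]
    if len(abp) < min_epochs:
        raise InsufficientDataError(f"only {len(abp)} valid epochs (< {min_epochs})")
    if abp.max() - abp.min() < min_span_mmhg:
        raise InsufficientDataError(
            f"ABP span {abp.max() - abp.min():.1f} mmHg < {min_span_mmhg}"
        )
    order = np.argsort(abp, kind="stable")
    abp, flow = abp[order], flow[order]

    lo = np.ceil(abp.min() / grid_mmhg) * grid_mmhg
    hi = np.floor(abp.max() / grid_mmhg) * grid_mmhg
    candidates = np.arange(lo, hi + grid_mmhg / 2, grid_mmhg)

    best = None
    for b in candidates:
        nl = int(np.searchsorted(abp, b, side="left"))  # ABP < b on the left
        if nl < min_points_per_side or len(abp) - nl < min_points_per_side:
            continue
        fl, rl = _ols(abp[:nl], flow[:nl])
        fr, rr = _ols(abp[nl:], flow[nl:])
        sse = rl + rr
        if best is None or sse < best[0] - 1e-12:  # strict: ties keep lower b
            best = (sse, b, fl, fr, nl)
    if best is None:
        raise InsufficientDataError("no admissible breakpoint (too few points per side)")
    sse, b, (ml, cl), (mr, cr), nl = best
    if abs(ml - mr) < 1e-12:
        raise DegenerateIntersectionError("fitted segments are parallel")
    lla = (cr - cl) / (ml - mr)
    return LLAEstimate(
        lla=float(lla),
        left_slope=float(ml),
        left_intercept=float(cl),
        right_slope=float(mr),
        right_intercept=float(cr),
        sse=float(sse),
        n_left=nl,
        n_right=len(abp) - nl,
        breakpoint=float(b),
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], float]:
    """Least-squares line fit; returns ((slope, intercept), SSE)."""
    if np.ptp(x) == 0.0:  # vertical stack of points: slope 0 through the mean
        resid = y - y.mean()
        return (0.0, float(y.mean())), float(resid @ resid)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return (float(slope), float(intercept)), float(resid @ resid)


def median_abp_epochs(
    series: SlowWaveSeries,
    index: IndexSeries,
    window_s: float = 300.0,
    abp_ch: str = "abp",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per non-overlapping 5-min window: (median ABP, mean index, window end time).

    Windows with no valid ABP or no valid index value are dropped.  Empty
    input yields empty arrays.
    """
    abp = series[abp_ch]
    if len(index) != len(series):
        raise InsufficientDataError("index and series are not aligned")
    per = max(int(round(window_s / series.block_s)), 1)
    n_win = len(series) // per
    med, mean_idx, t_end = [], [], []
    for k in range(n_win):
        sl = slice(k * per, (k + 1) * per)
        a = abp[sl]
        v = index.values[sl]
        a = a[np.isfinite(a)]
        v = v[np.isfinite(v)]
        if a.size == 0 or v.size == 0:
            continue
        med.append(float(np.median(a)))
        mean_idx.append(float(v.mean()))
        t_end.append(float(series.time_s[sl][-1]))
    return np.asarray(med), np.asarray(mean_idx), np.asarray(t_end)


def bin_index_curve(
    abp_samples: np.ndarray,
    index_samples: np.ndarray,
    bin_width: float = 5.0,
    abp_range: tuple[float, float] = (20.0, 100.0),
    clip_r: float = 0.99,
) -> BinnedIndexCurve:
    """Sort (ABP, index) samples into half-open 5-mmHg bins of Fisher-z values.

    Index values are clipped to ``|r| <= clip_r`` before ``atanh`` so the
    transform stays finite; samples outside ``abp_range`` are discarded.
    """
    abp = np.asarray(abp_samples, dtype=float)
    r = np.asarray(index_samples, dtype=float)
    ok = np.isfinite(abp) & np.isfinite(r) & (abp >= abp_range[0]) & (abp < abp_range[1])
    abp, r = abp[ok], r[ok]
    z = np.arctanh(np.clip(r, -clip_r, clip_r))

    edges = np.arange(abp_range[0], abp_range[1] + bin_width / 2, bin_width)
    nb = len(edges) - 1
    mean_z = np.full(nb, np.nan)
    sem_z = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    which = np.floor((abp - abp_range[0]) / bin_width).astype(int)
    for k in range(nb):
        zb = z[which == k]
        count[k] = zb.size
        if zb.size:
            mean_z[k] = zb.mean()
            sem_z[k] = zb.std(ddof=1) / np.sqrt(zb.size) if zb.size > 1 else 0.0
    return BinnedIndexCurve(bin_edges=edges, mean_z=mean_z, sem_z=sem_z, count=count)


def fit_u_vertex(
    curve: BinnedIndexCurve, min_bins: int = 4
) -> tuple[float | None, float | None, str]:
    """Count-weighted quadratic fit through the occupied bins.

    Returns ``(vertex, fit_error, shape)``: *full-U* when curvature is
    positive and the vertex lies strictly inside the occupied span; *half-U*
    when curvature is positive but the vertex falls at or beyond the span
    edge (the vertex is then clamped to the nearest occupied bin center);
    *none* otherwise.  ``fit_error`` is the RMS difference between bin means
    and fitted values over occupied bins.
    """
    occ = curve.occupied
    if int(occ.sum()) < min_bins:
        return None, None, NO_SHAPE
    x = curve.centers[occ]
    zbar = curve.mean_z[occ]
    wts = np.sqrt(curve.count[occ].astype(float))  # residuals weighted by sqrt(n) => n-weighted SSE
    a, b, c = np.polyfit(x, zbar, 2, w=wts)
    fitted = a * x**2 + b * x + c
    fit_error = float(np.sqrt(np.mean((zbar - fitted) ** 2)))
    if a <= 0:
        return None, fit_error, NO_SHAPE
    vertex = -b / (2 * a)
    if x.min() < vertex < x.max():
        return float(vertex), fit_error, FULL_U
    clamped = float(x[np.argmin(np.abs(x - vertex))])
    return clamped, fit_error, HALF_U


def default_weights(window_s: float, fit_error: float, shape: str,
                    min_window_s: float = 7200.0, max_window_s: float = 14400.0) -> float:
    """Combined multi-window weight: shorter windows, smaller fit errors and
    full U shapes count more.

    ``w = w_len * w_err * w_shape`` with ``w_len`` linear from 1.0 (shortest
    window) to 0.5 (longest), ``w_err = 1/(1 + fit_error)`` in z units, and
    ``w_shape`` 1.0 / 0.5 / 0 for full-U / half-U / no shape.
    """
    span = max(max_window_s - min_window_s, 1e-9)
    w_len = 1.0 - 0.5 * (np.clip(window_s, min_window_s, max_window_s) - min_window_s) / span
    w_shape = {FULL_U: 1.0, HALF_U: 0.5, NO_SHAPE: 0.0}[shape]
    if shape == NO_SHAPE:
        return 0.0
    w_err = 1.0 / (1.0 + fit_error)
    return float(w_len * w_err * w_shape)


def multiwindow_abpopt(
    index: IndexSeries,
    series: SlowWaveSeries,
    lla: float,
    n_windows: int = 12,
    min_window_s: float = 7200.0,
    max_window_s: float = 14400.0,
    bin_width: float = 5.0,
    abp_range: tuple[float, float] = (20.0, 100.0),
    abp_ch: str = "abp",
    weight_fn=default_weights,
) -> ABPoptEstimate:
    """Weighted multi-window ABPopt from one index, using only epochs with
    ABP above the LLA.

    Twelve trailing windows with lengths uniform between 2 and 4 h (anchored
    at the last above-LLA sample; shorter records truncate the longer
    windows) each produce a binned U-curve and vertex; the final ABPopt is
    the weight-normalized average of the vertices of the windows that
    produced one, or missing if none did.
    """
    abp = series[abp_ch]
    above = np.isfinite(abp) & (abp > lla)
    masked_idx = IndexSeries(
        name=index.name,
        time_s=index.time_s,
        values=np.where(above, index.values, np.nan),
    )
    masked_series = SlowWaveSeries(
        time_s=series.time_s,
        channels={abp_ch: np.where(above, abp, np.nan)},
        block_s=series.block_s,
    )
    valid_above = above & np.isfinite(index.values)
    if not valid_above.any():
        raise InsufficientDataError("no valid index epochs above the LLA")
    t_valid = series.time_s[valid_above]
    if t_valid[-1] - t_valid[0] < min_window_s:
        raise InsufficientDataError(
            f"above-LLA index span {t_valid[-1] - t_valid[0]:.0f} s < {min_window_s:.0f} s"
        )

    med, mean_idx, t_end = median_abp_epochs(masked_series, masked_idx, abp_ch=abp_ch)
    anchor = t_valid[-1]

    lengths = np.linspace(min_window_s, max_window_s, n_windows)
    fits: list[WindowFit] = []
    for L in lengths:
        sel = t_end > anchor - L
        curve = bin_index_curve(
            med[sel], mean_idx[sel], bin_width=bin_width, abp_range=abp_range
        )
        vertex, fit_error, shape = fit_u_vertex(curve)
        w = weight_fn(L, fit_error if fit_error is not None else np.inf, shape,
                      min_window_s=min_window_s, max_window_s=max_window_s) if vertex is not None else 0.0
        fits.append(WindowFit(window_s=float(L), vertex=vertex, fit_error=fit_error,
                              shape=shape, weight=float(w)))

    total = sum(f.weight for f in fits)
    if total <= 0:
        for f in fits:
            f.weight = 0.0
        return ABPoptEstimate(abpopt=None, windows=fits)
    for f in fits:
        f.weight /= total
    abpopt = sum(f.weight * f.vertex for f in fits if f.vertex is not None and f.weight > 0)
    return ABPoptEstimate(abpopt=float(abpopt), windows=fits)
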