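# Methods

This note documents the models, estimators and numerical choices behind
`autoreg`, and what the synthetic experiments do and do not establish.

## Signal model and preprocessing

All analysis operates on **consecutive, non-overlapping 10-second means** of
the sampled channels (ABP, ICP, rSO₂, rTHb, LDF). Ten-second averaging
removes pulse and respiratory waveforms and leaves the slow vasogenic
oscillations (0.007–0.05 Hz) that carry autoregulatory information; the
resulting epoch series has a 0.1 Hz sampling rate, which places the upper
edge of the analysis band exactly at its Nyquist frequency. A trailing
partial block is discarded rather than padded, and any invalid (NaN) sample
inside a block marks the whole epoch missing — epochs are cheap and
conservative exclusion is safer than imputation. Epoch timestamps mark the
block end. No artifact repair or detrending is performed at this stage;
trends are handled inside the index estimators.

## Correlation indices (PRx, COx, HVx)

Each index is the Pearson correlation of two channels' 10-s means over a
trailing window of 30 epochs (300 s), advanced one epoch (10 s) per step and
timestamped at the window end. The 10-s step is chosen so correlation and
wavelet indices share a common timestamp grid for paired statistics. Windows
with more than 25% missing epochs emit a missing value; remaining missing
epochs are excluded pairwise. A zero-variance channel in a window yields a
missing value, not an exception — flat segments are a data condition, not a
programming error.

## Wavelet semblance indices (wPRx, wCOx, wHVx)

### Transform

The continuous wavelet transform uses the analytic Morlet wavelet with
center parameter ω₀ = 6, implemented as a frequency-domain filter bank

    W(s, t) = IFFT[ X(ω) · π^(-1/4) · √(2πs) · exp(−(sω − ω₀)²/2) ],  ω > 0,

which approximates the continuous transform s^(−1/2)∫x(u)ψ*((u−t)/s)du
with the unit-energy Morlet. The frequency-domain form is exact for the
Gaussian spectral envelope at *any* scale; discretized time-domain
convolution of a sampled wavelet degrades badly at the band's upper edge,
where the scale is about two epoch samples (we measured ~87% magnitude error
for an available time-domain implementation there, against a direct
numerical-integration oracle, which is why the transform is computed
in-package). Scale-to-frequency conversion uses the standard Morlet Fourier
factor 4π/(ω₀ + √(2 + ω₀²)). The scale grid spans 0.007–0.05 Hz at 12
voices per octave (35 scales). Signals are linearly detrended (the induced
hypotension ramp would otherwise wrap around the FFT boundary) and
zero-padded to the next power of two; missing epochs are linearly
interpolated for the transform only, while the missing-data accounting is
kept separately. A cone-of-influence mask records points within the
e-folding time √2·s of either record end.

### Coherence and phase

Magnitude-squared coherence is computed from the smoothed cross-spectrum
with the usual 1/s scale weighting. Some smoothing is mandatory — unsmoothed
wavelet coherence is identically 1 — and the kernel's strength fixes the
operating characteristics of the 0.46 reliability threshold. The default is
a scale-proportional Gaussian in time with σ = 0.2·s and **no** cross-scale
smoothing. Two stronger alternatives were evaluated and rejected:

* a 0.6-octave boxcar across scales adds almost no independent averaging
  (adjacent 1/12-octave voices of an ω₀ = 6 Morlet are largely redundant)
  while correlating the retained points, so whole scale bands pass or fail
  the gate together;
* heavy time smoothing (σ ≈ 1–3·s) makes the gate nearly binary: the points
  it retains are clean ±1 phase clusters, the semblance saturates at the
  extremes, and on this generator the wavelet indices become *more*
  variable than the correlation indices — inverting the phenomenon the
  method exists to produce.

With the light default kernel the gate acts as a mild reliability filter:
most scale-time points pass, unreliable phases are partially rejected, and
the scale-and-time average over the remaining points suppresses phase noise.
Both knobs (`time_smoothing_scales`, `scale_smoothing_octaves`) are exposed
in `WaveletConfig`; the threshold 0.46 is used as given and its calibration
against any particular smoothing kernel is explicitly *not* reproduced here.

Phase is the argument of the smoothed cross-spectrum with the convention
that y lagging x gives positive phase (a 12.5-s delay of a 0.02-Hz signal
appears as +π/2 at the matching scale).

### Windowing and averaging

The semblance index steps every 10 s over trailing 800-s windows; the outer
250 s at each end of a window are edge-rejected, leaving a central 300-s
segment — the same effective support as the correlation window. Within that
segment, cos(phase) is averaged (unweighted by default; scale weighting is
available) over every in-band scale-epoch point whose coherence reaches the
threshold. A step is missing when its window has >25% missing epochs,
overhangs the record, or retains no point. The transform and coherence are
computed once over the whole record rather than once per window: the 250-s
trim exists precisely to discard window-edge effects, and the Morlet
e-folding time at the largest in-band scale (~195 s) is inside the trim, so
the central segment of a windowed transform coincides with the same segment
of the full-record transform away from the record ends. One consequence of
trailing windows with symmetric trimming is that a step timestamped t
summarizes data centered near t − 400 s; on a slow hypotension ramp this is
a ~1–2 mmHg offset and is accepted as the cost of causal (real-time-like)
timestamps.

## Lower limit of autoregulation

The LLA is estimated from the (ABP, LDF) pairs of the 10-s means:
candidates on a 1-mmHg grid across the observed ABP range split the
ABP-sorted pairs into a lower and an upper segment (each with ≥3 points);
ordinary least squares is fitted per side; the candidate with minimal
combined SSE wins, with ties broken toward the lower ABP (a conservative
LLA); the estimate is the abscissa of the two lines' intersection.
Preconditions: ≥20 valid epochs and ≥15 mmHg of ABP span. Near-parallel
fitted lines (|Δslope| < 1e−12) raise a degenerate-intersection error — a
single straight line has no breakpoint. Pairs are ABP-sorted rather than
time-ordered: the Lassen relation is a function of pressure, not of time,
and sorting makes the split a one-dimensional search.

## Optimal ABP (multi-window method)

Only epochs with ABP strictly above the estimated LLA participate. Per
non-overlapping 5-min window the median ABP is paired with the mean of the
valid index values; samples are sorted into half-open 5-mmHg bins on
[20, 100) mmHg; index values are clipped to |r| ≤ 0.99 before the Fisher
transform z = atanh(r) (bounding the influence of saturated values; atanh
diverges at ±1). A quadratic is fitted through the occupied bins' (center,
mean z) points, weighted by bin count, provided ≥4 bins are occupied. Shape
classification: *full-U* for positive curvature with the vertex strictly
inside the occupied span; *half-U* for positive curvature with the vertex at
or beyond the span edge (the vertex is then clamped to the nearest occupied
bin center); *none* otherwise. The curve-fit error is the RMS difference
between bin means and fitted values over occupied bins, so it is zero
exactly when the bin means lie on the quadratic.

Twelve windows with lengths uniform from 2 h to 4 h, anchored at the last
valid above-LLA sample (shorter records truncate the longer windows), each
produce a vertex and a weight

    w = w_len · w_err · w_shape,
    w_len  = 1.0 at 2 h declining linearly to 0.5 at 4 h,
    w_err  = 1 / (1 + fit_error)          [z units],
    w_shape = 1.0 (full-U), 0.5 (half-U), 0 (none),

and the final ABPopt is the weight-normalized average of the contributing
vertices, or missing when no window yields one. The weight components are
declared package defaults (any non-negative alternative is pluggable via
`weight_fn`): shorter windows track nonstationary physiology, smaller fit
errors indicate more trustworthy curves, and shapeless fits carry no vertex
information. One ABPopt is produced per recording (evaluated at the record
end); a continuously updating trace is out of scope.

## Evaluation statistics

The study design is **paired within animal**: each recording contributes one
mean index value over all epochs with ABP above its LLA and one over all
epochs below, per index. ROC analyses for discriminating below- from
above-LLA states operate on these per-animal means (two observations per
animal), not on pooled epochs. AUC is the trapezoidal/Mann-Whitney statistic
with half-credit ties; the operating cutoff maximizes Youden's J;
sensitivity/specificity at the cutoff carry Clopper-Pearson exact 95% CIs
(the binomial method chosen here; none is mandated by the design). AUC
difference tests between paired indices use DeLong's structural-component
covariance for correlated ROC curves, and each AUC's significance against
0.5 is a z-test on its own DeLong variance (a documented package choice).
Index variability is summarized per animal as the SD of the index over
above-LLA epochs, and wavelet-correlation pairs are compared by paired t
tests across animals. Method agreement uses Pearson correlation plus
Bland-Altman bias and 95% limits of agreement (bias ± 1.96·SD of paired
differences).

## Synthetic piglet recordings

The generator emulates a hypotension experiment: ABP declines linearly
(default 80 → 30 mmHg over 4 h; the cohort design uses 85 → 30 over 5 h)
across a known LLA, carrying band-limited slow waves — a sum of 12
log-spaced in-band sinusoids with random phases, per-component amplitude
amp/√n so the summed RMS is amp/√2 (default amp 4.5 mmHg). Flow follows a
Lassen curve: constant at the plateau above the LLA, linearly
pressure-passive below (2 a.u./mmHg), floored at zero.

Vasoreactive coupling is the scientifically load-bearing part:

* **Above the LLA** blood volume (rTHb), ICP and a small rSO₂ component
  respond *against* slow ABP fluctuations through a first-order lag
  (default τ = 20 s). The lag matters: real vasomotor responses take tens of
  seconds, which leaves a frequency-dependent phase shift across the band.
  An instantaneous coupling puts every coherent point at exactly π, the
  gated semblance saturates at −1, and the wavelet indices come out *more*
  variable than the correlation indices — with the lag, phases spread over
  roughly 0.6π–0.9π across scales and both index families occupy comparable
  dynamic ranges, as they do in animal recordings.
* **Below the LLA** pressure transmits immediately and in phase into volume
  (passive gain equal to the active gain). The sign flip is blended by a
  logistic of 2-mmHg width so no discontinuity artifact sits at the LLA.
* The active gain is modulated by a Gaussian in ABP centered at
  `abpopt_true` (width 8 mmHg), planting the U-shaped index-vs-ABP curve
  whose vertex the multi-window estimator must recover. Reactivity strength
  genuinely varying with distance from an optimum is the premise of
  optimal-ABP monitoring; its Gaussian form and width here are free
  parameters, not measurements.

rSO₂ = 50 + 20·(LDF − plateau)/plateau plus the small vasoreactive term,
clamped to [0, 100] %; ICP baseline is 10 mmHg (experimental cohorts report
mean ICP ≤ 15 mmHg); rTHb is in arbitrary units around a baseline of 50.
White Gaussian measurement noise is added per channel (defaults 1.5, 2.5,
4.0, 9.0, 3.0 for ABP/ICP/rSO₂/rTHb/LDF in channel units), calibrated once
so the windowed correlation indices sit in the moderately-negative /
strongly-positive regimes seen above/below the LLA in piglet recordings,
with above-LLA index SDs around 0.3. Optional generator features — slow-wave
amplitude modulation (wave trains), independent in-band slow activity,
aliased mid-band interference, and step artifacts — are available in the
config but off by default.

Signals are generated at 1 Hz and sample-held to the declared rate; all
analysis consumes 10-s means, so sub-second morphology (pulse, respiration)
is deliberately absent. Generation is bit-reproducible for a fixed seed.

The **cohort design** used by `run_cohort` and the acceptance script draws
each animal's LLA uniformly from 35–55 mmHg, plants the optimum 15 mmHg
above it, and uses 5-h recordings so that even the highest-LLA animals
retain more than the 2 h of above-LLA data the multi-window ABPopt
precondition requires. Per-animal seeds derive deterministically from the
master seed via `SeedSequence`.

### What the synthetic experiments do not show

The generator's couplings are piecewise-linear fictions with stationary
noise; real recordings contain nonstationary physiology, shared confounders
(CO₂, hemoglobin, temperature), vendor-specific NIRS processing, and
artifact structure none of which are modeled. Passing recovery tests
demonstrates that the estimators are implemented correctly and behave as
designed under the stated model — not that they are accurate on animal or
patient data. Discrimination statistics on the synthetic cohort (AUCs near
1) are cleaner than any real cohort's because the ground-truth regimes are
exactly two well-separated states. The upper limit of autoregulation is
neither simulated nor estimated.

## Numerical choices and degenerate inputs

* Pearson correlation of a constant vector: missing value (logged), never an
  exception; computed values are clipped to [−1, 1] against rounding.
* Fisher clipping bound 0.99; half-open bins [lo, hi); samples outside
  [20, 100) mmHg discarded.
* Breakpoint ties: first (lowest-ABP) candidate wins via strict-improvement
  comparison with a 1e−12 guard.
* DeLong test of identical score vectors returns (0, 0, 1); zero variance
  with a nonzero AUC difference raises a degenerate-variance error, as does
  a paired t test on a constant nonzero difference.
* Coherence is clipped to [0, 1] after division (the smoothed estimator
  satisfies Cauchy-Schwarz up to rounding).
* JSON/CSV artifacts embed the run-config hash and master seed; recording
  CSVs store 12 significant digits so a write-read round trip reproduces
  values to better than 1e−9.

## Problem sizes

Default experiments are desk-scale by construction: recordings are generated
at 1 Hz (4–5 h ≈ 14–18 k samples, 1440–1800 epochs), the standard cohort is
30 animals, and the parameter-recovery suite uses 50 recordings. The full
test suite and the acceptance script each run in well under a minute on one
CPU.
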