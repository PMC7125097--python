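import numpy as np
import pytest

from autoreg import (
    DegenerateIntersectionError,
    IndexSeries,
    InsufficientDataError,
    SlowWaveSeries,
    bin_index_curve,
    find_lla,
    fit_u_vertex,
    lassen_flow,
    median_abp_epochs,
    multiwindow_abpopt,
)
from autoreg.limits import FULL_U, HALF_U, NO_SHAPE, default_weights


def series_from(abp, ldf=None, **extra):
    n = len(abp)
    ch = {"abp": np.asarray(abp, float)}
    if ldf is not None:
        ch["ldf"] = np.asarray(ldf, float)
    ch.update({k: np.asarray(v, float) for k, v in extra.items()})
    return SlowWaveSeries(time_s=(np.arange(n) + 1) * 10.0, channels=ch)


class TestFindLLA:
    def test_exact_piecewise_linear_input(self):
        abp = np.linspace(30, 70, 200)
        ldf = np.where(abp >= 45, 90.0, 2.0 * abp)
        est = find_lla(series_from(abp, ldf))
        assert est.lla == pytest.approx(45.0, abs=1e-6)
        assert est.sse == pytest.approx(0.0, abs=1e-12)

    def test_straight_line_has_no_breakpoint(self):
        abp = np.linspace(30, 70, 100)
        with pytest.raises(DegenerateIntersectionError):
            find_lla(series_from(abp, 2.0 * abp + 1.0))

    def test_matches_independent_grid_scan_oracle(self, rng):
        """Noisy Lassen data (true LLA 48): same breakpoint, lines and LLA
        as a from-scratch scan over the same 1-mmHg candidate grid."""
        abp = rng.uniform(30, 75, 400)
        ldf = lassen_flow(abp, 48.0, 100.0, 2.0) + rng.normal(0, 1.0, 400)
        est = find_lla(series_from(abp, ldf))

        order = np.argsort(abp, kind="stable")
        a, f = abp[order], ldf[order]
        best = None
        for b in np.arange(np.ceil(a.min()), np.floor(a.max()) + 0.5, 1.0):
            left = a < b
            if left.sum() < 3 or (~left).sum() < 3:
                continue
            sse = 0.0
            fits = []
            for m in (left, ~left):
                X = np.vstack([a[m], np.ones(m.sum())]).T
                beta, res, *_ = np.linalg.lstsq(X, f[m], rcond=None)
                sse += float(((f[m] - X @ beta) ** 2).sum())
                fits.append(beta)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, b, fits)
        (ml, cl), (mr, cr) = best[2]
        lla_oracle = (cr - cl) / (ml - mr)
        assert est.breakpoint == pytest.approx(best[1], abs=1e-9)
        assert est.lla == pytest.approx(lla_oracle, abs=1e-9)
        assert est.sse == pytest.approx(best[0], rel=1e-9)
        assert abs(est.lla - 48.0) < 2.0

    def test_insufficient_span_raises(self):
        abp = np.linspace(50, 60, 100)
        with pytest.raises(InsufficientDataError):
            find_lla(series_from(abp, 2 * abp))

    def test_too_few_epochs_raises(self):
        abp = np.linspace(30, 70, 10)
        with pytest.raises(InsufficientDataError):
            find_lla(series_from(abp, 2 * abp))


class TestMedianAbpEpochs:
    def test_constant_abp_median(self):
        s = series_from(np.full(90, 60.0))
        idx = IndexSeries("i", s.time_s, np.zeros(90))
        med, mi, te = median_abp_epochs(s, idx)
        assert np.all(med == 60.0)
        assert len(med) == 3

    def test_odd_count_median(self):
        abp = np.tile([40.0, 50.0, 60.0, 70.0, 80.0], 6)
        s = series_from(abp)
        idx = IndexSeries("i", s.time_s, np.zeros(30))
        med, _, _ = median_abp_epochs(s, idx)
        assert med[0] == 60.0

    def test_matches_sorting_oracle(self, rng):
        abp = rng.uniform(30, 80, 120)
        vals = rng.uniform(-1, 1, 120)
        s = series_from(abp)
        idx = IndexSeries("i", s.time_s, vals)
        med, mi, _ = median_abp_epochs(s, idx)
        for k in range(4):
            block = slice(k * 30, (k + 1) * 30)
            assert med[k] == pytest.approx(np.sort(abp[block])[14:16].mean(), abs=1e-12)
            assert mi[k] == pytest.approx(vals[block].mean(), abs=1e-12)

    def test_empty_input_gives_empty_output(self):
        s = series_from(np.full(10, np.nan))
        idx = IndexSeries("i", s.time_s, np.full(10, np.nan))
        med, mi, te = median_abp_epochs(s, idx, window_s=100.0)
        assert med.size == 0


class TestBinnedCurve:
    def test_single_bin_arithmetic(self):
        curve = bin_index_curve(np.array([52.0, 53.0]), np.array([0.5, 0.5]))
        k = int(np.searchsorted(curve.bin_edges, 52.0, side="right")) - 1
        assert curve.count[k] == 2
        assert curve.mean_z[k] == pytest.approx(np.arctanh(0.5))

    def test_saturated_index_clipped_before_atanh(self):
        curve = bin_index_curve(np.array([52.0]), np.array([1.0]))
        k = 6  # [50, 55)
        assert np.isfinite(curve.mean_z[k])
        assert curve.mean_z[k] == pytest.approx(np.arctanh(0.99))

    def test_samples_outside_range_discarded(self):
        curve = bin_index_curve(np.array([10.0, 150.0, 60.0]), np.array([0.1, 0.2, 0.3]))
        assert curve.count.sum() == 1

    def test_matches_grouping_oracle(self, rng):
        abp = rng.uniform(20, 100, 300)
        r = rng.uniform(-0.99, 0.99, 300)
        curve = bin_index_curve(abp, r)
        z = np.arctanh(np.clip(r, -0.99, 0.99))
        for k, lo in enumerate(np.arange(20.0, 100.0, 5.0)):
            m = (abp >= lo) & (abp < lo + 5.0)
            assert curve.count[k] == m.sum()
            if m.any():
                assert curve.mean_z[k] == pytest.approx(z[m].mean(), abs=1e-12)


class TestUVertex:
    def test_exact_parabola(self):
        # scaled so the Fisher round trip tanh/atanh stays below the 0.99 clip
        centers = np.arange(32.5, 80.0, 5.0)
        z = (centers - 50.0) ** 2 / 400.0
        curve = bin_index_curve(
            np.repeat(centers, 2), np.repeat(np.tanh(z), 2)
        )
        vertex, err, shape = fit_u_vertex(curve)
        assert shape == FULL_U
        assert vertex == pytest.approx(50.0, abs=1e-6)
        assert err == pytest.approx(0.0, abs=1e-9)

    def test_monotone_line_has_no_vertex(self):
        centers = np.arange(32.5, 80.0, 5.0)
        z = 1.0 - 0.02 * centers
        curve = bin_index_curve(centers, np.tanh(z))
        vertex, err, shape = fit_u_vertex(curve)
        assert shape == NO_SHAPE and vertex is None

    def test_half_u_vertex_clamped_to_span(self):
        centers = np.arange(52.5, 100.0, 5.0)
        z = (centers - 45.0) ** 2 / 1500.0  # minimum left of the observed span
        curve = bin_index_curve(centers, np.tanh(z))
        vertex, _, shape = fit_u_vertex(curve)
        assert shape == HALF_U
        assert vertex == pytest.approx(centers.min())

    def test_matches_normal_equations_oracle(self, rng):
        abp = rng.uniform(25, 95, 200)
        z_true = (abp - 55.0) ** 2 / 150.0 - 0.5
        r = np.tanh(z_true + rng.normal(0, 0.1, 200))
        curve = bin_index_curve(abp, r)
        vertex, err, shape = fit_u_vertex(curve)

        occ = curve.occupied
        x, zb, w = curve.centers[occ], curve.mean_z[occ], curve.count[occ].astype(float)
        V = np.vstack([x**2, x, np.ones_like(x)]).T
        A = V.T @ (w[:, None] * V)
        b = V.T @ (w * zb)
        a2, a1, _ = np.linalg.solve(A, b)
        assert shape == FULL_U
        assert vertex == pytest.approx(-a1 / (2 * a2), abs=1e-9)

    def test_fit_error_zero_iff_on_quadratic(self, rng):
        # already exact in test_exact_parabola; perturb one bin -> error > 0
        centers = np.arange(32.5, 80.0, 5.0)
        r = np.tanh((centers - 50.0) ** 2 / 100.0)
        r[3] = np.tanh(0.9)
        curve = bin_index_curve(centers, r)
        _, err, _ = fit_u_vertex(curve)
        assert err > 1e-6

    def test_too_few_bins_no_fit(self):
        curve = bin_index_curve(np.array([52.0, 57.0, 62.0]), np.array([0.1, 0.0, 0.1]))
        assert fit_u_vertex(curve) == (None, None, NO_SHAPE)


def u_shaped_series(n_epochs=1800, opt=60.0, seed=0):
    """Above-LLA data whose binned index curve is a time-invariant U.

    ABP sweeps slowly (so 5-min medians trace the full range) while the
    index is a fixed function of ABP plus small noise.
    """
    rng = np.random.default_rng(seed)
    t = (np.arange(n_epochs) + 1) * 10.0
    abp = 65.0 + 18.0 * np.sin(2 * np.pi * t / 5400.0) + rng.normal(0, 0.3, n_epochs)
    r = np.tanh((abp - opt) ** 2 / 200.0 - 0.8) + rng.normal(0, 0.02, n_epochs)
    s = series_from(abp)
    idx = IndexSeries("i", s.time_s, np.clip(r, -1, 1))
    return s, idx


class TestMultiwindow:
    def test_stationary_u_curve_recovers_common_vertex(self):
        s, idx = u_shaped_series()
        est = multiwindow_abpopt(idx, s, lla=45.0)
        vertices = [w.vertex for w in est.windows if w.vertex is not None]
        assert len(vertices) == 12
        assert est.abpopt == pytest.approx(60.0, abs=2.0)
        # unanimity: weighted average sits inside the vertex range
        assert min(vertices) - 1e-9 <= est.abpopt <= max(vertices) + 1e-9

    def test_weights_normalized_over_contributing_windows(self):
        s, idx = u_shaped_series(seed=1)
        est = multiwindow_abpopt(idx, s, lla=45.0)
        wsum = sum(w.weight for w in est.windows)
        assert wsum == pytest.approx(1.0, abs=1e-9)
        assert all(w.weight >= 0 for w in est.windows)

    def test_matches_componentwise_recomputation_oracle(self):
        """Final ABPopt equals the hand-assembled weighted mean of the
        per-window vertices under the declared weight formula."""
        s, idx = u_shaped_series(seed=2)
        est = multiwindow_abpopt(idx, s, lla=45.0)
        num = den = 0.0
        for w in est.windows:
            if w.vertex is None:
                continue
            raw = default_weights(w.window_s, w.fit_error, w.shape)
            num += raw * w.vertex
            den += raw
        assert est.abpopt == pytest.approx(num / den, abs=1e-9)

    def test_equal_weight_mean_of_two_vertices(self):
        """With a constant weight function the estimate is the plain mean of
        the contributing window vertices."""
        s, idx = u_shaped_series(seed=3)
        flat = lambda *a, **k: 1.0
        est = multiwindow_abpopt(idx, s, lla=45.0, weight_fn=flat)
        vertices = [w.vertex for w in est.windows if w.vertex is not None]
        assert est.abpopt == pytest.approx(np.mean(vertices), abs=1e-9)

    def test_insufficient_above_lla_data_raises(self):
        s, idx = u_shaped_series(n_epochs=400)  # ~67 min of data
        with pytest.raises(InsufficientDataError):
            multiwindow_abpopt(idx, s, lla=45.0)

    def test_below_lla_epochs_excluded(self):
        s, idx = u_shaped_series(seed=4)
        # poison epochs below a raised LLA with extreme values; they must not
        # affect the estimate computed above that LLA
        abp = s["abp"]
        poisoned = idx.values.copy()
        poisoned[abp <= 55.0] = 0.99
        est_a = multiwindow_abpopt(idx, s, lla=55.0)
        est_b = multiwindow_abpopt(
            IndexSeries("i", idx.time_s, poisoned), s, lla=55.0
        )
        assert est_a.abpopt == pytest.approx(est_b.abpopt, abs=1e-9)


def test_default_weights_behavior():
    assert default_weights(7200.0, 0.0, FULL_U) == pytest.approx(1.0)
    assert default_weights(14400.0, 0.0, FULL_U) == pytest.approx(0.5)
    assert default_weights(7200.0, 1.0, FULL_U) == pytest.approx(0.5)
    assert default_weights(7200.0, 0.0, HALF_U) == pytest.approx(0.5)
    assert default_weights(7200.0, 0.0, NO_SHAPE) == 0.0
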