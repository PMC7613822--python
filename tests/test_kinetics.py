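"""Calibration, rate estimation, ratio-based rate conversion, optima."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydromine.kinetics import (
    AssayTimeSeries,
    CalibrationCurve,
    Condition,
    convert_rate,
    fit_calibration,
    fold_change,
    initial_rate,
    optimum_map,
    quantify,
)
from hydromine.synthetic_data import AssayConfig, gen_assay


def ols_normal_equations(x, y):
    """Closed-form OLS oracle via the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[0], beta[1]


class TestCalibration:
    def test_exact_line(self):
        pts = [(c, 2 * c + 0.1) for c in (0, 5, 10, 20, 40)]
        curve = fit_calibration(pts, "TPA")
        assert curve.slope == pytest.approx(2)
        assert curve.intercept == pytest.approx(0.1)
        assert curve.r2 == pytest.approx(1)

    def test_noisy_standards_recover_slope_within_three_se(self):
        rng = np.random.default_rng(42)
        conc = np.repeat(np.arange(0, 110, 10.0), 3)
        slope, sigma = 0.017, 0.01
        pts = list(zip(conc, slope * conc + rng.normal(0, sigma, size=conc.size)))
        curve = fit_calibration(pts, "TPA")
        se = sigma / np.sqrt(np.sum((conc - conc.mean()) ** 2))
        assert abs(curve.slope - slope) < 3 * se

    def test_duplicate_concentrations_match_normal_equations(self):
        pts = [(0, 0.02), (0, -0.01), (10, 0.19), (10, 0.21), (20, 0.38)]
        curve = fit_calibration(pts, "MHET")
        slope, intercept = ols_normal_equations(*zip(*pts))
        assert curve.slope == pytest.approx(slope)
        assert curve.intercept == pytest.approx(intercept)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(5, 1), (5, 2)])


class TestQuantify:
    def test_intercept_signal_maps_to_zero(self):
        curve = CalibrationCurve("TPA", slope=2.0, intercept=0.1, r2=1.0, n_points=5)
        assert quantify(0.1, curve) == (0.0, False)

    def test_round_trip_identity(self):
        curve = CalibrationCurve("TPA", slope=0.017, intercept=0.01, r2=1.0, n_points=5)
        for c in (0.0, 1.0, 37.5, 500.0):
            got, flagged = quantify(curve.predict(c), curve)
            assert got == pytest.approx(c) and not flagged

    def test_negative_floored_and_flagged(self):
        curve = CalibrationCurve("TPA", slope=2.0, intercept=0.5, r2=1.0, n_points=5)
        assert quantify(0.2, curve) == (0.0, True)


class TestInitialRate:
    def test_exact_linear_series(self):
        times = tuple(float(t) for t in range(0, 40, 4))
        cond = Condition(temperature=37.0)
        ts = AssayTimeSeries(cond, times, tuple(0.01 * t + 0.05 for t in times))
        slope, r2 = initial_rate(ts)
        assert slope == pytest.approx(0.01)
        assert r2 == pytest.approx(1.0)

    def test_linear_then_plateau_recovers_linear_phase(self):
        cfg = AssayConfig(sigma=0.0)
        _, series, manifest = gen_assay(cfg, seed=2)
        slope, _ = initial_rate(series)  # default window = first 25% < t_sat
        assert slope == pytest.approx(manifest.assay["a260_rate_linear"], rel=0.05)

    def test_constant_signal_zero_slope(self):
        ts = AssayTimeSeries(Condition(37.0), (0.0, 1.0, 2.0, 3.0), (0.2,) * 4)
        assert initial_rate(ts)[0] == 0.0

    def test_window_needs_three_points(self):
        ts = AssayTimeSeries(Condition(37.0), (0.0, 1.0, 5.0), (0.0, 0.1, 0.5))
        with pytest.raises(ValueError):
            initial_rate(ts, window=1.5)


class TestConvertRate:
    TPA = CalibrationCurve("TPA", slope=0.017, intercept=0.0, r2=1.0, n_points=5)
    MHET = CalibrationCurve("MHET", slope=0.012, intercept=0.0, r2=1.0, n_points=5)

    def test_zero_ratio_assigns_all_to_mhet(self):
        tpa, mhet = convert_rate(0.024, 0.0, self.TPA, self.MHET)
        assert tpa == 0.0
        assert mhet == pytest.approx(0.024 / 0.012)

    def test_unit_symmetric_case(self):
        one = CalibrationCurve("TPA", 1.0, 0.0, 1.0, 2)
        onem = CalibrationCurve("MHET", 1.0, 0.0, 1.0, 2)
        tpa, mhet = convert_rate(0.4, 1.0, one, onem)
        assert tpa == pytest.approx(0.2) and mhet == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None)
    @given(
        rate=st.floats(0, 10, allow_nan=False),
        ratio=st.floats(0, 20, allow_nan=False),
    )
    def test_signal_conservation_identity(self, rate, ratio):
        tpa, mhet = convert_rate(rate, ratio, self.TPA, self.MHET)
        assert self.TPA.slope * tpa + self.MHET.slope * mhet == pytest.approx(
            rate, abs=1e-12
        )

    def test_noiseless_simulator_recovered_exactly(self):
        cfg = AssayConfig(sigma=0.0)
        standards, series, manifest = gen_assay(cfg, seed=3)
        curves = {a: fit_calibration(p, a) for a, p in standards.items()}
        rate, _ = initial_rate(series)
        tpa, mhet = convert_rate(
            rate, manifest.assay["endpoint_ratio"], curves["TPA"], curves["MHET"]
        )
        assert tpa == pytest.approx(manifest.assay["tpa_rate"], rel=1e-9)
        assert mhet == pytest.approx(manifest.assay["mhet_rate"], rel=1e-9)

    def test_noisy_replicates_recover_rates_within_two_percent(self):
        cfg = AssayConfig(sigma=0.005)
        tpa_est, mhet_est = [], []
        for rep in range(50):
            standards, series, manifest = gen_assay(cfg, seed=1000 + rep)
            curves = {a: fit_calibration(p, a) for a, p in standards.items()}
            rate, _ = initial_rate(series)
            tpa, mhet = convert_rate(
                rate, manifest.assay["endpoint_ratio"], curves["TPA"], curves["MHET"]
            )
            tpa_est.append(tpa)
            mhet_est.append(mhet)
        assert np.mean(tpa_est) == pytest.approx(cfg.tpa_rate, rel=0.02)
        assert np.mean(mhet_est) == pytest.approx(cfg.mhet_rate, rel=0.02)


class TestFoldChange:
    def test_basic_ratios(self):
        assert fold_change(1.0, 1.0) == (1.0, False)
        assert fold_change(2.6, 0.1) == (pytest.approx(26.0), False)

    def test_zero_reference_flagged(self):
        value, flagged = fold_change(1.0, 0.0)
        assert np.isnan(value) and flagged

    def test_table_matches_elementwise_division(self):
        rng = np.random.default_rng(5)
        test = rng.uniform(0.1, 5, size=12)
        ref = rng.uniform(0.1, 5, size=12)
        got = np.array([fold_change(t, r)[0] for t, r in zip(test, ref)])
        assert np.allclose(got, test / ref)


class TestOptimumMap:
    def test_single_cell(self):
        c = Condition(37.0, 1.0, 7.0, 500.0)
        best, table = optimum_map({c: 1.2})
        assert best == c and len(table) == 1

    def test_unimodal_surface_peak_found(self):
        temps = (30.0, 37.0, 45.0, 55.0, 65.0)
        salts = (1.0, 2.0, 3.0, 4.0)
        grid = {
            Condition(t, s): -((t - 55.0) ** 2) - 10 * (s - 4.0) ** 2
            for t in temps
            for s in salts
        }
        best, table = optimum_map(grid)
        assert (best.temperature, best.nacl) == (55.0, 4.0)
        assert len(table) == len(grid)

    def test_tie_breaks_to_lower_temperature(self):
        grid = {Condition(45.0): 2.0, Condition(55.0): 2.0, Condition(65.0): 1.0}
        best, _ = optimum_map(grid)
        assert best.temperature == 45.0

    def test_nan_cells_excluded_with_warning(self):
        grid = {Condition(37.0): float("nan"), Condition(45.0): 1.0}
        with pytest.warns(UserWarning):
            best, _ = optimum_map(grid)
        assert best.temperature == 45.0
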