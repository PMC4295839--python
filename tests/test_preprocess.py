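"""Plate I/O, background correction, smoothing and promoter activities."""

import numpy as np
import pandas as pd
import pytest

from promkin import preprocess as pp
from promkin import synthetic_data as sd


def make_plate_csv(tmp_path, rows):
    df = pd.DataFrame(rows, columns=pp.PLATE_COLUMNS)
    path = tmp_path / "plate.csv"
    df.to_csv(path, index=False)
    return path


def well_rows(well, times, A, I, cond="c1", rep=0, role="reporter", reporter="fliA"):
    return [(cond, well, rep, role, reporter, t, a, i) for t, a, i in zip(times, A, I)]


class TestReadPlateTable:
    def test_groups_and_sorts(self, tmp_path):
        rows = well_rows("w1", [0.0, 10.0, 20.0], [0.1, 0.2, 0.3], [5.0, 6.0, 7.0])
        series = pp.read_plate_table(make_plate_csv(tmp_path, rows))
        assert len(series) == 1
        s = series[0]
        assert s.well_id == "w1" and len(s.time) == 3
        np.testing.assert_array_equal(s.time, [0, 10, 20])

    def test_row_order_invariance(self, tmp_path):
        rows = well_rows("w1", [0.0, 10.0, 20.0], [0.1, 0.2, 0.3], [5.0, 6.0, 7.0])
        sorted_path = make_plate_csv(tmp_path, rows)
        shuffled = tmp_path / "shuffled.csv"
        pd.DataFrame(rows[::-1], columns=pp.PLATE_COLUMNS).to_csv(shuffled, index=False)
        a = pp.read_plate_table(sorted_path)[0]
        b = pp.read_plate_table(shuffled)[0]
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)

    def test_duplicate_time_rejected(self, tmp_path):
        rows = well_rows("w1", [0.0, 10.0, 10.0], [0.1, 0.2, 0.3], [5.0, 6.0, 7.0])
        with pytest.raises(ValueError, match="duplicated"):
            pp.read_plate_table(make_plate_csv(tmp_path, rows))

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"well": ["w"], "time_min": [0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            pp.read_plate_table(path)


class TestBackgroundCorrection:
    def _background_wells(self, t, cond="c1"):
        medium = pp.PlateTimeSeries(cond, "bm", 0, "background_medium",
                                    t, np.full_like(t, 0.04), np.full_like(t, 30.0))
        strain = pp.PlateTimeSeries(cond, "bs", 0, "background_strain",
                                    t, 0.04 + 0.1 * t / t[-1], 30.0 + 6.0 * t / t[-1])
        return medium, strain

    def test_blank_like_reporter_goes_to_zero(self):
        t = np.linspace(0, 100, 11)
        medium, strain = self._background_wells(t)
        rep = pp.PlateTimeSeries("c1", "w", 0, "reporter",
                                 t, np.full_like(t, 0.04), np.full_like(t, 30.0))
        out = pp.correct_background([rep, medium, strain])
        assert len(out) == 1
        np.testing.assert_allclose(out[0].absorbance, 0.0, atol=1e-12)

    def test_known_injected_background_recovered(self):
        # forward-generate with known backgrounds at zero measurement noise,
        # then check the corrected signals match the clean truth within 2%
        scen = sd.default_scenario(seed=3)
        cond = scen.conditions[0]
        A, _ = sd.make_growth_curve(cond.growth)
        f = sd.make_activity(cond.pulses["fliA"])
        t = np.linspace(0, cond.t_max, 120)
        noise0 = sd.NoiseModel(absorbance_sd=0.0, fluorescence_rel=0.0,
                               fluorescence_floor=0.0)
        wells = sd.simulate_reporter_fluorescence(
            f, A, scen.gamma_r, noise0, 2, 5, t, r0=f(0.0) / scen.gamma_r,
            condition_id=cond.name, reporter="fliA")
        corrected = pp.correct_background(wells)
        clean_A = A(t)
        clean_I = sd._integrate_fluorescence(f, A, scen.gamma_r, t,
                                             f(0.0) / scen.gamma_r * A(0.0))
        for w in corrected:
            np.testing.assert_allclose(w.absorbance, clean_A, rtol=0.02)
            np.testing.assert_allclose(w.fluorescence, clean_I, rtol=0.02)

    def test_zero_background_identity(self):
        t = np.linspace(0, 100, 11)
        A = 0.1 + 0.001 * t
        I = 50.0 + t
        rep = pp.PlateTimeSeries("c1", "w", 0, "reporter", t, A, I)
        medium = pp.PlateTimeSeries("c1", "bm", 0, "background_medium",
                                    t, np.zeros_like(t), np.zeros_like(t))
        strain = pp.PlateTimeSeries("c1", "bs", 0, "background_strain",
                                    t, A, np.zeros_like(t))
        out = pp.correct_background([rep, medium, strain])
        np.testing.assert_allclose(out[0].absorbance, A, rtol=1e-12)
        np.testing.assert_allclose(out[0].fluorescence, I, rtol=1e-12)

    def test_missing_background_well_errors(self):
        t = np.linspace(0, 100, 11)
        rep = pp.PlateTimeSeries("c9", "w", 0, "reporter", t,
                                 np.full_like(t, 0.1), np.full_like(t, 5.0))
        with pytest.raises(ValueError, match="c9"):
            pp.correct_background([rep])


class TestSmoothingAndDerived:
    def _series(self, t, A, I):
        return pp.PlateTimeSeries("c", "w", 0, "reporter", t, A, I)

    def test_noise_free_exponential_interpolated(self):
        t = np.linspace(0, 400, 150)
        A = 0.2 * np.exp(0.01 * t / 10)
        sm = pp.smooth_signals(self._series(t, A, A * 10), smoothing=1.0)
        interior = t[5:-5]
        np.testing.assert_allclose(sm.A(interior), A[5:-5], rtol=1e-3)

    def test_exponential_derivative(self):
        t = np.linspace(0, 400, 200)
        A = 0.2 * np.exp(0.002 * t)
        sm = pp.smooth_signals(self._series(t, A, A), smoothing=1.0)
        assert sm.dA(100.0) == pytest.approx(0.002 * sm.A(100.0), rel=1e-3)

    def test_derivatives_match_finite_differences(self):
        # the exposed derivatives are the exact spline derivatives
        t = np.linspace(0, 300, 100)
        rng = np.random.default_rng(0)
        A = 0.2 + 0.001 * t + 0.01 * rng.normal(size=t.size)
        sm = pp.smooth_signals(self._series(t, A, A * 3), smoothing=0.9)
        x = np.linspace(20, 280, 31)
        h = 1e-4
        fd = (sm.A(x + h) - sm.A(x - h)) / (2 * h)
        np.testing.assert_allclose(sm.dA(x), fd, rtol=1e-6, atol=1e-10)

    def test_polynomial_data_reproduced_at_points(self):
        t = np.linspace(0, 90, 10)
        A = 1.0 + 0.02 * t + 1e-4 * t**2 + 1e-6 * t**3
        sm = pp.smooth_signals(self._series(t, A, A), smoothing=1.0)
        np.testing.assert_allclose(sm.A(t), A, rtol=1e-9)

    def test_too_few_points(self):
        t = np.linspace(0, 10, 5)
        with pytest.raises(ValueError, match="8"):
            pp.smooth_signals(self._series(t, t + 1, t), smoothing=0.9)

    def test_growth_rate_exponential_and_constant(self):
        t = np.linspace(0, 400, 150)
        A = 0.2 * np.exp(0.01 * t / 10)
        mu = pp.growth_rate(pp.smooth_signals(self._series(t, A, A), smoothing=1.0))
        assert mu(200.0) == pytest.approx(0.001, rel=1e-3)
        const = np.full_like(t, 0.5)
        mu0 = pp.growth_rate(pp.smooth_signals(self._series(t, const, const), 1.0))
        assert abs(mu0(200.0)) < 1e-10

    def test_growth_rate_logistic_matches_closed_form(self):
        g = sd.GrowthParams(A0=0.05, rate=0.01, capacity=0.7)
        A_fun, mu_fun = sd.make_growth_curve(g)
        t = np.linspace(0, 900, 150)
        sm = pp.smooth_signals(self._series(t, A_fun(t), A_fun(t)), smoothing=1.0)
        mu = pp.growth_rate(sm)
        interior = np.linspace(50, 850, 81)
        err = np.abs(mu(interior) - mu_fun(interior)) / np.max(mu_fun(interior))
        assert np.max(err) < 0.02

    def test_reporter_concentration(self):
        t = np.linspace(0, 200, 50)
        A = np.full_like(t, 0.5)
        I = np.full_like(t, 50.0)
        sm = pp.smooth_signals(self._series(t, A, I), smoothing=1.0)
        r = pp.reporter_concentration(sm)
        assert r(100.0) == pytest.approx(100.0, rel=1e-9)
        # balanced growth: I = c*A gives r identically c
        A2 = 0.2 * np.exp(0.003 * t)
        sm2 = pp.smooth_signals(self._series(t, A2, 7.0 * A2), smoothing=1.0)
        r2 = pp.reporter_concentration(sm2)
        assert r2(150.0) == pytest.approx(7.0, rel=1e-6)

    def test_promoter_activity_balances(self):
        t = np.linspace(0, 300, 100)
        # stationary phase: constant A and I, f = gamma_r * r0
        A = np.full_like(t, 0.5)
        I = np.full_like(t, 50.0)
        sm = pp.smooth_signals(self._series(t, A, I), smoothing=1.0)
        f = pp.promoter_activity(sm, gamma_r=0.0006)
        assert f(150.0) == pytest.approx(0.0006 * 100.0, rel=1e-6, abs=1e-8)
        # balanced exponential growth: f = c * (mu + gamma_r)
        A2 = 0.2 * np.exp(0.004 * t)
        sm2 = pp.smooth_signals(self._series(t, A2, 3.0 * A2), smoothing=1.0)
        f2 = pp.promoter_activity(sm2, gamma_r=0.0006)
        assert f2(150.0) == pytest.approx(3.0 * (0.004 + 0.0006), rel=1e-4)

    def test_negative_gamma_r_rejected(self):
        t = np.linspace(0, 100, 20)
        sm = pp.smooth_signals(self._series(t, t + 1.0, t), smoothing=1.0)
        with pytest.raises(ValueError):
            pp.promoter_activity(sm, gamma_r=-0.1)

    def test_equation_forms_agree(self):
        # dI/dt/A + gamma_r I/A  ==  dr/dt + (gamma_r + mu) r
        t = np.linspace(0, 500, 200)
        A = 0.1 * np.exp(0.005 * t) / (1 + 0.1 * (np.exp(0.005 * t) - 1))
        I = 20 + 3 * t + 0.01 * t**2
        sm = pp.smooth_signals(self._series(t, A, I), smoothing=1.0)
        gamma_r = 0.0006
        x = np.linspace(30, 470, 89)
        form1 = sm.dI(x) / sm.A(x) + gamma_r * sm.I(x) / sm.A(x)
        r = sm.I(x) / sm.A(x)
        drdt = (sm.dI(x) * sm.A(x) - sm.I(x) * sm.dA(x)) / sm.A(x) ** 2
        mu = sm.dA(x) / sm.A(x)
        form2 = drdt + (gamma_r + mu) * r
        assert np.max(np.abs(form1 - form2)) < 1e-8 * np.max(np.abs(form1))


class TestAggregate:
    def test_identical_replicates_zero_band(self):
        grid = np.linspace(0, 10, 11)
        prof = pp.aggregate_replicates([grid * 0 + 5.0] * 4, grid)
        np.testing.assert_allclose(prof.epsilon, 0.0, atol=1e-12)
        assert prof.n_replicates == 4

    def test_hand_computed_sem(self):
        grid = np.array([0.0])
        prof = pp.aggregate_replicates(
            [np.array([8.0]), np.array([10.0]), np.array([12.0]), np.array([10.0])],
            grid,
        )
        assert prof.f_mean[0] == pytest.approx(10.0)
        sd_ = np.sqrt(8.0 / 3.0)
        assert prof.epsilon[0] == pytest.approx(2 * sd_ / 2.0, rel=1e-12)

    def test_permutation_invariance(self, rng):
        grid = np.linspace(0, 50, 20)
        reps = [rng.normal(10, 1, 20) for _ in range(5)]
        a = pp.aggregate_replicates(reps, grid)
        b = pp.aggregate_replicates(reps[::-1], grid)
        np.testing.assert_allclose(a.f_mean, b.f_mean)
        np.testing.assert_allclose(a.epsilon, b.epsilon)

    def test_single_replicate_flagged(self):
        grid = np.linspace(0, 10, 5)
        prof = pp.aggregate_replicates([np.ones(5)], grid)
        assert not prof.epsilon_defined
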