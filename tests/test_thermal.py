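import dataclasses

import numpy as np
import pandas as pd
import pytest

from osteotherm import acoustics as ac
from osteotherm import thermal as th
from osteotherm.geometry import GeometryParams
from osteotherm.thermal import (TemperatureSeries, ThermalParams, fit_quadratic,
                                impulse_response, lag_table, ring_uniformity,
                                simulate, step, time_lag)

from .conftest import FAST_ELEMENT_MM


def heat_kernel_3d(shape, center, sigma_vox, amplitude):
    """Analytic Green's function of the heat equation on the voxel grid."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij",
                        sparse=True)
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return amplitude / (2 * np.pi * sigma_vox**2) ** 1.5 * \
        np.exp(-r2 / (2 * sigma_vox**2))


class TestStep:
    def test_zero_stays_zero(self, thermal_params):
        T = np.zeros((16, 16, 16))
        out = step(T, None, thermal_params, 1.0)
        assert np.all(out == 0)

    def test_point_impulse_matches_greens_function(self):
        # 10 steps of sigma-per-step s relax a delta to the analytic
        # Gaussian with sigma = s * sqrt(10)
        params = ThermalParams(time_step_s=2.0)
        spacing = 0.5
        sigma_step = params.kernel_sigma_mm() / spacing
        n = 64
        T = np.zeros((n, n, n))
        T[n // 2, n // 2, n // 2] = 1.0
        for _ in range(10):
            T = step(T, None, params, spacing)
        oracle = heat_kernel_3d((n, n, n), (n // 2,) * 3,
                                sigma_step * np.sqrt(10), 1.0)
        l2 = np.sqrt(np.sum((T - oracle) ** 2) / np.sum(oracle**2))
        assert l2 < 0.01

    def test_mass_conserved_over_100_steps(self):
        params = ThermalParams(time_step_s=1.0)
        n = 64
        T = np.zeros((n, n, n))
        T[n // 2, n // 2, n // 2] = 1.0
        total0 = T.sum()
        for _ in range(100):
            T = step(T, None, params, 1.0)
        assert abs(T.sum() - total0) / total0 < 0.005

    def test_source_term_scaling(self, thermal_params):
        q = np.zeros((12, 12, 12))
        q[6, 6, 6] = 3.8e6          # one volumetric heat capacity worth
        T = step(np.zeros_like(q), q, thermal_params, 1.0)
        assert T[6, 6, 6] == pytest.approx(thermal_params.time_step_s)

    def test_under_resolved_kernel_raises(self):
        params = ThermalParams(time_step_s=0.1)
        with pytest.raises(ValueError, match="under-resolved"):
            step(np.zeros((8, 8, 8)), None, params, 1.0)


class TestSimulate:
    def test_all_off_from_uniform_stays_uniform(self, thermal_params):
        # interior of a padded uniform block stays uniform (no gradients)
        n = 48
        q = np.zeros((n, n, n))
        T0 = np.ones((n, n, n))
        series, _, T = simulate(q, np.zeros(20), thermal_params, 1.0,
                                probe_index=(n // 2,) * 3, T0=T0)
        core = T[16:-16, 16:-16, 16:-16]
        assert np.ptp(core) < 1e-5   # flat to well below thermometry noise
        assert series.sonication_end_s == 0.0

    def test_linearity_in_source(self, thermal_params):
        rng = np.random.default_rng(11)
        q = rng.random((16, 16, 16)) * 1e5
        duty = np.array([1.0] * 5 + [0.0] * 5)
        _, _, t1 = simulate(q, duty, thermal_params, 1.0)
        _, _, t2 = simulate(2 * q, duty, thermal_params, 1.0)
        assert np.allclose(t2, 2 * t1, rtol=1e-10)

    def test_cooling_decays_monotonically(self, thermal_params):
        n = 32
        q = np.zeros((n, n, n))
        q[n // 2, n // 2, n // 2] = 1e7
        duty = np.array([1.0] * 3 + [0.0] * 30)
        series, _, _ = simulate(q, duty, thermal_params, 1.0,
                                probe_index=(n // 2,) * 3)
        post = series.values_c[3:]
        assert np.all(np.diff(post) < 0)


class TestTimeLag:
    def test_constructed_peak_position(self):
        t = np.arange(0.0, 200.0, 2.0)
        v = np.exp(-((t - 90.0) ** 2) / 300.0)     # peak at t = 90
        s = TemperatureSeries(t, v, sonication_end_s=50.0)
        assert time_lag(s) == pytest.approx(40.0, abs=0.1)

    def test_monotone_decay_gives_zero(self):
        t = np.arange(0.0, 100.0, 2.0)
        s = TemperatureSeries(t, np.exp(-t / 30.0), sonication_end_s=10.0)
        assert time_lag(s) == 0.0

    def test_peak_at_end_raises(self):
        t = np.arange(0.0, 100.0, 2.0)
        s = TemperatureSeries(t, t.copy(), sonication_end_s=10.0)
        with pytest.raises(RuntimeError, match="too short"):
            time_lag(s)


@pytest.fixture(scope="module")
def lag_r6(medium, source_params, thermal_params):
    geom = GeometryParams(grid_spacing_mm=1.0)
    tr = ac.TransducerSpec(efficiency=0.228)
    return impulse_response(geom, tr, medium, source_params, thermal_params,
                            element_size_mm=FAST_ELEMENT_MM)


class TestImpulseResponse:
    def test_cortical_source_peaks_after_sonication(self, lag_r6):
        eps = time_lag(lag_r6)
        assert eps > 0

    def test_lag_band_r6_h0(self, lag_r6):
        # on the order of the reported ~126 s for the 6 mm radius section
        eps = time_lag(lag_r6)
        assert 60.0 <= eps <= 150.0

    def test_tumoral_only_decays_after_end(self, medium, source_params,
                                           thermal_params):
        geom = GeometryParams(grid_spacing_mm=1.0)
        tr = ac.TransducerSpec(efficiency=0.228)
        s = impulse_response(geom, tr, medium, source_params, thermal_params,
                             source="tumoral", element_size_mm=FAST_ELEMENT_MM)
        assert time_lag(s) == pytest.approx(0.0, abs=2.1)

    def test_lag_increases_with_radius(self, medium, source_params,
                                       thermal_params, lag_r6):
        geom = GeometryParams(cortical_radius_mm=9.0, grid_spacing_mm=1.0)
        tr = ac.TransducerSpec(efficiency=0.228)
        s9 = impulse_response(geom, tr, medium, source_params, thermal_params,
                              element_size_mm=FAST_ELEMENT_MM)
        assert time_lag(s9) > time_lag(lag_r6)


class TestLagSurfaceFit:
    def test_exact_quadratic_recovered(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(-5, 5, 40)
        r = rng.uniform(6, 10, 40)
        c = dict(c00=236.0, c10=7.83, c01=-65.0, c20=1.54, c11=-4.0, c02=7.94)
        eps = (c["c00"] + c["c10"] * h + c["c01"] * r + c["c20"] * h**2
               + c["c11"] * h * r + c["c02"] * r**2)
        fit = fit_quadratic(pd.DataFrame({"H_mm": h, "R_mm": r, "eps_s": eps}))
        assert fit.mean_abs_residual_s < 1e-9
        for k, v in c.items():
            assert fit.coefficients[k] == pytest.approx(v, abs=1e-8)

    def test_rank_deficient_raises(self):
        df = pd.DataFrame({"H_mm": [0.0] * 6, "R_mm": [6.0] * 6,
                           "eps_s": [1.0] * 6})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_quadratic(df)

    def test_predict_matches_design(self):
        df = pd.DataFrame({"H_mm": [-2, 0, 2, -2, 0, 2, -1, 1],
                           "R_mm": [6, 7, 8, 8, 6, 7, 9, 9],
                           "eps_s": [50, 80, 120, 110, 60, 95, 140, 150]})
        fit = fit_quadratic(df)
        pred = fit.predict(df["H_mm"], df["R_mm"])
        resid = np.mean(np.abs(pred - df["eps_s"]))
        assert resid == pytest.approx(fit.mean_abs_residual_s, rel=1e-9)


class TestRingUniformity:
    def test_uniform_field_gives_zero(self, tmap_1mm):
        T = np.full(tmap_1mm.shape, 4.2)
        assert ring_uniformity(T, tmap_1mm) == pytest.approx(0.0, abs=1e-12)

    def test_nonuniform_positive(self, tmap_1mm):
        X, Y, Z = tmap_1mm.coordinate_grids()
        T = np.broadcast_to(1.0 + 0.5 * np.sign(Z), tmap_1mm.shape).copy()
        assert ring_uniformity(T, tmap_1mm) > 0.1


def test_grid_refinement_stability_of_lag(medium, source_params,
                                          thermal_params):
    """eps changes < 10% when the spacing halves (1.0 -> 0.5 mm)."""
    tr = ac.TransducerSpec(efficiency=0.228)
    eps = {}
    for sp in (1.0, 0.5):
        geom = GeometryParams(grid_spacing_mm=sp)
        s = impulse_response(geom, tr, medium, source_params, thermal_params,
                             element_size_mm=FAST_ELEMENT_MM)
        eps[sp] = time_lag(s)
    assert abs(eps[0.5] - eps[1.0]) / eps[1.0] < 0.10
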