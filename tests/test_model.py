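"""CVR estimation: percent normalization, OLS at fixed delay, delay grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvrkit.errors import (
    DegenerateDesignError,
    EstimationError,
    InvalidArgumentError,
    SignalError,
)
from cvrkit.model import (
    CVRResult,
    DelayGrid,
    fit_at_delay,
    normalize_percent,
    optimize_delay,
    run_subject,
)
from cvrkit.physio import EtCO2Trace, sample_trace, volume_times
from cvrkit.pipeline import paint_bold_4d
from cvrkit.synthetic import (
    SimulationConfig,
    make_gas_paradigm,
    simulate_bold_roi,
    simulate_etco2,
)


class TestDelayGrid:
    def test_values_include_zero_and_span(self):
        grid = DelayGrid(-5, 60, 1)
        vals = grid.values()
        assert vals[0] == -5 and vals[-1] == 60 and 0.0 in vals

    @pytest.mark.parametrize("args", [(5, 60, 1), (-5, 60, -1), (2, -2, 1)])
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(InvalidArgumentError):
            DelayGrid(*args)


class TestNormalizePercent:
    def test_constant_series_maps_to_zeros(self):
        assert np.allclose(normalize_percent(np.full(8, 500.0)), 0.0)

    def test_two_point_arithmetic(self):
        assert np.allclose(normalize_percent(np.array([90.0, 110.0])), [-10.0, 10.0])

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(SignalError):
            normalize_percent(np.array([-1.0, -3.0]))

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        series = np.array([100.0, 104.0, 98.0, 101.0, 97.0])
        assert np.allclose(
            normalize_percent(series * scale), normalize_percent(series), atol=1e-9
        )


class TestFitAtDelay:
    def test_exact_proportional_fit(self):
        x = np.array([38.0, 40.0, 44.0, 46.0, 44.0, 40.0, 38.0, 39.0])
        y = 0.05 * (x - x.mean())
        fit = fit_at_delay(y, x)
        assert fit.beta_co2 == pytest.approx(0.05, abs=1e-12)
        assert fit.ssr == pytest.approx(0.0, abs=1e-18)

    def test_pure_ramp_absorbed_by_drift_term(self):
        x = np.array([38.0, 40.0, 44.0, 46.0, 44.0, 40.0, 38.0, 39.0])
        y = 0.3 * np.arange(8.0) - 1.0
        fit = fit_at_delay(y, x)
        assert fit.beta_co2 == pytest.approx(0.0, abs=1e-10)
        assert fit.beta_drift == pytest.approx(0.3, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        # 6-point system solved independently via the normal equations
        x = np.array([38.0, 41.0, 45.0, 44.0, 40.0, 39.0])
        y = np.array([0.12, -0.05, 0.30, 0.18, -0.10, 0.02])
        design = np.column_stack([x, np.arange(6.0), np.ones(6)])
        expected = np.linalg.solve(design.T @ design, design.T @ y)
        fit = fit_at_delay(y, x)
        assert fit.beta_co2 == pytest.approx(expected[0], abs=1e-10)
        assert fit.beta_drift == pytest.approx(expected[1], abs=1e-10)
        assert fit.intercept == pytest.approx(expected[2], abs=1e-10)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_at_delay(np.arange(6.0), np.full(6, 40.0))


class TestOptimizeDelay:
    def test_round_trip_recovers_truth_exactly(self, paradigm):
        cfg = SimulationConfig(true_cvr_pct_per_mmHg=0.042, true_delay_s=10.0, seed=11)
        trace = simulate_etco2(paradigm, cfg)
        bold = simulate_bold_roi(trace, cfg)
        pct = normalize_percent(bold)
        res = optimize_delay(pct, trace, DelayGrid(), cfg.tr_s)
        assert res.delay_s == cfg.true_delay_s
        assert res.cvr_pct_per_mmHg == pytest.approx(cfg.true_cvr_pct_per_mmHg, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_singleton_grid_equals_fixed_delay_fit(self, etco2_trace, noiseless_config):
        bold = simulate_bold_roi(etco2_trace, noiseless_config)
        pct = normalize_percent(bold)
        grid = DelayGrid(0.0, 0.0, 1.0)
        res = optimize_delay(pct, etco2_trace, grid, noiseless_config.tr_s)
        times = volume_times(pct.size, noiseless_config.tr_s)
        direct = fit_at_delay(pct, sample_trace(etco2_trace, times))
        assert res.delay_s == 0.0
        assert res.cvr_pct_per_mmHg == pytest.approx(direct.beta_co2, abs=1e-12)
        assert res.ssr == pytest.approx(direct.ssr, abs=1e-12)

    def test_equals_exhaustive_ssr_minimization(self, etco2_trace):
        """Brute-force oracle: re-fit every grid delay and compare."""
        rng = np.random.default_rng(5)
        grid = DelayGrid(-5, 30, 1)
        cfg = SimulationConfig(noise_sd_pct=0.3, true_delay_s=12.0, seed=21)
        times = volume_times(cfg.n_volumes, cfg.tr_s)
        for trial in range(10):
            bold = simulate_bold_roi(
                etco2_trace,
                SimulationConfig(noise_sd_pct=0.3, true_delay_s=12.0, seed=100 + trial),
            )
            pct = normalize_percent(bold)
            res = optimize_delay(pct, etco2_trace, grid, cfg.tr_s)
            ssrs = {
                d: fit_at_delay(pct, sample_trace(etco2_trace, times - d)).ssr
                for d in grid.values()
            }
            best = min(ssrs.items(), key=lambda kv: (kv[1], abs(kv[0]), kv[0]))
            assert res.delay_s == best[0]
            assert res.ssr == pytest.approx(best[1], rel=1e-12)

    def test_all_air_paradigm_is_degenerate(self):
        flat = EtCO2Trace(
            times_s=np.arange(0.0, 720.0, 4.0),
            values_mmHg=np.full(180, 38.0),
            source="simulated",
        )
        pct = np.sin(np.arange(464) / 10.0)
        with pytest.raises(EstimationError):
            optimize_delay(pct, flat, DelayGrid(), 1.55)

    def test_recovery_under_roi_level_noise(self, paradigm):
        """At ROI-mean SNR (noise 0.2% of baseline) the median CVR error
        stays well below the smallest effects of interest."""
        errors = []
        for seed in range(100):
            cfg = SimulationConfig(noise_sd_pct=0.2, true_delay_s=8.0, seed=seed)
            trace = simulate_etco2(paradigm, cfg)
            bold = simulate_bold_roi(trace, cfg)
            res = optimize_delay(normalize_percent(bold), trace, DelayGrid(), cfg.tr_s)
            errors.append(abs(res.cvr_pct_per_mmHg - cfg.true_cvr_pct_per_mmHg))
        assert np.median(errors) < 0.005


class TestInvariances:
    def test_scale_invariance_of_cvr_delay_r2(self, etco2_trace):
        cfg = SimulationConfig(noise_sd_pct=0.2, drift_pct_per_scan=0.4, seed=17)
        bold = simulate_bold_roi(etco2_trace, cfg)
        a = optimize_delay(normalize_percent(bold), etco2_trace, DelayGrid(), cfg.tr_s)
        b = optimize_delay(normalize_percent(bold * 7.3), etco2_trace, DelayGrid(), cfg.tr_s)
        assert a.delay_s == b.delay_s
        assert a.cvr_pct_per_mmHg == pytest.approx(b.cvr_pct_per_mmHg, abs=1e-9)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-9)

    def test_added_linear_trend_leaves_cvr_unchanged(self, etco2_trace, noiseless_config):
        bold = simulate_bold_roi(etco2_trace, noiseless_config)
        n = bold.size
        ramp = np.arange(n) / n
        trend = 0.004 * noiseless_config.baseline_signal * (ramp - ramp.mean())
        a = optimize_delay(normalize_percent(bold), etco2_trace, DelayGrid(), 1.55)
        b = optimize_delay(normalize_percent(bold + trend), etco2_trace, DelayGrid(), 1.55)
        assert a.delay_s == b.delay_s
        assert a.cvr_pct_per_mmHg == pytest.approx(b.cvr_pct_per_mmHg, abs=1e-7)
        assert b.drift_pct_per_scan != pytest.approx(a.drift_pct_per_scan, abs=1e-3)


class TestRunSubject:
    def test_phantom_round_trip_per_tissue(self, phantom, paradigm):
        base = SimulationConfig(seed=31)
        trace = simulate_etco2(paradigm, base)
        truths = {"sgm": 0.171, "nawm": 0.042, "wmh": 0.040}
        series = {
            label: simulate_bold_roi(
                trace, SimulationConfig(true_cvr_pct_per_mmHg=cvr, seed=31)
            )
            for label, cvr in truths.items()
        }
        bold = paint_bold_4d(phantom, series)
        results = run_subject(bold, phantom, trace, base.tr_s)
        assert {r.label for r in results} == set(truths)
        for r in results:
            assert r.cvr_pct_per_mmHg == pytest.approx(truths[r.label], abs=1e-9)
            assert r.delay_s == base.true_delay_s

    def test_empty_wmh_roi_is_omitted_not_fatal(self, phantom, etco2_trace, noiseless_config):
        masks = {k: v.copy() for k, v in phantom.masks.items()}
        masks["wmh"][:] = False
        from cvrkit.roi import ROIMaskSet

        ms = ROIMaskSet(
            masks=masks,
            voxel_spacing_mm=phantom.voxel_spacing_mm,
            affine=phantom.affine,
        )
        bold = paint_bold_4d(
            ms, {"sgm": simulate_bold_roi(etco2_trace, noiseless_config)}
        )
        results = run_subject(bold, ms, etco2_trace, noiseless_config.tr_s)
        labels = {r.label for r in results}
        assert "wmh" not in labels and "sgm" in labels

    def test_duplicate_run_is_deterministic(self, phantom, etco2_trace, noiseless_config):
        bold = paint_bold_4d(
            phantom, {"nawm": simulate_bold_roi(etco2_trace, noiseless_config)}
        )
        r1 = run_subject(bold, phantom, etco2_trace, noiseless_config.tr_s)
        r2 = run_subject(bold, phantom, etco2_trace, noiseless_config.tr_s)
        assert r1 == r2
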