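"""Staged fit: stage-1 rate extraction and stage-2 grid search."""

import warnings

import numpy as np
import pandas as pd
import pytest

from motortraffic import (
    KineticParams,
    fit_low_density,
    grid_search_fit,
    nM_to_per_um3,
    predict_series,
)
from motortraffic.crowding_fit import validate_series
from motortraffic.lattice_sim import EstimationError


def analytic_linear_series(params: KineticParams, concs_nM, se_frac=0.01):
    """Exact dilute-limit series implied by a parameter set (no simulation)."""
    v0 = params.motor_step_um * params.step_rate
    rl0 = v0 / params.omega_D
    slope = params.omega_A0 * params.n_lanes / (params.omega_D * params.motor_step_um)
    rows = []
    for c in concs_nM:
        d = slope * nM_to_per_um3(c)
        rows.append(
            {
                "conc_nM": c,
                "density": d,
                "density_se": se_frac * d,
                "velocity": v0,
                "velocity_se": se_frac * v0,
                "runlength": rl0,
                "runlength_se": se_frac * rl0,
            }
        )
    return pd.DataFrame(rows)


class TestSeriesSchema:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_series(pd.DataFrame({"conc_nM": [1, 2, 3]}))

    def test_needs_three_concentrations(self, kinesin2_params):
        s = analytic_linear_series(kinesin2_params, [10.0, 20.0])
        with pytest.raises(ValueError, match="3 distinct"):
            validate_series(s)

    def test_nonpositive_concentration_rejected(self, kinesin2_params):
        s = analytic_linear_series(kinesin2_params, [0.0, 10.0, 20.0])
        with pytest.raises(ValueError, match="> 0"):
            validate_series(s)


class TestStage1:
    def test_exact_linear_series_recovers_table_rates(self, kinesin2_params):
        """omega_D = 0.25/s, step rate = 37.5/s, omega_A0 = 1.53e-4 um^3/s."""
        s = analytic_linear_series(kinesin2_params, [5.0, 20.0, 50.0, 100.0])
        fit = fit_low_density(s, kinesin2_params)
        assert fit.omega_D == pytest.approx(0.25, rel=1e-9)
        assert fit.step_rate == pytest.approx(37.5, rel=1e-9)
        assert fit.omega_A0 == pytest.approx(1.53e-4, rel=1e-9)

    def test_simulated_series_recovers_rates(self, kinesin2_params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_series(
                kinesin2_params, [10.0, 40.0, 80.0], reps=2, seed=3,
                lattice_length=8.0, duration=60.0,
            )
            fit = fit_low_density(pred, kinesin2_params)
        assert fit.omega_D == pytest.approx(0.25, rel=0.1)
        assert fit.step_rate == pytest.approx(37.5, rel=0.05)

    def test_saturated_series_refused_with_range(self, kinesin2_params):
        s = analytic_linear_series(kinesin2_params, [50.0, 400.0, 1250.0])
        # impose saturation by capping density
        s["density"] = np.minimum(s["density"], 300.0)
        with pytest.raises(EstimationError, match="nM"):
            fit_low_density(s, kinesin2_params)

    def test_zero_density_series_errors(self, kinesin2_params):
        s = analytic_linear_series(kinesin2_params, [5.0, 10.0, 20.0])
        s["density"] = 0.0
        with pytest.raises(EstimationError):
            fit_low_density(s, kinesin2_params)


class TestPredictSeries:
    def test_zero_affinity_gives_zero_density(self, kinesin2_params):
        params = KineticParams(omega_A0=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_series(params, [10.0, 100.0, 1000.0], reps=1, seed=1,
                                  lattice_length=6.0, duration=20.0)
        assert (pred["density"] == 0.0).all()

    def test_langmuir_isotherm_control(self):
        """Footprint 1, no stepping: density follows k c/(k c + omega_D)."""
        params = KineticParams(
            motor_size=8.0, motor_step=8.0, step_rate=0.0,
            omega_A0=1e-3, omega_D=0.25, omega_DC=0.25, n_lanes=1,
        )
        concs = [100.0, 400.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_series(params, concs, reps=3, seed=11,
                                  lattice_length=2.0, duration=200.0)
        for _, row in pred.iterrows():
            k = 1e-3 * nM_to_per_um3(row["conc_nM"])
            occ = k / (k + 0.25)
            expected = occ / 0.008  # motors/um on one lane
            assert abs(row["density"] - expected) < max(3 * row["density_se"], 0.02 * expected)

    def test_density_sublinear_at_high_concentration(self, kinesin2_params):
        """Linear scaling at low c, saturation bends the curve down at high c."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_series(kinesin2_params, [10.0, 100.0, 1000.0], reps=2,
                                  seed=13, lattice_length=8.0, duration=60.0)
        d = pred.set_index("conc_nM")["density"]
        assert d[100.0] / d[10.0] == pytest.approx(10.0, rel=0.2)
        assert d[1000.0] / d[100.0] < 8.0


@pytest.fixture(scope="module")
def observed_series(kinesin2_params):
    """Synthetic 'experimental' series at the true triple (13, 0, 3) + 5% noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = predict_series(
            kinesin2_params, [10.0, 50.0, 100.0, 400.0, 1250.0],
            reps=2, seed=21, lattice_length=8.0, duration=60.0,
        )
    rng = np.random.default_rng(22)
    for k in ("density", "velocity", "runlength"):
        obs[k] = obs[k] * rng.lognormal(0.0, 0.05, len(obs))
        obs[f"{k}_se"] = 0.05 * obs[k]
    return obs


class TestGridSearch:
    def test_empty_grid_rejected(self, observed_series, kinesin2_params):
        fit = fit_low_density(observed_series[observed_series.conc_nM <= 100], kinesin2_params)
        with pytest.raises(ValueError, match="empty"):
            grid_search_fit(observed_series, fit, lanes_grid=[])

    def test_out_of_bounds_grid_rejected(self, observed_series, kinesin2_params):
        fit = fit_low_density(observed_series[observed_series.conc_nM <= 100], kinesin2_params)
        with pytest.raises(ValueError, match="\\[1, 13\\]"):
            grid_search_fit(observed_series, fit, lanes_grid=[14])

    def test_single_triple_grid_returns_it(self, observed_series, kinesin2_params):
        fit = fit_low_density(observed_series[observed_series.conc_nM <= 100], kinesin2_params)
        res = grid_search_fit(
            observed_series, fit, lanes_grid=[13], range_grid=[0], ratio_grid=[3],
            reps=1, seed=23, duration=40.0,
        )
        assert (res.n_lanes, res.interaction_range, res.ratio) == (13, 0, 3.0)
        assert len(res.loss_table) == 1
        assert np.isfinite(res.loss)

    def test_tie_breaks_toward_smaller_triple(self, observed_series, kinesin2_params, monkeypatch):
        """Equal losses resolve to the smallest (lanes, range, ratio)."""
        import motortraffic.crowding_fit as cf

        fit = fit_low_density(observed_series[observed_series.conc_nM <= 100], kinesin2_params)
        fixed = observed_series.copy()

        def fake_predict(params, concs, **kw):
            return fixed

        monkeypatch.setattr(cf, "predict_series", fake_predict)
        res = cf.grid_search_fit(
            observed_series, fit, lanes_grid=[3, 7], range_grid=[2, 4],
            ratio_grid=[1, 5], reps=1, seed=0,
        )
        assert (res.n_lanes, res.interaction_range, res.ratio) == (3, 2, 1.0)

    def test_loss_landscape_prefers_generating_triple(self, observed_series, kinesin2_params):
        """Truth beats triples >= 2 grid steps away in any coordinate."""
        fit = fit_low_density(observed_series[observed_series.conc_nM <= 100], kinesin2_params)
        res = grid_search_fit(
            observed_series, fit, lanes_grid=[5, 13], range_grid=[0, 4],
            ratio_grid=[3, 9], reps=1, seed=31, duration=40.0,
        )
        assert (res.n_lanes, res.interaction_range, res.ratio) == (13, 0, 3.0)
        tab = res.loss_table.set_index(["n_lanes", "interaction_range", "ratio"])["loss"]
        truth_loss = tab[(13, 0, 3.0)]
        assert (truth_loss <= tab.drop(index=(13, 0, 3.0))).all()


class TestClosedLoop:
    def test_simulate_render_analyze_fit_recovers_rates(self, kinesin2_params):
        """Full loop: lattice sim -> TIRF render -> correlation analysis ->
        stage-1 fit recovers omega_D within 20% and step rate within 10%."""
        from motortraffic import (
            OpticsConfig,
            background_subtract,
            extract_velocity_runlength,
            fcs_density,
            make_kymograph,
            render_stack,
            simulate,
            spatiotemporal_correlation,
        )
        from motortraffic.lattice_sim import LatticeConfig

        omega_ds, step_rates = [], []
        for seed in (1, 2, 3):
            rows = []
            for i, c_nm in enumerate([5.0, 20.0, 50.0]):
                cfg = LatticeConfig(
                    lattice_length=10.0, duration=160.0,
                    concentration=nM_to_per_um3(c_nm), burn_in=30.0,
                    seed=1000 * seed + i,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ts = simulate(kinesin2_params, cfg)
                    # keep ~0.5 labeled motors/um in the rendered stack
                    dens = ts.mean_bound_count(30.0, 160.0) / 10.0
                    frac = min(1.0, 0.5 / max(dens, 1e-9))
                    sub = ts.runs[ts.runs["bind_time_s"] >= 30.0].copy()
                    sub[["bind_time_s", "unbind_time_s"]] -= 30.0
                    ts_r = type(ts)(runs=sub, snapshots=ts.snapshots, params=ts.params, config=ts.config)
                    optics = OpticsConfig(
                        n_frames=600, labeled_fraction=frac, seed=2000 * seed + i
                    )
                    stack = render_stack(ts_r, optics)
                    kymo = background_subtract(make_kymograph(stack))
                    est = extract_velocity_runlength(
                        spatiotemporal_correlation(kymo, max_lag=8.0)
                    )
                    d = fcs_density(kymo, labeled_conc=frac, total_conc=1.0)
                rows.append(
                    {
                        "conc_nM": c_nm,
                        "density": d.total_density,
                        "density_se": d.total_density_se,
                        "velocity": est.velocity,
                        "velocity_se": est.velocity_se,
                        "runlength": est.run_length,
                        "runlength_se": est.run_length_se,
                    }
                )
            # only omega_D and the step rate are asserted here; the FCS
            # density points on short records are noisy, so the density
            # curvature gate is opened wide for this loop
            fit = fit_low_density(pd.DataFrame(rows), kinesin2_params, curvature_tol=2.0)
            omega_ds.append(fit.omega_D)
            step_rates.append(fit.step_rate)
        assert abs(np.median(omega_ds) - 0.25) / 0.25 <= 0.20
        assert abs(np.median(step_rates) - 37.5) / 37.5 <= 0.10
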