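import numpy as np
import pandas as pd
import pytest

from fermkin import (StudyConfig, fit_prediction_equation, generate_study,
                     lin_ccc, model_g, read_tables, simulate_gas_curve,
                     simulate_odorants, solve_mean_shift_for_ccc,
                     write_tables)
from fermkin.balance import digestibility_table
from fermkin.simulate import ConfigError

from conftest import HALF_HOUR_GRID, make_tiny_config


class TestSimulateGasCurve:
    def test_half_asymptote_and_tail(self):
        g = simulate_gas_curve(85.76, 1.27, 3.42, [3.42, 48.0], 0.0)
        assert g[0] == pytest.approx(42.88)
        assert g[1] == pytest.approx(82.87, abs=0.01)

    def test_noiseless_reproduces_model_everywhere(self):
        g = simulate_gas_curve(85.76, 1.27, 3.42, HALF_HOUR_GRID, 0.0)
        assert g == pytest.approx(model_g(HALF_HOUR_GRID,
                                          85.76, 1.27, 3.42))

    def test_early_times_near_zero(self):
        g = simulate_gas_curve(85.76, 1.27, 3.42, [1e-9], 0.0)
        assert g[0] == pytest.approx(0.0, abs=1e-6)

    def test_noisy_curve_is_nondecreasing(self):
        g = simulate_gas_curve(85.76, 1.27, 3.42, HALF_HOUR_GRID, 2.0,
                               rng=5)
        assert np.all(np.diff(g) >= 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_gas_curve(-1, 1.3, 3.4, [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            simulate_gas_curve(80, 1.3, 3.4, [2, 1, 3])


class TestMeanShiftSolver:
    def test_unit_shift_example(self):
        # CCC = 2/(2 + delta^2) at r=1, unit sds
        assert solve_mean_shift_for_ccc(1, 1, 1, 2 / 3) \
            == pytest.approx(1.0)

    def test_zero_shift_at_perfect_target(self):
        assert solve_mean_shift_for_ccc(1, 1, 1, 1.0) == 0.0

    def test_round_trip_through_ccc_formula(self):
        r, sx, sy, target = 0.9, 2.0, 2.0, 0.8
        delta = solve_mean_shift_for_ccc(r, sx, sy, target)
        assert delta == pytest.approx(1.0)
        implied = 2 * r * sx * sy / (sx ** 2 + sy ** 2 + delta ** 2)
        assert implied == pytest.approx(target)

    def test_infeasible_target_names_maximum(self):
        with pytest.raises(ValueError, match="0.9"):
            solve_mean_shift_for_ccc(0.9, 1, 1, 0.95)


class TestSimulateOdorants:
    def test_line_evaluation(self):
        out = simulate_odorants([20.0],
                                {"pc": {"slope": -0.7524,
                                        "intercept": 27.3514}}, 0.0)
        assert out["pc"].iloc[0] == pytest.approx(12.30, abs=5e-3)

    def test_zero_slope_returns_intercept(self):
        out = simulate_odorants([5, 50, 95],
                                {"c": {"slope": 0.0, "intercept": 7.5}},
                                0.0)
        assert (out["c"] == 7.5).all()

    def test_truncated_at_zero(self):
        out = simulate_odorants([1.0],
                                {"c": {"slope": 0.1, "intercept": -5.0}},
                                0.0)
        assert out["c"].iloc[0] == 0.0

    def test_refit_recovers_generating_slope(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(5, 30, 18)
        out = simulate_odorants(x, {"pc": {"slope": -0.7524,
                                           "intercept": 27.3514}},
                                0.5, rng=3)
        fit = fit_prediction_equation(x, out["pc"])
        assert fit.slope == pytest.approx(-0.7524, rel=0.10)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            simulate_odorants([120.0], {"c": {"slope": 1, "intercept": 0}},
                              0.0)


class TestGenerateStudy:
    def test_seed_determinism_byte_identical(self, tiny_config, tmp_path):
        t1 = generate_study(tiny_config)
        t2 = generate_study(tiny_config)
        p1 = write_tables(t1, tmp_path / "a")
        p2 = write_tables(t2, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seed_differs(self, tiny_config):
        import copy
        other = copy.deepcopy(tiny_config)
        other.seed = tiny_config.seed + 1
        a = generate_study(tiny_config).gas_curves["cum_ml"]
        b = generate_study(other).gas_curves["cum_ml"]
        assert not np.allclose(a, b)

    def test_tables_key_back_to_config(self, tiny_config):
        tables = generate_study(tiny_config)
        diets = set(tiny_config.diets)
        for df in (tables.gas_curves, tables.residue_records,
                   tables.odorant_records, tables.invivo_records):
            assert set(df["diet"]) <= diets
        assert set(tables.residue_records["method"]) \
            == set(tiny_config.methods)

    def test_round_trip_through_csv(self, tiny_config, tmp_path):
        tables = generate_study(tiny_config)
        write_tables(tables, tmp_path)
        back = read_tables(tmp_path)
        pd.testing.assert_frame_equal(
            back.residue_records, tables.residue_records,
            check_dtype=False)
        assert set(back.odorant_records.columns) \
            >= {"diet", "p_cresol", "nh3"}

    def test_noiseless_closure_of_kinetics_and_regressions(
            self, noiseless_tables, noiseless_tiny_config):
        cfg = noiseless_tiny_config
        # gas curves reproduce the generating triples exactly
        one = noiseless_tables.gas_curves.query(
            "diet == 'W1' and method == 'S' and replicate == 1")
        assert one["cum_ml"].to_numpy() == pytest.approx(
            model_g(one["time_h"].to_numpy(),
                    *cfg.kinetic_params["W1"]["S"]))
        # odorant regression returns the generating coefficients
        odor = noiseless_tables.odorant_records
        fit = fit_prediction_equation(odor["ivfcpd"], odor["p_cresol"])
        assert fit.slope == pytest.approx(
            cfg.odorant_models["p_cresol"]["slope"], abs=1e-9)
        assert fit.intercept == pytest.approx(
            cfg.odorant_models["p_cresol"]["intercept"], abs=1e-7)

    def test_sample_ccc_converges_to_target(self, default_config):
        """~500 paired samples at target CCC 0.95: sample CCC within
        0.02 of the target."""
        cfg = make_tiny_config(default_config, seed=3)
        cfg.diets = {d: v for d, v in
                     StudyConfig.default().diets.items()}
        cfg.invivo_attd = StudyConfig.default().invivo_attd
        cfg.methods = ["D"]
        cfg.kinetic_params = {d: {"D": StudyConfig
                                  .default().kinetic_params[d]["D"]}
                              for d in cfg.diets}
        cfg.replicates = 84          # 6 diets x 84 = 504 pairs
        cfg.fermentation_times_h = [48]
        cfg.ferm_time_fraction = {48: 1.0}
        cfg.gas_sampling_times_h = np.array([1.0, 6, 12, 24, 48.0])
        cfg.agreement = {"dm": {"r": 0.98, "ccc": 0.95},
                         "cp": {"r": 0.98, "ccc": 0.95}}
        tables = generate_study(cfg)
        long = digestibility_table(tables.residue_records)
        dm = long[long["nutrient"] == "DM"]
        vivo = tables.invivo_records.assign(
            x=lambda df: 100 * (1 - df["aia_diet_pct"]
                                / df["aia_feces_pct"]))
        pairs = dm.merge(vivo[["diet", "pen", "x"]],
                         left_on=["diet", "replicate"],
                         right_on=["diet", "pen"])
        ccc = lin_ccc(pairs["x"], pairs["total_pct"])
        assert ccc == pytest.approx(0.95, abs=0.02)

    def test_config_validation_errors(self, tiny_config):
        import copy
        bad = copy.deepcopy(tiny_config)
        del bad.kinetic_params["W1"]["S"]
        with pytest.raises(ConfigError, match="missing cells"):
            bad.validate()
        bad2 = copy.deepcopy(tiny_config)
        bad2.replicates = 1
        with pytest.raises(ConfigError, match="replicates"):
            bad2.validate()
        bad3 = copy.deepcopy(tiny_config)
        bad3.noise["gas_increment_sd_ml"] = -1.0
        with pytest.raises(ConfigError):
            bad3.validate()
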