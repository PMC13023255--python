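import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fermkin import (correlation_matrix, factorial_anova,
                     fit_prediction_equation, lsd_letters, pearson)
from fermkin.association import LinearPredictionEquation


class TestPredictionEquation:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = fit_prediction_equation(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_ols(self):
        fit = fit_prediction_equation([0, 1, 2], [0, 1, 3])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-1 / 6)
        assert fit.r_squared == pytest.approx(27 / 28, abs=1e-4)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = 1.3 * x + rng.normal(size=40)
        fit = fit_prediction_equation(x, y)
        r, _ = pearson(x, y)
        assert fit.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_recovers_generating_coefficients(self):
        """Data simulated from a published prediction line (slope
        -0.7524, intercept 27.3514) with sd 0.3 at n=60."""
        rng = np.random.default_rng(12)
        x = rng.uniform(5, 30, 60)
        y = -0.7524 * x + 27.3514 + rng.normal(0, 0.3, 60)
        fit = fit_prediction_equation(x, y)
        assert fit.slope == pytest.approx(-0.7524, rel=0.05)

    def test_coefficient_bias_vanishes_with_n(self):
        biases = []
        for n in (20, 200, 2000):
            rng = np.random.default_rng(5)
            x = rng.uniform(0, 10, n)
            y = 2.0 * x + 1.0 + rng.normal(0, 1.0, n)
            biases.append(abs(fit_prediction_equation(x, y).slope - 2.0))
        assert biases[2] < biases[0]

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            LinearPredictionEquation().fit([1, 1, 1, 1], [1, 2, 3, 4])

    def test_estimator_predicts(self):
        est = LinearPredictionEquation().fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert est.predict([10]) == pytest.approx([21.0])


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        cm = correlation_matrix(df)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T)
        assert (cm.stars.values[np.diag_indices(3)] == "").all()

    def test_independent_columns_unstarred(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"u": rng.normal(size=50),
                               "v": rng.normal(size=50)})
            cm = correlation_matrix(df)
            hits += (abs(cm.r.loc["u", "v"]) < 0.3
                     and cm.stars.loc["u", "v"] == "")
        assert hits >= 36      # ~95% of independent draws

    def test_near_perfect_association_double_starred(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": x + rng.normal(0, 0.05, 30)})
        assert correlation_matrix(df).stars.loc["x", "y"] == "**"

    def test_constant_column_dropped_with_flag(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "k": [5.0, 5, 5, 5],
                           "y": [2.0, 4, 6, 9]})
        cm = correlation_matrix(df)
        assert cm.dropped == ["k"]
        assert list(cm.r.columns) == ["x", "y"]


def brute_force_ss(df):
    """Balanced two-way SS decomposition from cell/marginal means."""
    y = df["value"].to_numpy()
    grand = y.mean()
    ss = {"total": ((y - grand) ** 2).sum()}
    for eff, col in (("method", "method"), ("time", "time_h")):
        ss[eff] = sum(len(g) * (g["value"].mean() - grand) ** 2
                      for _, g in df.groupby(col))
    ss_cells = sum(len(g) * (g["value"].mean() - grand) ** 2
                   for _, g in df.groupby(["method", "time_h"]))
    ss["interaction"] = ss_cells - ss["method"] - ss["time"]
    ss["error"] = ss["total"] - ss_cells
    return ss


class TestFactorialAnova:
    @staticmethod
    def _design(cells, n, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (m, t), mu in cells.items():
            for _ in range(n):
                rows.append({"method": m, "time_h": t,
                             "value": mu + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_all_equal_gives_zero_effect_ss(self):
        df = self._design({(m, t): 5.0 for m in "SD" for t in (12, 48)},
                          n=3)
        res = factorial_anova(df, "value")
        assert res.ss["method"] == pytest.approx(0.0, abs=1e-12)
        assert res.ss["time"] == pytest.approx(0.0, abs=1e-12)

    def test_toy_design_matches_brute_force_oracle(self):
        cells = {("A", 1): 11.0, ("A", 2): 21.0, ("B", 1): 31.0,
                 ("B", 2): 41.0}
        df = pd.DataFrame([{"method": m, "time_h": t, "value": v}
                           for (m, t), mu in cells.items()
                           for v in (mu - 1, mu + 1)])
        res = factorial_anova(df, "value")
        oracle = brute_force_ss(df)
        for eff in ("method", "time", "interaction", "error"):
            assert res.ss[eff] == pytest.approx(oracle[eff], abs=1e-9)

    def test_ss_additivity_on_random_balanced_designs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cells = {(m, t): rng.normal(20, 5)
                     for m in ("S", "D", "SD") for t in (12, 48)}
            df = self._design(cells, n=4, sd=2.0, seed=seed)
            res = factorial_anova(df, "value")
            total = sum(res.ss.values())
            oracle = brute_force_ss(df)
            assert total == pytest.approx(oracle["total"], rel=1e-9)

    def test_unbalanced_design_rejected(self):
        df = self._design({("S", 12): 1.0, ("D", 12): 2.0}, n=3)
        res_df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="unbalanced"):
            factorial_anova(res_df, "value")

    def test_method_effect_detected_with_power(self):
        """A 5-unit method effect against sd 1 noise at n=6 should be
        declared significant in nearly every replicate."""
        detected = 0
        for seed in range(100):
            cells = {("S", 12): 25.0, ("D", 12): 20.0, ("SD", 12): 20.0,
                     ("S", 48): 25.0, ("D", 48): 20.0, ("SD", 48): 20.0}
            df = self._design(cells, n=6, sd=1.0, seed=seed)
            res = factorial_anova(df, "value")
            detected += res.p["method"] < 0.05
        assert detected >= 95

    def test_degenerate_cells_suppress_letters(self):
        df = self._design({(m, t): float(ord(m[0]))
                           for m in "SD" for t in (12, 48)}, n=2)
        res = factorial_anova(df, "value")
        assert res.degenerate and res.letters == {}, res.ms_error


class TestLSDLetters:
    def test_all_equal_share_one_letter(self):
        out = lsd_letters({"S": 10.0, "D": 10.0, "SD": 10.0},
                          ms_error=1.0, n_cell=6, df_error=30)
        assert set(out.values()) == {"a"}

    def test_clearly_separated_means(self):
        out = lsd_letters({"S": 30.0, "D": 20.0, "SD": 10.0},
                          ms_error=1e-6, n_cell=6, df_error=30)
        assert out == {"S": "a", "D": "b", "SD": "c"}

    def test_partial_overlap(self):
        # LSD ~ 2: 30 and 29 share a letter, 10 stands alone
        out = lsd_letters({"x": 30.0, "y": 29.0, "z": 10.0},
                          ms_error=0.96, n_cell=2, df_error=30)
        assert out["x"] == out["y"] == "a"
        assert out["z"] == "b"

    def test_letters_agree_with_all_pairs_oracle(self):
        """Two groups share a letter iff their difference is within the
        LSD threshold, over 100 random mean sets."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            k = rng.integers(2, 7)
            means = {f"g{i}": float(rng.uniform(0, 10)) for i in range(k)}
            ms_error, n, dfe = 1.5, 5, 24
            lsd = stats.t.ppf(0.975, dfe) * np.sqrt(2 * ms_error / n)
            letters = lsd_letters(means, ms_error, n, dfe)
            for a, b in itertools.combinations(means, 2):
                share = bool(set(letters[a]) & set(letters[b]))
                differ = abs(means[a] - means[b]) > lsd
                assert share != differ, (seed, means, letters)
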