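"""Statistics-pipeline tests against independent textbook implementations."""

import numpy as np
import pandas as pd
import pytest

from rmlsim.analysis import (
    akaike_weights,
    anova_load,
    bin_foraging,
    bin_speeded,
    compose_dacc_signal,
    fit_polynomial_aic,
    linear_trend_ttest,
    participant_slopes,
)


def aic_reference(x, y, deg):
    """Independent AIC evaluation: n ln(RSS/n) + 2k, k = deg + 2."""
    coeffs = np.polyfit(x, y, deg)
    rss = float(np.sum((y - np.polyval(coeffs, x)) ** 2))
    return len(x) * np.log(rss / len(x)) + 2 * (deg + 2)


class TestPolynomialAIC:
    def test_aic_matches_formula_oracle_on_hand_dataset(self):
        x = np.arange(7.0)
        y = np.array([2.0, 1.0, 3.5, 2.2, 4.8, 4.1, 6.0])
        table = fit_polynomial_aic(x, y, degrees=(1, 2, 4))
        for deg in (1, 2, 4):
            assert table.loc[deg, "aic"] == pytest.approx(
                aic_reference(x, y, deg), abs=1e-10
            )

    def test_weights_sum_to_one(self):
        w = akaike_weights([103.2, 99.5, 120.0, 99.6])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        x = np.arange(-5, 6.0)
        y = x**2 + 0.1 * np.sin(x)
        table = fit_polynomial_aic(x, y, degrees=(1, 2, 4))
        assert table["akaike_weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_generative_quartic_recovered(self):
        rng = np.random.default_rng(0)
        x = np.arange(-5, 6.0)
        y = 0.05 * x**4 - 0.8 * x**2 + 3 + 0.05 * rng.standard_normal(x.size)
        table = fit_polynomial_aic(x, y, degrees=(2, 4))
        assert table.loc[4, "akaike_weight"] > 0.999
        assert table.loc[4, "leading_coeff"] > 0

    def test_linear_data_prefers_linear_over_quadratic(self):
        rng = np.random.default_rng(1)
        x = np.arange(-5, 6.0)
        y = 1.3 * x + 0.2 + 0.05 * rng.standard_normal(x.size)
        table = fit_polynomial_aic(x, y, degrees=(1, 2))
        assert table.loc[2, "akaike_weight"] < 0.5

    def test_rank_deficient_design_raises(self):
        with pytest.raises(ValueError):
            fit_polynomial_aic([1, 1, 1, 1, 1, 1, 1], np.arange(7.0), degrees=(4,))
        with pytest.raises(ValueError):
            fit_polynomial_aic(np.arange(4.0), np.arange(4.0), degrees=(4,))


class TestTrendTest:
    def test_symmetric_slopes_give_zero_t(self):
        res = linear_trend_ttest([-1.0, 1.0, -2.0, 2.0])
        assert res["t"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        res = linear_trend_ttest([1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res["df"] == 2

    def test_df_is_participants_minus_one(self):
        res = linear_trend_ttest(np.random.default_rng(2).normal(1, 0.1, 15))
        assert res["df"] == 14

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            linear_trend_ttest([1.0])


class TestAnova:
    def manual_rm_anova(self, a):
        """Independent sums-of-squares decomposition (the oracle)."""
        n, L = a.shape
        grand = a.mean()
        ss_cond = n * ((a.mean(0) - grand) ** 2).sum()
        ss_subj = L * ((a.mean(1) - grand) ** 2).sum()
        ss_err = ((a - grand) ** 2).sum() - ss_cond - ss_subj
        return (ss_cond / (L - 1)) / (ss_err / ((L - 1) * (n - 1)))

    def test_constant_table_gives_zero_f(self):
        table = pd.DataFrame(np.full((5, 4), 0.87))
        res = anova_load(table)
        assert res["F"] == 0.0

    def test_toy_table_matches_sums_of_squares_oracle(self):
        a = np.array([[0.9, 0.7], [0.8, 0.75], [0.95, 0.6]])
        res = anova_load(pd.DataFrame(a))
        assert res["F"] == pytest.approx(self.manual_rm_anova(a), abs=1e-10)
        assert (res["df1"], res["df2"]) == (1, 2)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        a = rng.uniform(0.6, 1.0, size=(15, 4))
        df = pd.DataFrame(a, columns=[1, 4, 6, 8])
        long = df.reset_index().melt(
            id_vars="index", var_name="load", value_name="acc"
        )
        sm = AnovaRM(long, depvar="acc", subject="index", within=["load"]).fit()
        res = anova_load(df)
        assert res["F"] == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0]), abs=1e-8
        )
        assert res["df1"] == 3 and res["df2"] == 42

    def test_missing_cells_raise(self):
        table = pd.DataFrame([[0.9, np.nan], [0.8, 0.7]])
        with pytest.raises(ValueError):
            anova_load(table)


def toy_speeded_records():
    rows = []
    rng = np.random.default_rng(4)
    for p in range(3):
        for d in range(-5, 6):
            for _ in range(6 - abs(d)):
                rows.append({
                    "participant": p,
                    "value_difference": d,
                    "boost": 5.0 - 0.1 * d * d + 0.01 * rng.standard_normal(),
                    "value_regressor": 3.0 + 0.1 * d * d,
                    "surprise_regressor": abs(d) / 2,
                    "correct": True,
                    "rt_cycles": 1000 + 50 * abs(d),
                    "timed_out": False,
                })
    return pd.DataFrame(rows)


class TestBinning:
    def test_speeded_bins_match_groupby_oracle(self):
        rec = toy_speeded_records()
        table = bin_speeded(rec)
        assert list(table.index) == list(range(-5, 6))
        # independent two-stage group-by
        manual = (
            rec.groupby(["participant", "value_difference"])["boost"].mean()
            .groupby("value_difference").mean()
        )
        assert np.allclose(table["boost"], manual)
        # occupancy equals grid combinatorics times participants
        assert list(table["n_trials"]) == [3 * (6 - abs(d)) for d in range(-5, 6)]

    def test_empty_bin_raises(self):
        rec = toy_speeded_records()
        with pytest.raises(ValueError):
            bin_speeded(rec[rec.value_difference != 0])

    def test_compose_recipes(self):
        rec = toy_speeded_records()
        table = bin_speeded(rec)
        composed = compose_dacc_signal(table, "speeded")
        assert np.allclose(composed, table["value"] + table["boost"])
        wm_like = table.rename(columns={"boost": "boost"})
        assert np.allclose(compose_dacc_signal(wm_like, "wm"), table["boost"])
        with pytest.raises(ValueError):
            compose_dacc_signal(table, "unknown-task")

    def test_compose_additivity(self):
        rec = toy_speeded_records()
        table = bin_speeded(rec)
        shifted = table.copy()
        shifted["value"] = shifted["value"] + 2.5
        assert np.allclose(
            compose_dacc_signal(shifted, "speeded"),
            compose_dacc_signal(table, "speeded") + 2.5,
        )

    def test_foraging_bins_match_groupby_oracle(self):
        rng = np.random.default_rng(5)
        n = 4000
        fv = rng.uniform(3, 6, n)
        rec = pd.DataFrame({
            "participant": rng.integers(0, 4, n),
            "forage_value": fv,
            "choice_difficulty": -np.abs(fv - 4.5),
            "boost": 5 - (fv - 4.5) ** 2 + 0.1 * rng.standard_normal(n),
            "value_regressor": fv,
        })
        table = bin_foraging(rec, by="forage_value", n_bins=8)
        assert len(table) == 8
        assert table["n_trials"].sum() == n
        assert np.allclose(
            table["composite"],
            table["boost"] + (table["composite"] - table["boost"]),
        )
        # constant boost -> flat profile
        rec2 = rec.assign(boost=3.3)
        flat = bin_foraging(rec2, by="choice_difficulty", n_bins=8)
        assert np.allclose(flat["boost"], 3.3)

    def test_participant_slopes_match_polyfit(self):
        per = pd.DataFrame({
            "participant": [0, 0, 0, 1, 1, 1],
            "load": [1, 4, 8, 1, 4, 8],
            "boost": [1.0, 2.0, 4.0, 2.0, 2.0, 2.0],
        })
        slopes = participant_slopes(per, "load", "boost")
        assert slopes[0] == pytest.approx(
            np.polyfit([1, 4, 8], [1, 2, 4], 1)[0]
        )
        assert slopes[1] == pytest.approx(0.0)
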