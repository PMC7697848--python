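"""Time-bin peaks and the ANOVA/Tukey/regression machinery, with
independent statsmodels and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from betabalance._anova import additive_two_way_anova, tukey_hsd
from betabalance.binstats import (
    TIME_BINS,
    ability_association,
    confound_regressions,
    magnitude_anova,
    peak_in_bin,
    pre_post_anova,
)


class TestPeakInBin:
    times = np.linspace(-857.0, 1857.0, 200)

    def test_monotone_trace_peaks_at_last_center(self):
        trace = np.linspace(0, 1, 200)
        in_bin = (self.times >= 0) & (self.times <= 400)
        assert peak_in_bin(self.times, trace, (0, 400)) == trace[in_bin][-1]

    def test_zero_trace_gives_zero(self):
        assert peak_in_bin(self.times, np.zeros(200), (0, 400)) == 0.0

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            peak_in_bin(self.times, np.zeros(200), (100.0, 101.0))

    def test_overall_peak_bounds_subbin_peaks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            trace = rng.standard_normal(200)
            overall = peak_in_bin(self.times, trace, TIME_BINS["overall"])
            early = peak_in_bin(self.times, trace, TIME_BINS["early"])
            late = peak_in_bin(self.times, trace, TIME_BINS["late"])
            assert overall >= max(early, late)


class TestAdditiveAnova:
    def random_table(self, seed, n_a=3, n_b=5, reps=1):
        rng = np.random.default_rng(seed)
        a = np.repeat(np.arange(n_a), n_b * reps)
        b = np.tile(np.repeat(np.arange(n_b), reps), n_a)
        y = rng.standard_normal(a.size)
        return y, a, b

    def test_sum_of_squares_additivity(self):
        for seed in range(5):
            y, a, b = self.random_table(seed, reps=2)
            res = additive_two_way_anova(y, a, b)
            total = res.ss["A"] + res.ss["B"] + res.ss["residual"]
            assert total == pytest.approx(res.ss["total"], rel=1e-8)

    def test_matches_statsmodels_ols(self):
        y, a, b = self.random_table(42)
        res = additive_two_way_anova(y, a, b)
        df = pd.DataFrame({"y": y, "a": a.astype(str), "b": b.astype(str)})
        tab = anova_lm(ols("y ~ C(a) + C(b)", data=df).fit(), typ=2)
        assert res.factor_F["A"] == pytest.approx(tab.loc["C(a)", "F"], rel=1e-8)
        assert res.factor_F["B"] == pytest.approx(tab.loc["C(b)", "F"], rel=1e-8)
        assert res.factor_p["A"] == pytest.approx(tab.loc["C(a)", "PR(>F)"], rel=1e-8)

    def test_single_level_factor_reduces_to_one_way(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(12)
        a = np.repeat([0, 1, 2], 4)
        b = np.zeros(12, dtype=int)  # single participant
        res = additive_two_way_anova(y, a, b)
        f_ref, p_ref = stats.f_oneway(y[a == 0], y[a == 1], y[a == 2])
        assert res.factor_F["A"] == pytest.approx(f_ref, rel=1e-10)
        assert res.factor_p["A"] == pytest.approx(p_ref, rel=1e-10)

    def test_unbalanced_rejected(self):
        y, a, b = self.random_table(3)
        with pytest.raises(ValueError):
            additive_two_way_anova(y[:-1], a[:-1], b[:-1])

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(11)
        a = np.repeat(np.arange(3), 4)
        b = np.tile(np.arange(4), 3)
        Y = rng.standard_normal((12, 6))
        vec = additive_two_way_anova(Y, a, b)
        for j in range(6):
            sc = additive_two_way_anova(Y[:, j], a, b)
            assert vec.factor_F["A"][j] == pytest.approx(sc.factor_F["A"])
            assert vec.factor_p["B"][j] == pytest.approx(sc.factor_p["B"])


class TestTukey:
    def test_matches_explicit_studentized_range(self):
        # fixed 3x3 table: magnitudes x participants, one observation per cell
        table = np.array([
            [1.2, 0.8, 1.5],
            [2.4, 2.9, 2.2],
            [4.1, 3.6, 4.4],
        ])
        y = table.ravel()
        mag = np.repeat(["s", "m", "l"], 3)
        part = np.tile(["p1", "p2", "p3"], 3)
        res = additive_two_way_anova(y, mag, part, names=("magnitude", "participant"))

        # brute-force oracle: explicit SS decomposition
        grand = y.mean()
        ss_mag = 3 * sum((table[i].mean() - grand) ** 2 for i in range(3))
        ss_part = 3 * sum((table[:, j].mean() - grand) ** 2 for j in range(3))
        ss_tot = ((y - grand) ** 2).sum()
        ss_res = ss_tot - ss_mag - ss_part
        mse = ss_res / 4
        f_mag = (ss_mag / 2) / mse
        assert res.factor_F["magnitude"] == pytest.approx(f_mag, rel=1e-8)
        assert res.mse == pytest.approx(mse, rel=1e-8)

        means = {m: table[i].mean() for i, m in enumerate(["s", "m", "l"])}
        hsd = tukey_hsd(means, 3, res.mse, res.df["residual"], alpha=0.05)
        for rec in hsd:
            lo, hi = rec["pair"]
            q_oracle = abs(means[hi] - means[lo]) / np.sqrt(mse / 3)
            assert rec["q"] == pytest.approx(q_oracle, rel=1e-10)
            p_oracle = stats.studentized_range.sf(q_oracle, 3, 4)
            assert rec["p_adj"] == pytest.approx(p_oracle, rel=1e-8)

    def test_no_significance_when_levels_identical(self):
        peaks = pd.DataFrame(
            {
                "participant": np.tile([f"P{i}" for i in range(4)], 3),
                "magnitude": np.repeat(["small", "medium", "large"], 4),
                "peak_db": np.tile([1.0, 2.0, 3.0, 4.0], 3),
            }
        )
        res = magnitude_anova(peaks)
        assert not any(r["significant"] for r in res.posthoc)


class TestPrePost:
    def test_equal_pre_post_gives_zero_f(self):
        pre = np.array([1.0, 2.0, 3.0])
        part = np.array(["a", "b", "c"])
        res = pre_post_anova(pre, pre, part)
        assert res.factor_F["time_bin"] == pytest.approx(0.0, abs=1e-20)

    def test_large_noise_free_shift_is_overwhelming(self):
        pre = np.array([1.0, 2.0, 3.0])
        res = pre_post_anova(pre, pre + 50.0, np.array(["a", "b", "c"]))
        assert res.factor_p["time_bin"] < 1e-6

    def test_hand_table_matches_explicit_formulas(self):
        pre = np.array([60.0, 65.0, 70.0])
        post = np.array([68.0, 71.0, 75.0])
        part = np.array(["a", "b", "c"])
        res = pre_post_anova(pre, post, part)
        df = pd.DataFrame(
            {
                "y": np.concatenate([pre, post]),
                "bin": ["pre"] * 3 + ["post"] * 3,
                "p": list(part) * 2,
            }
        )
        tab = anova_lm(ols("y ~ C(bin) + C(p)", data=df).fit(), typ=2)
        assert res.factor_F["time_bin"] == pytest.approx(tab.loc["C(bin)", "F"], rel=1e-8)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            pre_post_anova(np.zeros(3), np.zeros(2), np.array(["a", "b"]))


class TestMagnitudeAnova:
    def test_incomplete_participants_dropped(self):
        peaks = pd.DataFrame(
            {
                "participant": ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 2,
                "magnitude": ["small", "medium", "large"] * 2 + ["small", "medium"],
                "peak_db": [1, 2, 3, 1.5, 2.5, 3.5, 1.2, 2.2],
            }
        )
        res = magnitude_anova(peaks)  # P3 lacks large and must be excluded
        assert res.df["participant"] == 1

    def test_single_level_rejected(self):
        peaks = pd.DataFrame(
            {"participant": ["P1", "P2"], "magnitude": ["small"] * 2,
             "peak_db": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            magnitude_anova(peaks)

    def test_type_one_error_calibrated_under_null(self):
        """Rejection rate of the magnitude F test on null peak tables
        (6 participants, no magnitude effect) stays near alpha = 0.05."""
        rng = np.random.default_rng(123)
        n_rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = rng.standard_normal(18) + np.tile(rng.standard_normal(6), 3)
            peaks = pd.DataFrame(
                {
                    "participant": np.tile([f"P{i}" for i in range(6)], 3),
                    "magnitude": np.repeat(["small", "medium", "large"], 6),
                    "peak_db": y,
                }
            )
            res = magnitude_anova(peaks)
            n_rej += res.factor_p["magnitude"] < 0.05
        rate = n_rej / n_rep
        tol = 4 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < tol


class TestAbility:
    def make_peaks(self, slope=0.0, seed=0, n=12):
        rng = np.random.default_rng(seed)
        parts = [f"P{i}" for i in range(n)]
        abilities = {p: rng.uniform(0.1, 1.0) for p in parts}
        rows = []
        for p in parts:
            for m, base in zip(["small", "medium", "large"], [1.0, 2.0, 3.0]):
                rows.append(
                    {
                        "participant": p,
                        "magnitude": m,
                        "bin": "late",
                        "peak_db": base + slope * abilities[p]
                        + 0.05 * rng.standard_normal(),
                    }
                )
        return pd.DataFrame(rows), abilities

    def test_flat_ability_effect_recovers_near_zero_slope(self):
        peaks, abilities = self.make_peaks(slope=0.0, seed=1)
        out = ability_association(peaks, abilities, "late")
        assert abs(out["model_slope"]) < 0.3

    def test_injected_negative_slope_recovered(self):
        peaks, abilities = self.make_peaks(slope=-2.0, seed=2)
        out = ability_association(peaks, abilities, "late")
        assert out["model_slope"] == pytest.approx(-2.0, abs=0.3)
        assert out["model_p"] < 0.05

    def test_univariate_r2_is_squared_pearson(self):
        peaks, abilities = self.make_peaks(slope=-1.0, seed=3)
        out = ability_association(peaks, abilities, "late")
        per_part = peaks.groupby("participant")["peak_db"].mean()
        r, _ = stats.pearsonr(
            [abilities[p] for p in per_part.index], per_part.to_numpy()
        )
        assert out["univariate"]["r2"] == pytest.approx(r**2, rel=1e-8)

    def test_constant_ability_rejected(self):
        peaks, _ = self.make_peaks()
        with pytest.raises(ValueError):
            ability_association(peaks, {p: 0.5 for p in peaks["participant"]}, "late")


class TestConfounds:
    def test_constant_success_rate_flagged_degenerate(self):
        rates = {f"P{i}": 100.0 for i in range(5)}
        abilities = {f"P{i}": 0.5 + 0.1 * i for i in range(5)}
        peaks = pd.DataFrame(
            {"participant": [f"P{i}" for i in range(5)], "magnitude": "large",
             "bin": "overall", "peak_db": np.arange(5.0)}
        )
        out = confound_regressions(rates, abilities, peaks)
        assert out["ability_vs_success"] == {"degenerate": True}
        assert out["peak_vs_success_overall"] == {"degenerate": True}

    def test_four_point_regression_matches_least_squares(self):
        rates = {"P0": 25.0, "P1": 50.0, "P2": 75.0, "P3": 100.0}
        abilities = {"P0": 0.3, "P1": 0.5, "P2": 0.4, "P3": 0.9}
        peaks = pd.DataFrame(
            {"participant": list(rates), "magnitude": "large", "bin": "overall",
             "peak_db": [4.0, 3.0, 3.5, 2.0]}
        )
        out = confound_regressions(rates, abilities, peaks)
        x = np.array(list(rates.values()))
        y = np.array([abilities[p] for p in rates])
        slope, intercept, r, p, _ = stats.linregress(x, y)
        assert out["ability_vs_success"]["slope"] == pytest.approx(slope, rel=1e-8)
        assert out["ability_vs_success"]["p"] == pytest.approx(p, rel=1e-6)
        assert out["ability_vs_success"]["r2"] == pytest.approx(r**2, rel=1e-8)

    def test_independent_rates_not_significant_at_large_n(self):
        rng = np.random.default_rng(77)
        n = 200
        rates = {f"P{i}": rng.uniform(0, 100) for i in range(n)}
        abilities = {f"P{i}": rng.uniform(0.1, 1.0) for i in range(n)}
        peaks = pd.DataFrame(
            {"participant": list(rates), "magnitude": "large", "bin": "overall",
             "peak_db": rng.standard_normal(n)}
        )
        out = confound_regressions(rates, abilities, peaks)
        assert out["ability_vs_success"]["p"] > 0.05
        assert out["peak_vs_success_overall"]["p"] > 0.05

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            confound_regressions({"P0": 1.0, "P1": 2.0}, {}, pd.DataFrame())
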