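"""RCB ANOVA, planned contrasts, convergence rule, Tukey letters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nstwindow.simulate import simulate_residues
from nstwindow.trial_io import apply_lod_policy
from nstwindow.config import AnalysisConfig
from nstwindow.windows import (
    CONTRAST_SETS,
    ContrastResult,
    contrast_table,
    convergence_date,
    planned_contrast,
    rcb_anova,
    reconcile_years,
    tukey_hsd,
)

from conftest import make_config


def _frame(values):
    """values: {(treatment, block): y}"""
    return pd.DataFrame(
        [{"treatment": t, "block": b, "value": v} for (t, b), v in values.items()]
    )


class TestRcbAnova:
    def test_hand_decomposition_2x2(self):
        """SS_treat=16, SS_block=4, SS_err=1 for the 2x2 hand case."""
        df = _frame({("A", "b1"): 1, ("A", "b2"): 2, ("B", "b1"): 4, ("B", "b2"): 7})
        res = rcb_anova(df)
        assert res.ss_treatment == pytest.approx(16.0)
        assert res.ss_block == pytest.approx(4.0)
        assert res.ss_error == pytest.approx(1.0)
        assert res.f_treatment == pytest.approx(16.0)
        assert res.f_block == pytest.approx(4.0)
        assert (res.df_treatment, res.df_block, res.df_error) == (1, 1, 1)

    def test_all_equal_gives_zero_f(self):
        df = _frame({(t, b): 3.0 for t in "ABC" for b in ("b1", "b2")})
        res = rcb_anova(df)
        assert res.f_treatment == 0.0

    def test_exact_ss_decomposition(self, rng):
        """Balanced data: SS_total = SS_treat + SS_block + SS_error exactly."""
        df = _frame({
            (t, b): rng.normal() for t in "ABCD" for b in ("b1", "b2", "b3", "b4")
        })
        res = rcb_anova(df)
        assert res.ss_total == pytest.approx(
            res.ss_treatment + res.ss_block + res.ss_error, rel=1e-9
        )

    def test_agrees_with_statsmodels_oracle(self, rng):
        """Independent route: OLS + anova_lm on the same layout."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = _frame({
            (t, b): rng.normal() for t in "ABCD" for b in ("b1", "b2", "b3", "b4")
        })
        res = rcb_anova(df)
        fit = smf.ols("value ~ C(treatment) + C(block)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res.f_treatment == pytest.approx(table.loc["C(treatment)", "F"])
        assert res.f_block == pytest.approx(table.loc["C(block)", "F"])
        assert res.p_treatment == pytest.approx(table.loc["C(treatment)", "PR(>F)"])

    def test_missing_cell_is_explicit_error(self):
        df = _frame({("A", "b1"): 1, ("A", "b2"): 2, ("B", "b1"): 4})
        with pytest.raises(ValueError, match="unbalanced"):
            rcb_anova(df)

    def test_null_type_one_error(self):
        """Monte Carlo: under no treatment effect the 4x4 design rejects at
        alpha=0.05 within 0.05 +/- 0.02 (2000 replicates)."""
        rng = np.random.default_rng(808)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            y = rng.normal(size=(4, 4)) + rng.normal(size=(1, 4))  # block effects
            df = pd.DataFrame({
                "treatment": np.repeat(list("ABCD"), 4),
                "block": np.tile(["b1", "b2", "b3", "b4"], 4),
                "value": y.ravel(),
            })
            if rcb_anova(df).p_treatment <= 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestPlannedContrast:
    def test_one_way_toy_hand_value(self):
        """Groups N={2,4}, F={4,6}, L={1,1}; (N+F)/2 - L has estimate 3 and
        F = 9 on (1, 3) with MSE = 4/3."""
        df = pd.DataFrame({
            "treatment": ["N", "N", "F", "F", "L", "L"],
            "value": [2.0, 4.0, 4.0, 6.0, 1.0, 1.0],
        })
        c = planned_contrast(df, {"N": 0.5, "F": 0.5, "L": -1.0}, block=None)
        assert c.estimate == pytest.approx(3.0)
        assert c.F == pytest.approx(9.0)
        assert (c.df1, c.df2) == (1, 3)
        assert c.p == pytest.approx(float(stats.f.sf(9.0, 1, 3)))

    def test_equal_means_give_null_f(self, rng):
        df = _frame({(t, b): 2.0 + {"b1": 0, "b2": 1}[b]
                     for t in "NFLH" for b in ("b1", "b2")})
        c = planned_contrast(df, {"N": 0.5, "F": 0.5, "L": -1.0, "H": 0.0})
        assert c.F == pytest.approx(0.0, abs=1e-20)
        assert c.p == pytest.approx(1.0)

    def test_two_group_contrast_equals_pooled_t_squared(self, rng):
        """Weights (1, -1) on two groups reproduce the pooled two-sample t^2."""
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(0.8, 1.0, 6)
        df = pd.DataFrame({
            "treatment": ["A"] * 6 + ["B"] * 6,
            "value": np.r_[a, b],
        })
        c = planned_contrast(df, {"A": 1.0, "B": -1.0}, block=None)
        t_stat, _ = stats.ttest_ind(a, b, equal_var=True)
        assert c.F == pytest.approx(t_stat ** 2, rel=1e-9)

    def test_weights_must_sum_to_zero(self):
        df = _frame({(t, b): 1.0 * hash((t, b)) % 7
                     for t in "AB" for b in ("b1", "b2")})
        with pytest.raises(ValueError, match="sum to zero"):
            planned_contrast(df, {"A": 1.0, "B": -0.5})

    def test_missing_group_named(self):
        df = _frame({(t, b): 0.5 for t in "AB" for b in ("b1", "b2")})
        with pytest.raises(ValueError, match="C"):
            planned_contrast(df, {"A": 1.0, "C": -1.0})

    def test_zero_mse_flagged_infinite(self):
        df = _frame({("A", "b1"): 1.0, ("A", "b2"): 1.0,
                     ("B", "b1"): 2.0, ("B", "b2"): 2.0})
        c = planned_contrast(df, {"A": 1.0, "B": -1.0})
        assert math.isinf(c.F) and c.p == 0.0

    def test_rcb_error_df_matches_design(self):
        """4 treatments x 4 blocks of plot means -> error df 9."""
        rng = np.random.default_rng(5)
        df = _frame({(t, b): rng.normal()
                     for t in "NFLH" for b in ("b1", "b2", "b3", "b4")})
        c = planned_contrast(df, {"N": 0.5, "F": 0.5, "L": -1.0, "H": 0.0})
        assert c.df2 == 9


class TestConvergence:
    def _series(self, dpps, ps):
        return [ContrastResult(d, "x", 0.0, 1.0, 1, 9, p) for d, p in zip(dpps, ps)]

    def test_broken_run_restarts(self):
        s = self._series([15, 17, 20, 34], [0.001, 0.20, 0.01, 0.30])
        assert convergence_date(s, 0.05) == 34

    def test_sustained_run_starts_at_first_quiet_date(self):
        s = self._series([15, 17, 20, 34], [0.001, 0.01, 0.2, 0.3])
        assert convergence_date(s, 0.05) == 20

    def test_never_converges(self):
        s = self._series([15, 17, 20], [0.001, 0.01, 0.02])
        assert convergence_date(s, 0.05) is None

    def test_raising_alpha_never_earlier(self):
        """Demanding p > alpha for a larger alpha can only delay (or lose)
        the convergence date."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            s = self._series(range(10), rng.uniform(0, 0.5, 10))
            prev = None
            for alpha in (0.01, 0.05, 0.1, 0.25):
                d = convergence_date(s, alpha)
                d = math.inf if d is None else d
                if prev is not None:
                    assert d >= prev
                prev = d

    def test_reconcile_years_published_averages(self):
        assert reconcile_years([17, 20]) == pytest.approx(18.5)
        assert reconcile_years([15, 25]) == pytest.approx(20.0)
        assert reconcile_years([34]) == pytest.approx(34.0)
        with pytest.raises(ValueError):
            reconcile_years([])


class TestTukey:
    def test_all_equal_share_a_letter(self):
        out = tukey_hsd({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0},
                        mse=0.5, df_error=9, n_per_group=4)
        assert set(out["letters"]) == {"a"}

    def test_wide_separation_gets_distinct_letters(self):
        out = tukey_hsd({"lo": 0.0, "hi": 100.0}, mse=0.5, df_error=9,
                        n_per_group=4)
        assert out.set_index("group")["letters"].tolist() == ["a", "b"]

    def test_three_group_against_pairwise_oracle(self):
        """Every pair's letter-sharing must match the studentized-range
        pairwise decision computed independently."""
        means = {"x": 0.0, "y": 0.9, "z": 2.1}
        mse, dfe, n = 0.4, 9, 4
        out = tukey_hsd(means, mse, dfe, n).set_index("group")["letters"]
        q = stats.studentized_range.ppf(0.95, 3, dfe)
        hsd = q * math.sqrt(mse / n)
        for a in means:
            for b in means:
                if a >= b:
                    continue
                different = abs(means[a] - means[b]) > hsd
                share = bool(set(out[a]) & set(out[b]))
                assert share != different

    def test_degenerate_df_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": 1.0, "b": 2.0}, 0.5, 0, 4)


class TestContrastTable:
    def test_structure_and_log_scale(self):
        cfg = make_config()
        residues, _ = simulate_residues(cfg)
        residues = apply_lod_policy(residues, AnalysisConfig())
        table = contrast_table(residues)
        # one row per (year, region, dpp, contrast); seed absent late
        assert set(table["contrast"]) == set(CONTRAST_SETS)
        root = table[(table.region == "root") & (table.contrast == "untreated_vs_low")]
        assert sorted(root["dpp"]) == cfg.sampling_dpp["2015"]
        assert (table["df1"] == 1).all()
        assert (table["df2"] == 9).all()

    def test_rejects_nonpositive_concentrations(self):
        cfg = make_config()
        residues, _ = simulate_residues(cfg)
        residues.loc[residues.index[0], "conc"] = 0.0
        with pytest.raises(ValueError, match="LOD"):
            contrast_table(residues)

    def test_early_dates_significant_with_dose(self):
        """Dose-proportional C0 over background: earliest dates separate."""
        cfg = make_config()
        residues, _ = simulate_residues(cfg)
        residues = apply_lod_policy(residues, AnalysisConfig())
        table = contrast_table(residues)
        early = table[(table.dpp <= 9) & (table.region == "root")]
        assert early["significant"].all()
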