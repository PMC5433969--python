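import numpy as np
import pandas as pd
import pytest

from cetcond.evaluation import (
    GroundTruthReport,
    SingularDesignError,
    fit_condition_lm,
    ground_truth_assess,
    levene_test,
    partial_eta_squared,
    rank_indices,
)


class TestLevene:
    def test_identical_deviations_give_zero_statistic(self):
        w, p = levene_test([-1.0, 1.0, -1.0, 1.0], ["a", "a", "b", "b"])
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_insufficient_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            levene_test([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_type_one_error_calibrated(self):
        """Rejection rate under equal variances stays near nominal 5%."""
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            v = rng.normal(0, 1, 100)
            g = np.repeat(["a", "b"], 50)
            _, p = levene_test(v, g)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_power_against_ninefold_variance(self):
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            v = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 3, 50)])
            g = np.repeat(["a", "b"], 50)
            _, p = levene_test(v, g)
            hits += p < 0.05
        assert hits / n_rep >= 0.80


class TestConditionLm:
    def test_constant_response_gives_null_fit(self):
        df = pd.DataFrame(
            {"cod_class": ["acute", "chronic"] * 10, "age_class": ["adult"] * 20}
        )
        fit = fit_condition_lm(np.full(20, 3.0), df, ["cod_class"])
        assert fit.coef["cod_class[chronic]"] == pytest.approx(0.0, abs=1e-12)
        assert fit.adj_r_squared == pytest.approx(0.0, abs=1e-12)

    def test_binary_factor_coefficient_is_group_mean_difference(self):
        rng = np.random.default_rng(0)
        cod = np.repeat(["acute", "chronic"], 25)
        y = rng.normal(0, 1, 50) - 0.7 * (cod == "chronic")
        df = pd.DataFrame({"cod_class": cod})
        fit = fit_condition_lm(y, df, ["cod_class"])
        diff = y[cod == "chronic"].mean() - y[cod == "acute"].mean()
        assert fit.coef["cod_class[chronic]"] == pytest.approx(diff, rel=1e-10)

    def test_rank_deficient_design_names_alias(self):
        df = pd.DataFrame(
            {
                "cod_class": ["acute", "chronic"] * 10,
                "season": ["breeding", "nonbreeding"] * 10,  # aliased with cod
            }
        )
        with pytest.raises(SingularDesignError, match="aliased"):
            fit_condition_lm(np.arange(20.0), df, ["cod_class", "season"])

    def test_chronic_deficit_recovered_in_seeded_replicates(self):
        from cetcond.simulate import SynthConfig, generate_morphometrics

        cfg = SynthConfig()
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            records = generate_morphometrics(cfg, seed=seed)
            q = np.array([r.mass / r.length**2 for r in records])
            df = pd.DataFrame(
                {
                    "cod_class": [r.cod_class for r in records],
                    "age_class": [r.age_class for r in records],
                }
            )
            fit = fit_condition_lm(q, df, ["cod_class", "age_class"])
            coef = fit.coef["cod_class[chronic]"]
            p = fit.pvalues["cod_class[chronic]"]
            hits += (coef < 0) and (p < 0.05)
        assert hits / n_rep >= 0.95


class TestPartialEtaSquared:
    def test_single_predictor_equals_r_squared(self):
        rng = np.random.default_rng(1)
        cod = np.repeat(["acute", "chronic"], 30)
        y = rng.normal(0, 1, 60) - 0.8 * (cod == "chronic")
        df = pd.DataFrame({"cod_class": cod})
        fit = fit_condition_lm(y, df, ["cod_class"])
        assert partial_eta_squared(fit, "cod_class") == pytest.approx(
            fit.r_squared, rel=1e-10
        )

    def test_balanced_two_by_two_matches_hand_computed_ss(self):
        # 2x2 balanced orthogonal design, 2 obs per cell; SS by group means
        a = np.repeat(["acute", "chronic"], 4)
        b = np.tile(np.repeat(["adult", "juvenile"], 2), 2)
        y = np.array([10.0, 12.0, 7.0, 9.0, 6.0, 8.0, 5.0, 7.0])
        df = pd.DataFrame({"cod_class": a, "age_class": b})
        fit = fit_condition_lm(y, df, ["cod_class", "age_class"])
        grand = y.mean()
        ss_a = sum(
            4 * (y[a == lv].mean() - grand) ** 2 for lv in ("acute", "chronic")
        )
        ss_b = sum(
            4 * (y[b == lv].mean() - grand) ** 2 for lv in ("adult", "juvenile")
        )
        cell_means = {(x, z): y[(a == x) & (b == z)].mean() for x in set(a) for z in set(b)}
        ss_err = sum(
            (yi - cell_means[(x, z)]) ** 2 for yi, x, z in zip(y, a, b)
        )
        # additive model: error includes the (here zero) interaction cell term
        resid_err = fit.rss
        assert fit.ss_type2["cod_class"] == pytest.approx(ss_a, rel=1e-10)
        assert fit.ss_type2["age_class"] == pytest.approx(ss_b, rel=1e-10)
        assert partial_eta_squared(fit, "cod_class") == pytest.approx(
            ss_a / (ss_a + resid_err), rel=1e-10
        )
        assert 0.0 <= partial_eta_squared(fit, "age_class") <= 1.0

    def test_matches_statsmodels_type2_anova(self):
        rng = np.random.default_rng(4)
        n = 80
        df = pd.DataFrame(
            {
                "cod_class": rng.choice(["acute", "chronic"], n),
                "age_class": rng.choice(["adult", "juvenile", "calf"], n),
            }
        )
        y = (
            rng.normal(0, 1, n)
            - 0.5 * (df.cod_class == "chronic")
            + 0.8 * (df.age_class == "calf")
        )
        fit = fit_condition_lm(y, df, ["cod_class", "age_class"])
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        sdf = df.assign(y=y)
        res = smf.ols("y ~ C(cod_class) + C(age_class)", data=sdf).fit()
        an = sm.stats.anova_lm(res, typ=2)
        assert fit.ss_type2["cod_class"] == pytest.approx(
            an.loc["C(cod_class)", "sum_sq"], rel=1e-8
        )
        assert fit.ss_type2["age_class"] == pytest.approx(
            an.loc["C(age_class)", "sum_sq"], rel=1e-8
        )

    def test_zero_effect_gives_zero(self):
        a = np.repeat(["acute", "chronic"], 10)
        age = np.tile(np.repeat(["adult", "juvenile"], 5), 2)
        y = 2.0 - 1.0 * (age == "juvenile")  # no COD effect, noise-free
        df = pd.DataFrame({"cod_class": a, "age_class": age})
        fit = fit_condition_lm(y, df, ["cod_class", "age_class"])
        assert fit.ss_type2["cod_class"] == pytest.approx(0.0, abs=1e-16)


class TestVerdictsAndRanking:
    def _fit(self, coef_chronic=None, age_coefs=None, coef_breeding=None):
        terms, names, values = [], ["Intercept"], [1.0]
        if coef_chronic is not None:
            terms.append("cod_class")
            names.append("cod_class[chronic]")
            values.append(coef_chronic)
        if age_coefs is not None:
            terms.append("age_class")
            for lv, v in age_coefs.items():
                names.append(f"age_class[{lv}]")
                values.append(v)
        if coef_breeding is not None:
            terms.append("season")
            names.append("season[breeding]")
            values.append(coef_breeding)
        from cetcond.evaluation import LinearFit

        k = len(values)
        return LinearFit(
            terms=tuple(terms),
            coef=pd.Series(values, index=names),
            se=pd.Series(np.ones(k), index=names),
            pvalues=pd.Series(np.full(k, 0.01), index=names),
            n=100,
            rank=k,
            rss=1.0,
            tss=2.0,
        )

    def test_sign_rules(self):
        fit = self._fit(coef_chronic=-4e-4)
        assert ground_truth_assess(fit)["cod_class"] == "+"
        fit = self._fit(age_coefs={"juvenile": 0.5, "calf": 0.2})
        assert ground_truth_assess(fit)["age_class"] == "-"
        fit = self._fit(age_coefs={"juvenile": -0.5, "calf": -0.9})
        assert ground_truth_assess(fit)["age_class"] == "+"

    def test_dropped_term_is_na(self):
        fit = self._fit(coef_chronic=-1.0)
        v = ground_truth_assess(fit)
        assert v["season"] == "n/a"
        assert v["age_class"] == "n/a"

    def _report(self, name, age_verdict, adj_r2, retained=("cod_class", "age_class")):
        return GroundTruthReport(
            index=name,
            retained=tuple(retained),
            verdicts={"cod_class": "+", "age_class": age_verdict, "season": "n/a"},
            eta_partial={"cod_class": 0.19},
            adj_r_squared=adj_r2,
        )

    def test_published_verdict_pattern_recommends_quetelet(self):
        # verdict pattern of the summary table: the three blubber ratios and
        # Fulton's K fail on age class; mass/length leads on adjusted R2 but
        # the fitted exponent 2.33 redirects to mass/length^2
        reports = {
            "ventral_blubber": self._report("ventral_blubber", "+", 0.22),
            "blubber_over_girth": self._report("blubber_over_girth", "-", 0.09),
            "blubber_over_length": self._report("blubber_over_length", "-", 0.15),
            "girth_over_length": self._report("girth_over_length", "n/a", 0.19, ("cod_class",)),
            "mass_over_length": self._report("mass_over_length", "+", 0.72),
            "fulton_K": self._report("fulton_K", "-", 0.17),
            "quetelet": self._report("quetelet", "+", 0.50),
            "relative_condition": self._report("relative_condition", "+", 0.25),
            "residual_index": self._report("residual_index", "+", 0.21),
            "scaled_mass": self._report("scaled_mass", "n/a", 0.14, ("cod_class",)),
        }
        out = rank_indices(reports, beta=2.33, r_mass_over_length=0.8)
        assert out["recommended"] == "quetelet"
        assert out["provisional"] == "mass_over_length"

    def test_linear_scaling_keeps_mass_over_length(self):
        reports = {
            "mass_over_length": self._report("mass_over_length", "+", 0.6),
            "quetelet": self._report("quetelet", "+", 0.4),
        }
        out = rank_indices(reports, beta=1.0, r_mass_over_length=0.05)
        assert out["recommended"] == "mass_over_length"

    def test_all_contradicted_gives_no_recommendation(self):
        reports = {
            "a": self._report("a", "-", 0.5),
            "b": self._report("b", "-", 0.6),
        }
        out = rank_indices(reports, beta=2.33, r_mass_over_length=0.8)
        assert out["recommended"] is None
        assert out["survivors"] == []
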