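"""Censored regression: analytic limits, oracles, FDR, prevalence tests."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, norm

import viperpanel as vp
from viperpanel.panel_io import AnalyteDef, PanelMatrix, apply_lod_rules
from viperpanel.tobit import (
    AllCensoredError,
    TobitFit,
    _nll_and_grad,
    directional_fdr,
    lod_prevalence_compare,
    percent_change,
    tobit_fit,
)


def _censored_sample(rng, n=400, beta=(1.0, 0.6), sigma=0.8, censor_frac=0.3):
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    ystar = X @ np.array(beta) + sigma * rng.normal(size=n)
    c = np.quantile(ystar, censor_frac)
    cens = ystar < c
    return np.where(cens, c, ystar), X, cens


class TestTobitFit:
    def test_reduces_to_ols_without_censoring(self):
        rng = np.random.default_rng(1)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ np.array([0.5, -1.2, 0.3]) + 0.6 * rng.normal(size=n)
        fit = tobit_fit(y, X, np.zeros(n, bool))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, rtol=1e-6)
        sigma_ml = np.sqrt(np.mean((y - X @ ols) ** 2))
        assert fit.sigma == pytest.approx(sigma_ml, rel=1e-6)

    def test_matches_r_survreg_on_left_censored_data(self, tmp_path):
        """Independent oracle: survival::survreg, Gaussian, left censoring."""
        rng = np.random.default_rng(42)
        y, X, cens = _censored_sample(rng, n=250)
        fit = tobit_fit(y, X, cens)
        df = pd.DataFrame({"y": y, "x": X[:, 1], "obs": (~cens).astype(int)})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            f"""
            suppressMessages(library(survival)); library(jsonlite)
            d <- read.csv("{csv}")
            f <- survreg(Surv(y, obs, type="left") ~ x, data=d, dist="gaussian")
            cat(toJSON(list(beta=as.numeric(coef(f)), sigma=f$scale,
                            se=as.numeric(sqrt(diag(vcov(f)))[1:2]))))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        oracle = json.loads(out.stdout)
        np.testing.assert_allclose(fit.beta, oracle["beta"], rtol=1e-4)
        assert fit.sigma == pytest.approx(oracle["sigma"][0], rel=1e-4)
        np.testing.assert_allclose(fit.se, oracle["se"], rtol=1e-3)

    def test_loglik_never_below_ols_start(self):
        """Optimizer must improve on the threshold-substituted OLS start."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            y, X, cens = _censored_sample(rng, n=150, censor_frac=0.5)
            fit = tobit_fit(y, X, cens)
            beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
            s0 = max(np.sqrt(np.mean((y - X @ beta0) ** 2)), 1e-3)
            theta0 = np.concatenate([beta0, [np.log(s0)]])
            nll0, _ = _nll_and_grad(theta0, X, y, cens)
            assert fit.loglik >= -nll0 - 1e-8

    def test_estimator_consistent_under_increasing_censoring(self):
        """Bias shrinks with n for censoring fractions up to 60%."""
        for frac in (0.0, 0.3, 0.6):
            errs = []
            for rep in range(20):
                rng = np.random.default_rng(100 * rep + int(frac * 10))
                y, X, cens = _censored_sample(
                    rng, n=2000, beta=(1.0, 0.4), censor_frac=frac
                )
                errs.append(tobit_fit(y, X, cens).beta[1] - 0.4)
            assert abs(np.mean(errs)) < 0.03

    def test_all_censored_not_identifiable(self):
        n = 20
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        with pytest.raises(AllCensoredError):
            tobit_fit(np.zeros(n), X, np.ones(n, bool))

    def test_duplicated_column_is_rank_error(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, x])
        with pytest.raises(ValueError, match="rank"):
            tobit_fit(rng.normal(size=50), X, np.zeros(50, bool))


class TestPercentChange:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 0.0), (np.log(2.0), 100.0), (np.log(0.022), -97.8)],
    )
    def test_point_values(self, beta, expected):
        assert percent_change(beta, 0.1)[0] == pytest.approx(expected, abs=0.05)

    def test_order_preserving_in_beta(self):
        betas = np.linspace(-2, 2, 25)
        points = [percent_change(b, 0.5)[0] for b in betas]
        assert np.all(np.diff(points) > 0)

    def test_ci_brackets_point(self):
        point, lo, hi = percent_change(0.3, 0.1)
        assert lo < point < hi


class TestDirectionalFdr:
    @staticmethod
    def _fit_with_z(z, analyte="a"):
        """Minimal TobitFit carrying one focal term with Wald z = ``z``."""
        return TobitFit(
            analyte=analyte, predictors=["intercept", "trauma"],
            beta=np.array([0.0, z * 0.1]), se=np.array([0.1, 0.1]),
            sigma=1.0, sigma_se=0.1, cov=np.eye(2) * 0.01,
            loglik=0.0, converged=True, n_obs=10, n_censored=0,
        )

    def test_all_null_p_one_no_discoveries(self):
        fits = [self._fit_with_z(0.0, f"a{i}") for i in range(10)]
        directional_fdr(fits, alpha=0.01)
        assert not any(f.significant[1] for f in fits)

    def test_single_test_q_equals_p(self):
        z = norm.isf(0.004)  # one-sided p_pos = 0.004
        fits = [self._fit_with_z(z)]
        directional_fdr(fits, alpha=0.01)
        assert fits[0].q_pos[1] == pytest.approx(0.004, rel=1e-9)
        assert fits[0].significant[1]
        assert fits[0].direction[1] == "positive"

    def test_matches_brute_force_bh_enumeration(self):
        """q-values against a from-scratch step-up implementation."""
        rng = np.random.default_rng(9)
        z = rng.normal(size=10) * 2
        fits = [self._fit_with_z(zi, f"a{i}") for i, zi in enumerate(z)]
        directional_fdr(fits, alpha=0.01)

        def brute_bh(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            q = np.empty(m)
            prev = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                prev = min(prev, pvals[i] * m / (rank_idx + 1))
                q[i] = prev
            return q

        q_pos_expected = brute_bh(norm.sf(z))
        q_neg_expected = brute_bh(norm.cdf(z))
        np.testing.assert_allclose(
            [f.q_pos[1] for f in fits], q_pos_expected, rtol=1e-12
        )
        np.testing.assert_allclose(
            [f.q_neg[1] for f in fits], q_neg_expected, rtol=1e-12
        )


class TestFitPanel:
    def test_trauma_up_analyte_detected_with_positive_direction(self, small_cohort):
        panel, subjects, truth = small_cohort
        processed = apply_lod_rules(panel, "analysis")
        fits = vp.fit_panel(processed, subjects, model="univariable_group")
        directional_fdr(fits, alpha=0.01)
        by_name = {f.analyte: f for f in fits}
        mif = by_name["MIF"]  # configured strong trauma-up analyte
        assert mif.significant[1]
        assert mif.direction[1] == "positive"
        # and its percent change is positive with a CI excluding 0
        pct = mif.percent_change().loc["trauma"]
        assert pct["lo"] > 0

    def test_age_model_mean_centers_and_recovers_slope(self):
        from viperpanel.synthetic import AnalyteSpec, CohortConfig

        config = CohortConfig(
            n_trauma=3000, n_control=500, mortality_rate=0.0,
            analytes=[AnalyteSpec(name="X", mu_control=2.0, sigma=0.5,
                                  age_slope=0.02, lower_lod=1e-6, upper_lod=1e9)],
            outcome_model="marginal", seed=3,
        )
        panel, subjects, _ = vp.generate(config)
        fits = vp.fit_panel(
            apply_lod_rules(panel, "analysis"), subjects, model="age_adjusted"
        )
        age_idx = fits[0].predictors.index("age")
        assert fits[0].beta[age_idx] == pytest.approx(0.02, abs=0.005)

    def test_categorical_trauma_level_uses_level4_reference(self, small_cohort):
        panel, subjects, _ = small_cohort
        fits = vp.fit_panel(
            apply_lod_rules(panel, "analysis"), subjects, model="trauma_level"
        )
        assert fits[0].predictors == [
            "intercept",
            "trauma_level[level_1]",
            "trauma_level[level_2]",
            "trauma_level[level_3]",
        ]

    def test_all_censored_analyte_skipped(self, small_cohort):
        panel, subjects, _ = small_cohort
        clone = PanelMatrix(
            list(panel.subject_ids), list(panel.analytes),
            panel.raw.copy(), panel.status.copy(),
        )
        clone.status[:, 0] = "below"
        fits = vp.fit_panel(apply_lod_rules(clone, "analysis"), subjects)
        assert len(fits) == panel.shape[1] - 1


class TestLodPrevalence:
    @staticmethod
    def _panel_from_status(status_col_trauma, status_col_control):
        analytes = [AnalyteDef("A", 1.0, 100.0)]
        n = len(status_col_trauma) + len(status_col_control)
        raw = np.full((n, 1), 10.0)
        status = np.array(status_col_trauma + status_col_control, dtype=object)[:, None]
        ids = [f"s{i}" for i in range(n)]
        panel = PanelMatrix(ids, analytes, raw, status)
        subjects = [
            vp.SubjectRecord(id=f"s{i}", group="trauma" if i < len(status_col_trauma) else "control", age=30)
            for i in range(n)
        ]
        return panel, subjects

    def test_identical_proportions_give_p_one(self):
        panel, subjects = self._panel_from_status(
            ["below"] * 5 + ["within"] * 5, ["below"] * 5 + ["within"] * 5
        )
        res = lod_prevalence_compare(panel, subjects)
        assert res[0].difference == 0.0
        assert res[0].p_value == pytest.approx(1.0)

    def test_p_value_matches_hypergeometric_enumeration(self):
        """Fisher p for (8 below / 2 detected) vs (1 below / 9 detected)
        against direct enumeration of the conditional null."""
        panel, subjects = self._panel_from_status(
            ["below"] * 8 + ["within"] * 2, ["below"] * 1 + ["within"] * 9
        )
        res = lod_prevalence_compare(panel, subjects)
        # condition on margins: row totals 10/10, below total 9
        observed = hypergeom.pmf(8, 20, 9, 10)
        p_expected = sum(
            hypergeom.pmf(k, 20, 9, 10)
            for k in range(10)
            if hypergeom.pmf(k, 20, 9, 10) <= observed * (1 + 1e-9)
        )
        assert res[0].p_value == pytest.approx(p_expected, rel=1e-9)

    def test_il2_like_censoring_gap_is_large_and_significant(self, small_cohort):
        panel, subjects, _ = small_cohort
        res = {r.analyte: r for r in lod_prevalence_compare(panel, subjects)}
        il2 = res["IL-2"]
        assert il2.difference > 30  # configured ~46-point gap
        assert il2.q_value < 0.01


class TestRightCensoring:
    def test_recovers_parameters_with_censoring_on_both_sides(self):
        rng = np.random.default_rng(17)
        n = 4000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        ystar = 1.0 + 0.7 * x + 0.8 * rng.normal(size=n)
        lo, hi = np.quantile(ystar, [0.2, 0.9])
        left = ystar < lo
        right = ystar > hi
        y = np.clip(ystar, lo, hi)
        fit = tobit_fit(y, X, left, censored_right=right)
        assert fit.beta[1] == pytest.approx(0.7, abs=0.05)
        assert fit.sigma == pytest.approx(0.8, abs=0.05)
        assert fit.n_censored == int(left.sum() + right.sum())

    def test_both_directions_on_one_row_rejected(self):
        n = 10
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        flags = np.zeros(n, bool)
        flags[0] = True
        with pytest.raises(ValueError, match="both directions"):
            tobit_fit(np.zeros(n), X, flags, censored_right=flags)


class TestStoreyOption:
    def test_storey_q_never_exceeds_bh_q(self):
        rng = np.random.default_rng(23)
        z = np.concatenate([rng.normal(size=20), rng.normal(5, 1, 10)])
        make = TestDirectionalFdr._fit_with_z
        bh = [make(zi, f"a{i}") for i, zi in enumerate(z)]
        st = [make(zi, f"a{i}") for i, zi in enumerate(z)]
        directional_fdr(bh, alpha=0.01)
        directional_fdr(st, alpha=0.01, pi0="storey")
        for f_bh, f_st in zip(bh, st):
            assert f_st.q_pos[1] <= f_bh.q_pos[1] + 1e-12
            assert f_st.q_neg[1] <= f_bh.q_neg[1] + 1e-12


class TestLevelGradedMonotonicity:
    def test_level_graded_effect_orders_coefficients(self):
        """A cohort whose analyte rises with injury severity yields
        monotone level coefficients against the level-4 reference."""
        rng = np.random.default_rng(31)
        per_level = 150
        levels = np.repeat([1, 2, 3, 4], per_level)
        mu = 2.0 + 0.4 * (4 - levels)  # most severe = highest concentration
        conc = np.exp(mu + 0.5 * rng.normal(size=levels.size))
        analytes = [AnalyteDef("A", lower_lod=1e-6, upper_lod=1e9)]
        raw = pd.DataFrame(
            {"A": conc}, index=[f"s{i}" for i in range(levels.size)]
        )
        panel = PanelMatrix.from_raw(raw, analytes)
        subjects = [
            vp.SubjectRecord(id=f"s{i}", group="trauma", age=40,
                             trauma_level=int(lv), outcome="discharged_home")
            for i, lv in enumerate(levels)
        ]
        fits = vp.fit_panel(
            apply_lod_rules(panel, "analysis"), subjects, model="trauma_level"
        )
        coef = dict(zip(fits[0].predictors, fits[0].beta))
        b1 = coef["trauma_level[level_1]"]
        b2 = coef["trauma_level[level_2]"]
        b3 = coef["trauma_level[level_3]"]
        assert b1 > b2 > b3 > 0
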