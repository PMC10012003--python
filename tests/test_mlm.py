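"""Multilevel layer: variance components, mixed models, contrasts, semipartials."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import stepcompare as sc
from stepcompare.errors import InvalidInputError, SingularDesignError


def _nested_data(seed, n_persons=30, n_days=6, icc_var=1.0, resid=1.0,
                 slope=0.0):
    """Random-intercept data with a within-person continuous predictor."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_persons):
        b = rng.normal(0, math.sqrt(icc_var))
        for d in range(n_days):
            x = rng.normal()
            y = 1.0 + b + slope * x + rng.normal(0, math.sqrt(resid))
            rows.append({"participant_id": f"p{i}", "x": x, "y": y})
    return pd.DataFrame(rows)


class TestVarianceComponents:
    def test_hand_anova_oracle(self):
        # persons {(0,2),(2,4),(4,6)}: MSW=2, MSB=8, n0=2 -> sigma2_b=3, ICC=0.6
        vc = sc.variance_components([0, 2, 2, 4, 4, 6], ["a", "a", "b", "b", "c", "c"])
        assert vc.sigma2_within == pytest.approx(2.0)
        assert vc.sigma2_between == pytest.approx(3.0)
        assert vc.icc == pytest.approx(0.6, abs=1e-12)

    def test_no_within_variance_gives_icc_one(self):
        vc = sc.variance_components([1, 1, 3, 3, 5, 5], ["a", "a", "b", "b", "c", "c"])
        assert vc.sigma2_within == 0 and vc.icc == 1.0

    def test_equal_person_means_truncate_to_zero(self):
        vc = sc.variance_components([1, 3, 1, 3, 1, 3], ["a", "a", "b", "b", "c", "c"])
        assert vc.sigma2_between == 0.0 and vc.icc == 0.0

    def test_unbalanced_matches_closed_form(self):
        # unbalanced groups: check against a direct recomputation of the
        # estimator's defining quantities
        y = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 5.0])
        ids = np.array(["a", "a", "a", "b", "b", "c"])
        vc = sc.variance_components(y, ids)
        msw = (sum((y[:3] - 2) ** 2) + sum((y[3:5] - 10.5) ** 2)) / 3
        assert vc.sigma2_within == pytest.approx(msw)

    def test_reml_agrees_on_balanced_data(self):
        data = _nested_data(31, n_persons=60, n_days=8)
        anova = sc.variance_components(data["y"], data["participant_id"])
        reml = sc.variance_components(data["y"], data["participant_id"], method="reml")
        assert abs(anova.icc - reml.icc) < 0.02

    def test_all_singletons_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.variance_components([1, 2, 3], ["a", "b", "c"])


class TestFitDayLevelModel:
    def test_zero_icc_limit_matches_ols(self):
        # balanced two-level factor with no person variance: GLS = OLS exactly
        rng = np.random.default_rng(8)
        rows = []
        for i in range(20):
            for lvl in ("lo", "hi") * 3:
                rows.append(
                    {"participant_id": f"p{i}", "g": lvl,
                     "y": rng.normal(1.0 + 0.5 * (lvl == "hi"), 1.0)}
                )
        data = pd.DataFrame(rows)
        res = sc.fit_day_level_model(data, "y", ["g"])
        X = np.column_stack([np.ones(len(data)), (data["g"] == "lo").astype(float)])
        beta = np.linalg.lstsq(X, data["y"].values, rcond=None)[0]
        assert res.params.loc["Intercept", "B"] == pytest.approx(beta[0], abs=1e-6)
        assert res.params.loc["g[lo]", "B"] == pytest.approx(beta[1], abs=1e-6)

    def test_slope_recovery_with_ci_coverage(self):
        covered = 0
        for rep in range(40):
            data = _nested_data(1000 + rep, n_persons=40, n_days=6, slope=0.5)
            res = sc.fit_day_level_model(data, "y", ["x"])
            b, se = res.params.loc["x", "B"], res.params.loc["x", "SE"]
            if abs(b - 0.5) < 1.96 * se:
                covered += 1
        assert covered >= 34  # ~95% nominal; binomial slack

    def test_rank_deficiency_names_collinear_terms(self):
        data = _nested_data(2)
        data["x2"] = 2 * data["x"]
        with pytest.raises(SingularDesignError, match="x2"):
            sc.fit_day_level_model(data, "y", ["x", "x2"])

    def test_invariant_to_row_order_and_relabeling(self):
        data = _nested_data(3)
        res1 = sc.fit_day_level_model(data, "y", ["x"])
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["participant_id"] = shuffled["participant_id"].map(
            lambda s: "zz_" + s
        )
        res2 = sc.fit_day_level_model(shuffled, "y", ["x"])
        assert res1.params.loc["x", "B"] == pytest.approx(
            res2.params.loc["x", "B"], rel=1e-8
        )

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_against_lme4_reference(self, tmp_path):
        # independent mixed-model implementation as the oracle
        data = _nested_data(44, n_persons=25, n_days=5, slope=0.3)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(y ~ x + (1|participant_id), data=d, REML=TRUE);"
            "cat(fixef(m), sqrt(diag(vcov(m))))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        ref_int, ref_x, ref_se_int, ref_se_x = map(float, out)
        res = sc.fit_day_level_model(data, "y", ["x"])
        assert res.params.loc["Intercept", "B"] == pytest.approx(ref_int, rel=1e-3)
        assert res.params.loc["x", "B"] == pytest.approx(ref_x, rel=1e-3)
        assert res.params.loc["x", "SE"] == pytest.approx(ref_se_x, rel=1e-2)


class TestWithinBetween:
    def test_within_and_between_slopes_recovered(self):
        rng = np.random.default_rng(50)
        rows = []
        for i in range(80):
            person_mean = rng.normal(0, 1)
            b = 0.0 * person_mean  # between slope truly zero
            intercept = rng.normal(0, 0.8)
            for d in range(8):
                x = person_mean + rng.normal()
                y = intercept + b + 0.1 * (x - person_mean) + rng.normal(0, 0.3)
                rows.append({"participant_id": f"p{i}", "x": x, "y": y})
        data = pd.DataFrame(rows)
        res = sc.within_between_association(data, "y", "x")
        bw = res.params.loc["x_within", "B"]
        sw = res.params.loc["x_within", "SE"]
        assert abs(bw - 0.1) < 3 * sw  # single-seed check; coverage tested elsewhere
        bb = res.params.loc["x_between", "B"]
        sb = res.params.loc["x_between", "SE"]
        assert abs(bb) < 2.6 * sb

    def test_negative_within_slope_keeps_sign(self):
        rng = np.random.default_rng(51)
        rows = []
        for i in range(60):
            intercept = rng.normal(0, 1)
            for d in range(8):
                x = rng.normal()
                rows.append(
                    {"participant_id": f"p{i}", "x": x,
                     "y": intercept - 0.4 * x + rng.normal(0, 0.5)}
                )
        res = sc.within_between_association(pd.DataFrame(rows), "y", "x")
        assert res.params.loc["x_within", "B"] < 0

    def test_person_constant_predictor_drops_within_term(self):
        data = _nested_data(5)
        data["x"] = data["participant_id"].map(lambda s: float(hash(s) % 7))
        with pytest.warns(UserWarning, match="constant within"):
            res = sc.within_between_association(data, "y", "x")
        assert "x_within" not in res.params.index
        assert res.dropped_terms == ["x_within"]


class TestContrast:
    def _balanced_zero_icc(self, seed=60):
        rng = np.random.default_rng(seed)
        rows = []
        means = {"a": 1.0, "b": 2.0, "c": 4.0}
        for i in range(15):
            for lvl, mu in means.items():
                for _ in range(2):
                    rows.append(
                        {"participant_id": f"p{i}", "g": lvl,
                         "y": rng.normal(mu, 0.5)}
                    )
        return pd.DataFrame(rows)

    def test_two_level_contrast_equals_mean_difference(self):
        data = self._balanced_zero_icc()
        res = sc.fit_day_level_model(data, "y", ["g"])
        est, se, t, df, p = sc.contrast(res, "g", {"a": 1.0, "b": -1.0})
        diff = data.loc[data.g == "a", "y"].mean() - data.loc[data.g == "b", "y"].mean()
        assert est == pytest.approx(diff, abs=1e-6)
        assert se > 0 and df == res.df_resid

    def test_zero_weights_rejected(self):
        res = sc.fit_day_level_model(self._balanced_zero_icc(), "y", ["g"])
        with pytest.raises(InvalidInputError):
            sc.contrast(res, "g", {"a": 0.0, "b": 0.0})
        with pytest.raises(InvalidInputError):
            sc.contrast(res, "g", {"a": 1.0, "b": 1.0})  # nonzero sum

    def test_weight_permutation_invariance(self):
        res = sc.fit_day_level_model(self._balanced_zero_icc(), "y", ["g"])
        e1 = sc.contrast(res, "g", {"a": 1.0, "b": -0.5, "c": -0.5})[0]
        e2 = sc.contrast(res, "g", {"c": -0.5, "a": 1.0, "b": -0.5})[0]
        assert e1 == pytest.approx(e2)


class TestSemipartial:
    def test_orthogonal_focal_equals_simple_correlation(self):
        rng = np.random.default_rng(70)
        n = 500
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        Z = np.column_stack([np.ones(n), z])
        x -= Z @ np.linalg.lstsq(Z, x, rcond=None)[0]  # orthogonal to 1 and z
        y = 0.5 * x + rng.normal(size=n)
        data = pd.DataFrame({"y": y, "x": x, "z": z})
        sr = sc.semipartial_r(data, "y", "x", ["z"])
        simple = np.corrcoef(y, x)[0, 1]
        assert sr == pytest.approx(simple, abs=1e-10)

    def test_duplicated_focal_rejected(self):
        data = pd.DataFrame({"y": [1, 2, 3, 4], "x": [1, 2, 3, 4.0]})
        data["x2"] = data["x"]
        with pytest.raises(InvalidInputError):
            sc.semipartial_r(data, "y", "x", ["x2"])

    def test_six_row_hand_oracle(self):
        # classic identity for one covariate: sr = (r_yx - r_yz r_xz)/sqrt(1-r_xz^2)
        data = pd.DataFrame(
            {
                "y": [3.0, 5.0, 4.0, 7.0, 6.0, 9.0],
                "x": [1.0, 2.0, 2.0, 4.0, 3.0, 5.0],
                "z": [2.0, 1.0, 3.0, 2.0, 4.0, 3.0],
            }
        )
        r = data.corr()
        expected = (r.loc["y", "x"] - r.loc["y", "z"] * r.loc["x", "z"]) / math.sqrt(
            1 - r.loc["x", "z"] ** 2
        )
        assert sc.semipartial_r(data, "y", "x", ["z"]) == pytest.approx(expected)
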