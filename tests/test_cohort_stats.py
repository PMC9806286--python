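"""Rater averaging, descriptives, classification, and the from-scratch OLS."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spleenvol.cohort_stats import (
    average_raters,
    classify_volume,
    describe,
    ols_fit,
    run_study,
)
from spleenvol.records import PREDICTORS, SubjectRecord


def _pair(subject="S1", v1=180.0, v2=190.0, **kw):
    return [
        SubjectRecord(subject, sex="male", rater_id="r1", spleen_volume=v1, **kw),
        SubjectRecord(subject, sex="male", rater_id="r2", spleen_volume=v2, **kw),
    ]


class TestAverageRaters:
    def test_mean_of_two_raters(self):
        (out,) = average_raters(_pair())
        assert out.spleen_volume == pytest.approx(185.0)
        assert out.rater_id == "mean"

    def test_identical_records_unchanged(self):
        (out,) = average_raters(_pair(v1=200.0, v2=200.0, spleen_length=9.0))
        assert out.spleen_volume == pytest.approx(200.0)
        assert out.spleen_length == pytest.approx(9.0)

    def test_value_missing_for_one_rater_uses_other_and_flags(self):
        recs = _pair()
        recs[0].l1_area = 7.5
        recs[1].l1_area = None
        (out,) = average_raters(recs)
        assert out.l1_area == pytest.approx(7.5)
        assert "l1_area:single_value" in out.notes

    def test_single_rater_passes_through_flagged(self):
        (out,) = average_raters([SubjectRecord("S1", sex="male", spleen_volume=100.0)])
        assert out.spleen_volume == pytest.approx(100.0)
        assert "single_rater" in out.notes

    def test_more_than_two_raters_rejected(self):
        recs = _pair() + [SubjectRecord("S1", sex="male", rater_id="r3")]
        with pytest.raises(ValueError, match="two raters"):
            average_raters(recs)


class TestClassifyVolume:
    def test_at_threshold_is_normal_strictly_above_is_high(self):
        assert classify_volume(300.0, 300.0) == "normal"
        assert classify_volume(300.0 + 1e-9, 300.0) == "high"

    def test_missing_volume_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_volume(None, 300.0)
        with pytest.raises(ValueError, match="threshold"):
            classify_volume(100.0, 0.0)

    def test_percentile_threshold_splits_ninety_ten(self, rng):
        vols = rng.normal(187, 100, size=345).clip(min=1)
        thr = float(np.quantile(vols, 0.9))
        high = sum(classify_volume(v, thr) == "high" for v in vols)
        assert high / len(vols) == pytest.approx(0.10, abs=0.01)


class TestDescribe:
    def test_mean_sd_sem(self):
        df = pd.DataFrame({"spleen_volume": [1.0, 2.0, 3.0]})
        row = describe(df, variables=["spleen_volume"]).loc["spleen_volume"]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["sem"] == pytest.approx(0.5774, abs=1e-4)

    def test_single_value_mean_only(self):
        df = pd.DataFrame({"spleen_volume": [5.0]})
        row = describe(df, variables=["spleen_volume"]).loc["spleen_volume"]
        assert row["mean"] == 5.0 and math.isnan(row["sd"]) and math.isnan(row["sem"])

    def test_permutation_invariance_and_sem_identity(self, rng):
        x = rng.normal(10, 3, 50)
        df1 = pd.DataFrame({"age": x})
        df2 = pd.DataFrame({"age": x[::-1]})
        r1 = describe(df1, variables=["age"]).loc["age"]
        r2 = describe(df2, variables=["age"]).loc["age"]
        assert r1["mean"] == pytest.approx(r2["mean"])
        assert r1["sd"] == pytest.approx(r2["sd"])
        assert r1["sem"] * math.sqrt(r1["n"]) == pytest.approx(r1["sd"])

    def test_group_by_sex(self):
        df = pd.DataFrame(
            {"sex": ["male"] * 3 + ["female"] * 2, "spleen_volume": [1, 2, 3, 10, 20.0]}
        )
        out = describe(df, variables=["spleen_volume"], group_by="sex")
        assert out.loc[("male", "spleen_volume"), "mean"] == pytest.approx(2.0)
        assert out.loc[("female", "spleen_volume"), "mean"] == pytest.approx(15.0)


def _synth_frame(rng, n=200, missing=0):
    cols = {p: rng.normal(10, 2, n) for p in PREDICTORS}
    y = 5.0
    for j, p in enumerate(PREDICTORS):
        y = y + (j - 4) * cols[p]
    cols["spleen_volume"] = y + rng.normal(0, 5, n)
    df = pd.DataFrame(cols)
    df["subject_id"] = [f"S{i:03d}" for i in range(n)]
    df["sex"] = np.where(rng.random(n) < 0.3, "male", "female")
    for _ in range(missing):
        df.loc[rng.integers(n), PREDICTORS[int(rng.integers(len(PREDICTORS)))]] = np.nan
    return df


def _normal_equations_oracle(X, y):
    """Brute-force (XᵀX)⁻¹Xᵀy with textbook SE/t/p/R²/F formulas."""
    xtx_inv = np.linalg.inv(X.T @ X)
    b = xtx_inv @ X.T @ y
    resid = y - X @ b
    dfr = len(y) - X.shape[1]
    sigma2 = resid @ resid / dfr
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = b / se
    p = 2 * sps.t.sf(np.abs(t), dfr)
    r2 = 1 - (resid @ resid) / ((y - y.mean()) ** 2).sum()
    k = X.shape[1] - 1
    f = (r2 / k) / ((1 - r2) / dfr)
    return b, se, t, p, r2, f


class TestOlsFit:
    def test_exact_line_single_predictor(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["spleen_volume"] = 2 * df["x"] + 1
        res = ols_fit(df, predictors=["x"])
        assert res.table.loc["x", "B"] == pytest.approx(2.0)
        assert res.table.loc["(Constant)", "B"] == pytest.approx(1.0)
        assert res.table.loc["x", "beta"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_standardized_beta_equals_pearson_r(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=80)})
        df["spleen_volume"] = 3 * df["x"] + rng.normal(size=80)
        res = ols_fit(df, predictors=["x"])
        r = sps.pearsonr(df["x"], df["spleen_volume"]).statistic
        assert abs(res.table.loc["x", "beta"] - r) < 1e-10

    @pytest.mark.parametrize("missing", [0, 15])
    def test_matches_normal_equations_oracle(self, rng, missing):
        df = _synth_frame(rng, missing=missing)
        res = ols_fit(df)
        sub = df[["spleen_volume"] + list(PREDICTORS)].dropna()
        X = np.column_stack([np.ones(len(sub)), sub[list(PREDICTORS)].to_numpy()])
        y = sub["spleen_volume"].to_numpy()
        b, se, t, p, r2, f = _normal_equations_oracle(X, y)
        assert np.allclose(res.table["B"], b, rtol=1e-8)
        assert np.allclose(res.table["SE"], se, rtol=1e-8)
        assert np.allclose(res.table["t"], t, rtol=1e-8)
        assert np.allclose(res.table["p"], p, rtol=1e-8, atol=1e-12)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)
        assert res.anova_f == pytest.approx(f, rel=1e-10)
        assert res.n_used == len(sub)
        assert res.n_dropped == len(df) - len(sub)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        df = _synth_frame(rng)
        res = ols_fit(df)
        X = sm.add_constant(df[list(PREDICTORS)])
        fit = sm.OLS(df["spleen_volume"], X).fit()
        assert np.allclose(res.table["B"].to_numpy(), fit.params.to_numpy(), rtol=1e-8)
        assert np.allclose(res.table["SE"].to_numpy(), fit.bse.to_numpy(), rtol=1e-8)
        assert res.r_squared == pytest.approx(fit.rsquared, rel=1e-10)
        assert res.anova_f == pytest.approx(fit.fvalue, rel=1e-8)

    def test_collinear_columns_named(self, rng):
        df = _synth_frame(rng)
        df["l1_tv"] = 2 * df["l1_ap"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(df)

    def test_constant_predictor_named(self, rng):
        df = _synth_frame(rng)
        df["canal_area"] = 3.0
        with pytest.raises(ValueError, match="canal_area"):
            ols_fit(df)

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            ols_fit(_synth_frame(rng, n=8))


class TestRunStudy:
    def _measurement_frame(self, rng, n=40):
        df = _synth_frame(rng, n=n)
        df["spleen_length"] = df["spleen_length"].abs()
        rows = []
        for _, row in df.iterrows():
            for rater in ("r1", "r2"):
                r = row.to_dict()
                r["rater_id"] = rater
                rows.append(r)
        out = pd.DataFrame(rows)
        num = out.select_dtypes("number").columns
        out[num] = out[num].abs()
        return out

    def test_tables_produced_and_classes_partition(self, rng):
        df = self._measurement_frame(rng)
        report = run_study(df, volume_threshold=float(df["spleen_volume"].median()))
        counts = report.classification["frequency"]
        assert counts.sum() == report.n_subjects == 40
        assert set(report.volume_length_by_sex.index.get_level_values(0)) <= {
            "male", "female",
        }
        assert report.regression.n_used <= 40
        text = report.to_text()
        assert "R Square" in text and "ANOVA" in text

    def test_rater_averaging_matches_describe_of_subject_means(self, rng):
        df = self._measurement_frame(rng)
        report = run_study(df, volume_threshold=200.0)
        manual = df.groupby("subject_id")["spleen_volume"].mean()
        row = report.descriptives.loc["Spleen volume (cm3)"]
        assert row["mean"] == pytest.approx(manual.mean())
        assert row["sd"] == pytest.approx(manual.std(ddof=1))

    def test_constant_predictor_reported_cleanly(self, rng):
        df = self._measurement_frame(rng)
        df["age"] = 50.0
        with pytest.raises(ValueError, match="constant predictor"):
            run_study(df, volume_threshold=200.0)

    def test_write_outputs_smoke_cohort(self, rng, tmp_path):
        # smallest cohort with positive residual df for the 9-predictor fit
        df = self._measurement_frame(rng, n=12)
        report = run_study(df, volume_threshold=200.0)
        paths = report.write(tmp_path)
        for key in ("table3", "table4", "table5", "table6", "report"):
            assert paths[key].exists() and paths[key].stat().st_size > 0
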