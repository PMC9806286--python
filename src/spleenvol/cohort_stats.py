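"""Cohort statistics: dual-rater averaging, descriptives, volume
classification, and the multiple linear regression of spleen volume on nine
predictors — ordinary least squares implemented from first principles
(numerically stable QR), with unstandardized B, SE, standardized beta, t,
two-sided p, R², and the overall ANOVA F.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

from .records import CSV_COLUMNS, PREDICTORS, VARIABLE_LABELS, SubjectRecord

DESCRIBE_VARIABLES = ("age", "spleen_length", "spleen_volume") + tuple(
    v for v in PREDICTORS if v not in ("age", "spleen_length")
)

_MEAN_FIELDS = (
    "age",
    "spleen_volume",
    "spleen_ce",
    "n_slices",
    "spleen_length",
    "l1_ap",
    "l1_tv",
    "l1_area",
    "abd_ap",
    "abd_tv",
    "abd_circumference",
    "canal_area",
)


def average_raters(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Collapse one or two rater records per subject to their field-wise mean.

    Every measurement was taken independently by two raters and only the
    average is analyzed.  A field missing for one rater falls back to the
    other rater's value (flagged in notes); single-rater subjects pass
    through with a flag.  More than two raters per subject is an error.
    """
    by_subject: dict[str, list[SubjectRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    out = []
    for subject_id in sorted(by_subject):
        group = by_subject[subject_id]
        raters = {r.rater_id for r in group}
        if len(raters) != len(group) or len(group) > 2:
            raise ValueError(
                f"subject {subject_id}: expected one or two raters, got "
                f"{sorted(r.rater_id for r in group)}"
            )
        if len({r.sex for r in group}) > 1:
            raise ValueError(f"subject {subject_id}: raters disagree on sex")
        notes = []
        if len(group) == 1:
            notes.append("single_rater")
        merged = {"subject_id": subject_id, "sex": group[0].sex, "rater_id": "mean"}
        for name in _MEAN_FIELDS:
            values = [getattr(r, name) for r in group if getattr(r, name) is not None]
            if len(group) == 2 and len(values) == 1:
                notes.append(f"{name}:single_value")
            merged[name] = float(np.mean(values)) if values else None
        merged["notes"] = ";".join(notes)
        out.append(SubjectRecord(**merged))
    return out


def classify_volume(volume: Optional[float], threshold: float) -> str:
    """'high' iff volume strictly exceeds the explicit threshold (cm³).

    No reference cut-off for splenomegaly is assumed; the threshold is always
    a caller decision.  A volume exactly at the threshold is 'normal'.
    """
    if threshold is None or threshold <= 0:
        raise ValueError("classification threshold must be a positive volume (cm³)")
    if volume is None or (isinstance(volume, float) and math.isnan(volume)):
        raise ValueError("cannot classify a missing volume")
    return "high" if volume > threshold else "normal"


def describe(
    df: pd.DataFrame,
    variables: Sequence[str] = DESCRIBE_VARIABLES,
    group_by: Optional[str] = None,
) -> pd.DataFrame:
    """Mean, sample SD (n−1), and SEM = SD/√n per variable.

    With ``group_by`` (e.g. "sex") the table is stratified; a stratum with a
    single observation reports its mean with SD/SEM missing.
    """
    def one(frame: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for var in variables:
            x = pd.to_numeric(frame[var], errors="coerce").dropna()
            n = len(x)
            mean = x.mean() if n else np.nan
            sd = x.std(ddof=1) if n >= 2 else np.nan
            rows.append(
                {"variable": var, "n": n, "mean": mean, "sd": sd,
                 "sem": sd / math.sqrt(n) if n >= 2 else np.nan}
            )
        return pd.DataFrame(rows).set_index("variable")

    if group_by is None:
        return one(df)
    parts = {key: one(sub) for key, sub in df.groupby(group_by, sort=True)}
    return pd.concat(parts, names=[group_by])


@dataclass
class RegressionResult:
    """OLS fit summary in the layout of a standard regression table."""

    table: pd.DataFrame  # index: (Constant) + predictors; cols B, SE, beta, t, p
    r_squared: float
    anova_f: float
    anova_p: float
    n_used: int
    n_dropped: int
    df_resid: int
    response: str = "spleen_volume"

    def to_text(self) -> str:
        lines = [
            f"Linear regression: {self.response} ~ "
            + " + ".join(i for i in self.table.index if i != "(Constant)"),
            f"n = {self.n_used} complete cases ({self.n_dropped} dropped), "
            f"residual df = {self.df_resid}",
            f"R Square = {self.r_squared:.3f}, "
            f"ANOVA F = {self.anova_f:.2f} (p = {self.anova_p:.3g})",
            "",
            self.table.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


def ols_fit(
    df: pd.DataFrame,
    response: str = "spleen_volume",
    predictors: Sequence[str] = PREDICTORS,
) -> RegressionResult:
    """Multiple linear regression of ``response`` on ``predictors``.

    Complete cases only (listwise deletion; the retained n is reported).
    Solved by QR decomposition; SEs use the unbiased residual variance;
    standardized beta_j = B_j · s_xj / s_y with sample SDs; p-values are
    two-sided from t with n − k − 1 df; F = (R²/k)/((1−R²)/(n−k−1)).
    """
    predictors = list(predictors)
    cols = [response] + predictors
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = df[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n, k = len(sub), len(predictors)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} complete cases, have {n}")
    y = sub[response].to_numpy(dtype=float)
    Xp = sub[predictors].to_numpy(dtype=float)
    sx = Xp.std(axis=0, ddof=1)
    constant = [predictors[j] for j in range(k) if sx[j] == 0]
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    X = np.column_stack([np.ones(n), Xp])

    # rank check with column attribution via pivoted QR
    _, R_piv, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R_piv))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < k + 1:
        names = ["(Constant)"] + predictors
        bad = sorted(names[piv[j]] for j in range(rank, k + 1))
        raise ValueError(f"rank-deficient design; collinear columns involve {bad}")

    Q, R = np.linalg.qr(X)
    coef = sla.solve_triangular(R, Q.T @ y)
    resid = y - X @ coef
    df_resid = n - k - 1
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    Rinv = sla.solve_triangular(R, np.eye(k + 1))
    xtx_inv = Rinv @ Rinv.T
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(
            se > 0, coef / np.where(se > 0, se, 1.0),
            np.where(coef == 0, np.nan, np.inf * np.sign(coef)),
        )
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)

    sy = y.std(ddof=1)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot
    if r2 >= 1.0:  # exact fit: F degenerates
        f_stat, f_p = math.inf, 0.0
    else:
        f_stat = (r2 / k) / ((1.0 - r2) / df_resid)
        f_p = float(sps.f.sf(f_stat, k, df_resid))

    beta = np.full(k + 1, np.nan)
    beta[1:] = coef[1:] * sx / sy
    table = pd.DataFrame(
        {"B": coef, "SE": se, "beta": beta, "t": tvals, "p": pvals},
        index=["(Constant)"] + predictors,
    )
    return RegressionResult(
        table=table,
        r_squared=float(r2),
        anova_f=float(f_stat),
        anova_p=f_p,
        n_used=n,
        n_dropped=len(df) - n,
        df_resid=df_resid,
        response=response,
    )


# ---------------------------------------------------------------------------
# study report


@dataclass
class StudyReport:
    """The four result tables of a volumetry study run."""

    classification: pd.DataFrame  # normal/high counts and percentages
    volume_length_by_sex: pd.DataFrame
    descriptives: pd.DataFrame
    regression: RegressionResult
    volume_threshold: float
    n_subjects: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        reg = self.regression.table.copy()
        for name, frame in [
            ("table3", self.classification),
            ("table4", self.volume_length_by_sex),
            ("table5", self.descriptives),
            ("table6", reg),
        ]:
            p = out_dir / f"{name}.csv"
            frame.to_csv(p)
            paths[name] = p
        report = out_dir / "report.txt"
        report.write_text(self.to_text())
        paths["report"] = report
        return paths

    def to_text(self) -> str:
        parts = [
            f"Spleen volumetry study report (n = {self.n_subjects} subjects)",
            "",
            f"Volume classification (threshold = {self.volume_threshold:.1f} cm3):",
            self.classification.to_string(),
            "",
            "Spleen volume and length by sex (mean / SD / SEM):",
            self.volume_length_by_sex.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Descriptive statistics, all subjects:",
            self.descriptives.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            self.regression.to_text(),
            "",
        ]
        return "\n".join(parts)


def run_study(
    df: pd.DataFrame,
    volume_threshold: float,
    response: str = "spleen_volume",
    predictors: Sequence[str] = PREDICTORS,
) -> StudyReport:
    """Full cohort analysis on a measurement table (one row per subject-rater).

    Rater rows are averaged per subject first; then volumes are classified
    against the explicit threshold, sex-stratified and overall descriptives
    are tabulated, and the nine-predictor volume regression is fitted.
    """
    required = {"subject_id", "sex", response}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns: {sorted(missing)}")
    records = [SubjectRecord.from_dict(row.to_dict()) for _, row in df.iterrows()]
    subjects = average_raters(records)
    per_subject = pd.DataFrame([r.to_dict() for r in subjects], columns=CSV_COLUMNS)

    classes = per_subject[response].map(
        lambda v: classify_volume(v, volume_threshold) if pd.notna(v) else "missing"
    )
    counts = classes.value_counts()
    classification = pd.DataFrame(
        {
            "frequency": [int(counts.get(c, 0)) for c in ("normal", "high", "missing")],
        },
        index=pd.Index(["normal", "high", "missing"], name="spleen_volume_class"),
    )
    classification["percentage"] = 100.0 * classification["frequency"] / len(per_subject)

    by_sex = describe(per_subject, variables=("spleen_volume", "spleen_length"),
                      group_by="sex")
    overall = describe(per_subject, variables=DESCRIBE_VARIABLES)
    overall.index = [VARIABLE_LABELS.get(v, v) for v in overall.index]
    regression = ols_fit(per_subject, response=response, predictors=predictors)
    return StudyReport(
        classification=classification,
        volume_length_by_sex=by_sex,
        descriptives=overall,
        regression=regression,
        volume_threshold=float(volume_threshold),
        n_subjects=len(per_subject),
    )
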