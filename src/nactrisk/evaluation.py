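"""Diagnostic validation of a classifier on a labeled cohort.

The positive class is the chemotherapy non-responder throughout.
Metrics follow the standard diagnostic-test layout: confusion-table
percentages with binomial standard errors on each metric's own
denominator, AUC with a DeLong 95% confidence interval and a z-test
against 0.5, cross-product odds ratios with Wald intervals
(Haldane-Anscombe corrected for zero cells), and univariate /
multivariate logistic association reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

NON_RESPONDER = "non_responder"
RESPONDER = "responder"


def _labels01(labels) -> np.ndarray:
    values = labels.to_numpy() if isinstance(labels, pd.Series) else np.asarray(labels)
    if values.dtype.kind in "USO":
        return (values == NON_RESPONDER).astype(int)
    return values.astype(int)


@dataclass
class ConfusionTable:
    """2x2 counts with non-responder as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_calls(cls, calls, truth) -> "ConfusionTable":
        c = _labels01(calls)
        y = _labels01(truth)
        return cls(tp=int(((c == 1) & (y == 1)).sum()),
                   fn=int(((c == 0) & (y == 1)).sum()),
                   fp=int(((c == 1) & (y == 0)).sum()),
                   tn=int(((c == 0) & (y == 0)).sum()))

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class Metric:
    """One percentage metric with its binomial standard error."""

    pct: float
    se: float
    numerator: int
    denominator: int


@dataclass
class MetricsReport:
    accuracy: Metric | None
    sensitivity: Metric | None
    specificity: Metric | None
    ppv: Metric | None
    npv: Metric | None
    n: int

    def to_dict(self) -> dict:
        out = {name: (None if m is None else asdict(m))
               for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
               for m in [getattr(self, name)]}
        out["n"] = self.n
        return out


def _metric(num: int, den: int) -> Metric | None:
    if den == 0:
        return None
    p = num / den
    return Metric(pct=100 * p, se=100 * np.sqrt(p * (1 - p) / den),
                  numerator=num, denominator=den)


def confusion_metrics(table: ConfusionTable) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV as % with binomial SE.

    Each SE is 100 * sqrt(p(1-p)/m) on the metric's own denominator; a
    zero denominator yields an undefined (None) metric, never 0.
    """
    t = table
    return MetricsReport(
        accuracy=_metric(t.tp + t.tn, t.n),
        sensitivity=_metric(t.tp, t.tp + t.fn),
        specificity=_metric(t.tn, t.tn + t.fp),
        ppv=_metric(t.tp, t.tp + t.fp),
        npv=_metric(t.tn, t.tn + t.fn),
        n=t.n,
    )


@dataclass
class DelongResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_vs_half: float


def delong_auc(scores, labels, level: float = 0.95) -> DelongResult:
    """AUC with DeLong placement-value variance, CI and z-test vs 0.5.

    AUC is the Mann-Whitney probability with half credit for ties; the
    variance is S10/m + S01/n from per-observation placement values.
    """
    scores = np.asarray(scores, dtype=float)
    y = _labels01(labels)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # placement values via midranks
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    auc = psi.mean()
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return DelongResult(float(auc), se, float(lo), float(hi), p)


@dataclass
class OddsRatioResult:
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool = False
    stabilized: bool = False


def odds_ratio_wald(table: ConfusionTable, level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio with a Wald interval on the log scale.

    0.5 is added to every cell when any cell is zero.
    """
    a, b, c, d = table.tp, table.fn, table.fp, table.tn
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    p = float(2 * stats.norm.sf(abs(np.log(orr)) / se))
    return OddsRatioResult("classifier", float(orr),
                           float(np.exp(np.log(orr) - z * se)),
                           float(np.exp(np.log(orr) + z * se)), p)


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """IRLS logistic fit with an L2 penalty (intercept unpenalized).

    Fallback under separation; returns coefficients and Wald standard
    errors from the penalized information matrix.
    """
    n, p = X.shape
    exog = np.column_stack([np.ones(n), X])
    pen = np.diag([0.0] + [alpha] * p)
    beta = np.zeros(p + 1)
    for _ in range(100):
        eta = exog @ beta
        mu = 1 / (1 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = exog.T @ (y - mu) - pen @ beta
        hess = (exog * w[:, None]).T @ exog + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def logistic_association(predictors: pd.DataFrame, labels, adjusted: bool = True,
                         level: float = 0.95) -> list[OddsRatioResult]:
    """Per-predictor odds ratios from logistic regression on non-response.

    ``adjusted=True`` fits all predictors jointly; otherwise each
    predictor is fit alone.  Rows with missing values are excluded.
    Under separation the fit falls back to a ridge-stabilized IRLS and
    the result is flagged.
    """
    import statsmodels.api as sm

    y_all = _labels01(labels)
    X_all = predictors.apply(pd.to_numeric, errors="coerce")
    groups = [list(X_all.columns)] if adjusted else [[c] for c in X_all.columns]
    z = stats.norm.ppf(0.5 + level / 2)
    results: list[OddsRatioResult] = []
    for cols in groups:
        sub = X_all[cols]
        ok = sub.notna().all(axis=1).to_numpy()
        X = sub.to_numpy(dtype=float)[ok]
        y = y_all[ok]
        stabilized = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                    disp=0, maxiter=200)
            params, bse = np.asarray(res.params), np.asarray(res.bse)
            if (not res.mle_retvals.get("converged", True)
                    or not np.all(np.isfinite(bse)) or np.abs(params).max() > 1e2):
                raise RuntimeError("separation")
        except Exception:
            params, bse = _ridge_logit(X, y)
            stabilized = True
        for k, name in enumerate(cols, start=1):
            b, s = params[k], bse[k]
            results.append(OddsRatioResult(
                predictor=name, odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * s)), ci_high=float(np.exp(b + z * s)),
                p_value=float(2 * stats.norm.sf(abs(b) / s)) if s > 0 else 0.0,
                adjusted=adjusted, stabilized=stabilized))
    return results


@dataclass
class EvaluationReport:
    """Full diagnostic report for one classifier on one cohort."""

    table: ConfusionTable
    metrics: MetricsReport
    auc: DelongResult
    odds_ratio: OddsRatioResult
    scores: pd.Series = field(repr=False, default=None)
    calls: pd.Series = field(repr=False, default=None)
    univariate: list[OddsRatioResult] = field(default_factory=list)
    multivariate: list[OddsRatioResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": asdict(self.table),
            "metrics": self.metrics.to_dict(),
            "auc": asdict(self.auc),
            "odds_ratio": asdict(self.odds_ratio),
            "univariate": [asdict(r) for r in self.univariate],
            "multivariate": [asdict(r) for r in self.multivariate],
        }

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            m = getattr(self.metrics, name)
            if m is not None:
                rows.append((name, m.pct, m.se, m.numerator, m.denominator))
        rows.append(("auc", 100 * self.auc.auc, 100 * self.auc.se, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["metric", "pct", "se", "num", "den"])


def evaluate_cohort(model, matrix, labels: pd.Series | None = None,
                    clinical: pd.DataFrame | None = None,
                    any_mutation: bool = False) -> EvaluationReport:
    """Score, classify and fully evaluate ``model`` on a labeled cohort.

    Model genes absent from the matrix are treated as unmutated.  When a
    clinical table is given, univariate and multivariate logistic
    associations of the classifier call and the clinical covariates with
    non-response are appended.
    """
    lab = matrix.labels if labels is None else labels
    scores = model.score_matrix(matrix)
    calls = model.classify_matrix(matrix, any_mutation=any_mutation)
    table = ConfusionTable.from_calls(calls, lab)
    report = EvaluationReport(
        table=table,
        metrics=confusion_metrics(table),
        auc=delong_auc(scores.to_numpy(), lab),
        odds_ratio=odds_ratio_wald(table),
        scores=scores,
        calls=calls,
    )
    if clinical is not None:
        preds = _association_predictors(calls, clinical)
        report.univariate = logistic_association(preds, lab, adjusted=False)
        report.multivariate = logistic_association(preds, lab, adjusted=True)
    return report


def _association_predictors(calls: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    df = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    df = df.reindex(calls.index).replace(".", np.nan)
    preds = pd.DataFrame(index=calls.index)
    preds["classifier"] = (calls == NON_RESPONDER).astype(float)
    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce")
        preds["age_old"] = (age >= np.nanmedian(age)).where(age.notna()).astype(float)
    if "stage" in df.columns:
        preds["advanced_stage"] = df["stage"].map(
            lambda s: np.nan if pd.isna(s) else float(str(s).startswith("II")))
    if "differentiation" in df.columns:
        preds["poor_differentiation"] = df["differentiation"].map(
            lambda s: np.nan if pd.isna(s) else float(s == "poor"))
    if "scc_ag" in df.columns:
        preds["log_scc_ag"] = np.log(pd.to_numeric(df["scc_ag"], errors="coerce"))
    return preds
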