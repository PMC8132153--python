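"""Final risk-model construction and the clinical-covariate classifier.

After the penalized cascade, the surviving candidates pass two
co-occurrence (Spearman) checks, then a greedy forward search seeded
with the two top-ranked genes: at each step the candidate whose addition
maximizes cross-validated AUC joins the model, ties going to the better
lasso rank and then to the candidate with fewer strong positive
correlations; the search stops when no addition strictly improves the
AUC.  The final logistic fit on the whole training set yields the risk
score — intercept + sum of per-gene log-odds coefficients over mutated
genes — and a Youden-index cutoff separates predicted non-responders
(score >= cutoff) from responders.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .evaluation import delong_auc
from .feature_selection import _as_xy, _label_array, spearman_prune
from .mutation_enrichment import MutationMatrix, NON_RESPONDER, RESPONDER

TIE_TOL = 1e-12


@dataclass
class RiskModel:
    """Weighted mutation risk score with a classification cutoff."""

    intercept: float
    coefficients: dict[str, float]
    cutoff: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValueError("duplicate genes in model")

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients)

    def risk_score(self, profile) -> float:
        """Intercept + sum of coefficients over mutated model genes.

        ``profile`` maps gene -> {0,1}; genes absent from the profile
        count as unmutated, genes absent from the model are ignored with
        a warning.
        """
        if isinstance(profile, pd.Series):
            profile = profile.to_dict()
        unknown = set(profile) - set(self.coefficients)
        if unknown:
            warnings.warn(f"profile genes not in model ignored: {sorted(unknown)[:5]}",
                          stacklevel=2)
        return float(self.intercept + sum(
            self.coefficients[g] * float(profile.get(g, 0)) for g in self.coefficients
        ))

    def score_matrix(self, matrix: MutationMatrix) -> pd.Series:
        sub = matrix.restrict(self.genes).data.astype(float)
        coef = np.array([self.coefficients[g] for g in self.genes])
        return pd.Series(self.intercept + sub.to_numpy() @ coef,
                         index=sub.index, name="risk_score")

    def classify(self, profile, any_mutation: bool = False) -> str:
        """Non-responder iff score >= cutoff (ties go to non-responder).

        ``any_mutation=True`` switches to the alternative rule that calls
        non-responder whenever any model gene is mutated.
        """
        if isinstance(profile, pd.Series):
            profile = profile.to_dict()
        if any_mutation:
            hit = any(float(profile.get(g, 0)) > 0 for g in self.coefficients)
            return NON_RESPONDER if hit else RESPONDER
        if self.cutoff is None:
            raise ValueError("model has no cutoff; classification disabled")
        return NON_RESPONDER if self.risk_score(profile) >= self.cutoff else RESPONDER

    def classify_matrix(self, matrix: MutationMatrix,
                        any_mutation: bool = False) -> pd.Series:
        if any_mutation:
            hit = matrix.restrict(self.genes).data.sum(axis=1) > 0
            return hit.map({True: NON_RESPONDER, False: RESPONDER}).rename("call")
        if self.cutoff is None:
            raise ValueError("model has no cutoff; classification disabled")
        scores = self.score_matrix(matrix)
        return pd.Series(np.where(scores >= self.cutoff, NON_RESPONDER, RESPONDER),
                         index=scores.index, name="call")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"intercept": self.intercept,
                "coefficients": dict(self.coefficients),
                "cutoff": self.cutoff,
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(float(d["intercept"]),
                   {str(k): float(v) for k, v in d["coefficients"].items()},
                   None if d.get("cutoff") is None else float(d["cutoff"]),
                   dict(d.get("provenance", {})))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def published_c_classifier() -> RiskModel:
    """The published 15-gene cervical-cancer NACT classifier (cutoff 8.4)."""
    text = resources.files("nactrisk").joinpath("data/c15_published.json").read_text()
    return RiskModel.from_dict(json.loads(text))


@dataclass
class CutoffResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def youden_cutoff(scores, labels) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Thresholds are the midpoints between adjacent distinct sorted
    scores, with score >= threshold called non-responder; the smallest
    maximizing threshold is returned.  All-identical scores give J = 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = _label_array(labels, None)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    distinct = np.unique(scores)
    if len(distinct) == 1:
        return CutoffResult(float(distinct[0]), 0.0, 1.0, 0.0)
    thresholds = (distinct[:-1] + distinct[1:]) / 2
    best = None
    for t in thresholds:
        call = scores >= t
        sens = (call & (y == 1)).sum() / (y == 1).sum()
        spec = (~call & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1
        if best is None or j > best[1] + TIE_TOL:
            best = (float(t), float(j), float(sens), float(spec))
    return CutoffResult(*best)


def cooccurrence_prune(matrix, candidates: list[str], scores: pd.Series,
                       threshold: float = 0.5, rounds: int = 2
                       ) -> tuple[list[str], pd.DataFrame]:
    """Consecutive Spearman co-occurrence checks before the final build."""
    logs = []
    kept = list(candidates)
    for _ in range(rounds):
        kept, log = spearman_prune(matrix, kept, scores, threshold=threshold)
        logs.append(log)
    return kept, pd.concat(logs, ignore_index=True)


@dataclass
class GreedyConfig:
    cv_folds: int = 10
    spearman_threshold: float = 0.5
    seed: int = 0


def _cv_auc(X: np.ndarray, y: np.ndarray, cols: list[int], folds) -> float:
    """Pooled out-of-fold AUC of an (effectively unpenalized) logistic fit."""
    pred = np.empty(len(y))
    sub = X[:, cols]
    for train, test in folds:
        est = LogisticRegression(C=1e6, max_iter=1000)
        est.fit(sub[train], y[train])
        pred[test] = est.predict_proba(sub[test])[:, 1]
    return _auc(pred, y)


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties (rank formula)."""
    r = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def greedy_forward_auc(matrix, labels, candidates: list[str],
                       config: GreedyConfig | None = None,
                       lasso_ranks: dict[str, int] | None = None) -> RiskModel:
    """Fixed-top-2 greedy AUC forward logistic model build.

    ``candidates`` must be ordered by lasso rank (best first) unless
    ``lasso_ranks`` is given.  The two top-ranked genes are fixed; each
    step adds the remaining candidate with the highest cross-validated
    AUC, breaking ties by better lasso rank and then by fewer positive
    Spearman correlations >= the threshold to the other candidates;
    candidates tied with the winner are permanently discarded.  The
    search stops when no addition strictly increases the AUC.  The final
    coefficients come from a logistic fit on the full training set
    (ridge-stabilized under separation, flagged in provenance), and the
    cutoff from the Youden rule on the training scores.
    """
    config = config or GreedyConfig()
    X_df, y = _as_xy(matrix, labels)
    if len(candidates) < 2:
        raise ValueError("need at least two candidates")
    ranks = lasso_ranks or {g: i + 1 for i, g in enumerate(candidates)}
    order = sorted(candidates, key=lambda g: ranks[g])
    X = X_df[order].to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(order)}

    # one fold assignment for the whole build keeps candidate comparisons fair
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    folds = list(skf.split(X, y))

    pos_corr = _positive_correlation_counts(X_df[order], config.spearman_threshold)

    selected = order[:2]
    remaining = order[2:]
    current_auc = _cv_auc(X, y, [idx[g] for g in selected], folds)
    auc_path = [(tuple(selected), current_auc)]
    while remaining:
        scored = []
        for g in remaining:
            auc = _cv_auc(X, y, [idx[s] for s in selected] + [idx[g]], folds)
            scored.append((g, auc))
        best_auc = max(a for _, a in scored)
        tied = [g for g, a in scored if a >= best_auc - TIE_TOL]
        tied.sort(key=lambda g: (ranks[g], pos_corr[g]))
        winner = tied[0]
        if best_auc <= current_auc + TIE_TOL:
            break
        selected = selected + [winner]
        current_auc = best_auc
        auc_path.append((winner, best_auc))
        remaining = [g for g in remaining if g not in tied]

    intercept, coefs, stabilized = _full_fit(X_df[selected].to_numpy(dtype=float), y)
    model = RiskModel(intercept, dict(zip(selected, coefs)), provenance={
        "candidates": list(candidates),
        "auc_path": [[list(g) if isinstance(g, tuple) else g, a] for g, a in auc_path],
        "cv_auc": current_auc,
        "seed": config.seed,
        "stabilized": stabilized,
    })
    scores = model.score_matrix(_as_matrix(matrix, X_df, labels))
    cut = youden_cutoff(scores.to_numpy(), y)
    model.cutoff = cut.cutoff
    return model


def _positive_correlation_counts(X_df: pd.DataFrame, threshold: float) -> dict[str, int]:
    if X_df.shape[1] < 2:
        return {g: 0 for g in X_df.columns}
    with np.errstate(invalid="ignore"):
        corr = stats.spearmanr(X_df.to_numpy(dtype=float)).statistic
    corr = np.atleast_2d(np.nan_to_num(corr))
    np.fill_diagonal(corr, 0.0)
    counts = (corr >= threshold).sum(axis=1)
    return dict(zip(X_df.columns, counts.astype(int)))


def _full_fit(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    import statsmodels.api as sm

    exog = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        converged = bool(res.mle_retvals.get("converged", True))
        if converged and np.all(np.isfinite(params)) and np.abs(params).max() < 1e3:
            return float(params[0]), params[1:], False
    except Exception:
        pass
    est = LogisticRegression(C=1e2, max_iter=2000)
    est.fit(X, y)
    return float(est.intercept_[0]), est.coef_.ravel(), True


def _as_matrix(matrix, X_df: pd.DataFrame, labels) -> MutationMatrix:
    if isinstance(matrix, MutationMatrix):
        return matrix
    lab = labels if isinstance(labels, pd.Series) else pd.Series(
        np.where(_label_array(labels, None) == 1, NON_RESPONDER, RESPONDER),
        index=X_df.index)
    return MutationMatrix(X_df.astype(np.int8), lab)


@dataclass
class ClinicalModel:
    """Logistic model on clinical covariates with its training ROC."""

    params: pd.Series
    bse: pd.Series
    fitted: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    n_used: int
    n_excluded: int
    dropped_covariates: list[str]
    age_median: float


def fit_clinical_classifier(clinical: pd.DataFrame, labels: pd.Series | None = None
                            ) -> ClinicalModel:
    """Binomial logistic model of non-response on clinical covariates.

    Age is dichotomized at the cohort median; stage and differentiation
    are dummy-coded; SCC-ag enters log-transformed.  Samples with any
    missing covariate (NaN or ".") are excluded; covariates constant
    after exclusion are dropped with a warning.
    """
    import statsmodels.api as sm

    df = clinical.copy().replace(".", np.nan)
    if labels is None:
        labels = pd.Series(df["response"].to_numpy(), index=df.index)
    else:
        labels = labels.reset_index(drop=True)
    y_all = pd.Series(_label_array(labels, None), index=df.index)

    covs = pd.DataFrame(index=df.index)
    age = pd.to_numeric(df.get("age"), errors="coerce")
    age_median = float(np.nanmedian(age))
    covs["age_old"] = (age >= age_median).where(age.notna()).astype(float)
    for col in ("stage", "differentiation"):
        if col in df.columns:
            dummies = pd.get_dummies(df[col], prefix=col, drop_first=True,
                                     dtype=float)
            dummies[df[col].isna()] = np.nan
            covs = covs.join(dummies)
    if "scc_ag" in df.columns:
        covs["log_scc_ag"] = np.log(pd.to_numeric(df["scc_ag"], errors="coerce"))

    complete = covs.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    covs, y = covs[complete], y_all[complete]
    if min(np.bincount(y.astype(int), minlength=2)) < 2:
        raise ValueError("need >=2 samples per class after missing-value exclusion")

    dropped = [c for c in covs.columns if covs[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"constant covariates dropped: {dropped}", stacklevel=2)
        covs = covs.drop(columns=dropped)

    exog = sm.add_constant(covs.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y.to_numpy(), exog, family=sm.families.Binomial()).fit()
    names = ["const", *covs.columns]
    fitted = pd.Series(res.fittedvalues, index=covs.index, name="fitted")
    if fitted.nunique() == 1:
        auc, ci = 0.5, (0.5, 0.5)
    else:
        d = delong_auc(fitted.to_numpy(), y.to_numpy())
        auc, ci = d.auc, (d.ci_low, d.ci_high)
    return ClinicalModel(pd.Series(res.params, index=names),
                         pd.Series(res.bse, index=names),
                         fitted, auc, ci, int(complete.sum()), n_excluded,
                         dropped, age_median)
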