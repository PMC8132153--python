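"""Repeated penalized-regression cascade for candidate-gene reduction.

Candidates pass through three penalized logistic stages in order —
ridge, elastic net, lasso — each repeated ``n_reps`` times with fresh
cross-validation fold assignments.  In every repetition the penalty
strength is chosen at minimum cross-validated mean squared error of the
predicted probabilities (the glmnet ``type.measure = "mse"`` rule), the
model is refit on the full data, and each gene's coefficient is
accumulated when nonzero.  Genes are ranked by absolute summed
coefficient, the top fraction is retained, and a Spearman
multicollinearity prune removes, from each highly correlated pair, the
member with the smaller absolute summed coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .mutation_enrichment import MutationMatrix

PENALTIES = ("ridge", "elastic_net", "lasso")


@dataclass
class StageConfig:
    """One stage of the cascade."""

    penalty: str
    keep_fraction: float | None = None
    keep_count: int | None = None
    l1_ratio: float = 0.5  # elastic-net mixing; ignored otherwise

    def __post_init__(self) -> None:
        if self.penalty not in PENALTIES:
            raise ValueError(f"penalty must be one of {PENALTIES}")
        if self.keep_fraction is not None and not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.keep_fraction is None and self.keep_count is None:
            raise ValueError("a stage needs keep_fraction or keep_count")


@dataclass
class SelectionConfig:
    """Cascade parameters; defaults follow the published build.

    200 repetitions per stage with 10-fold stratified CV, retention
    fractions 80% / 90% / 75% for ridge / elastic net / lasso, and
    Spearman pruning at |r| >= 0.5 after every stage.
    """

    stages: tuple[StageConfig, ...] = (
        StageConfig("ridge", keep_fraction=0.80),
        StageConfig("elastic_net", keep_fraction=0.90),
        StageConfig("lasso", keep_fraction=0.75),
    )
    n_reps: int = 200
    cv_folds: int = 10
    n_penalties: int = 10
    penalty_grid: tuple[float, float] = (1e-2, 1e2)  # C range, log-spaced
    spearman_threshold: float = 0.5
    max_failure_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def reduced(self, n_reps: int = 8, cv_folds: int = 5,
                n_penalties: int = 8) -> "SelectionConfig":
        """A cheaper profile for quick runs and simulation studies."""
        return replace(self, n_reps=n_reps, cv_folds=cv_folds,
                       n_penalties=n_penalties)


@dataclass
class SelectionStageResult:
    stage: str
    table: pd.DataFrame  # gene, summed_coef, nonzero_freq, rank, retained, dropped_by
    retained_genes: list[str]
    n_failed: int

    def scores(self) -> pd.Series:
        return self.table.set_index("gene")["summed_coef"]


def _estimator(stage: StageConfig, C: float, seed: int) -> LogisticRegression:
    # explicit random_state: saga/liblinear shuffle internally
    if stage.penalty == "ridge":
        return LogisticRegression(C=C, l1_ratio=0.0, solver="lbfgs", max_iter=200)
    if stage.penalty == "lasso":
        return LogisticRegression(C=C, l1_ratio=1.0, solver="liblinear",
                                  max_iter=200, random_state=seed)
    return LogisticRegression(C=C, l1_ratio=stage.l1_ratio, solver="saga",
                              max_iter=5000, tol=1e-3, random_state=seed)


def _one_repetition(X: np.ndarray, y: np.ndarray, stage: StageConfig,
                    c_grid: np.ndarray, cv_folds: int, rep_seed: int
                    ) -> np.ndarray | None:
    """Coefficients of the min-CV-MSE fit for one repetition, or None on failure."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rep_seed)
    folds = list(skf.split(X, y))
    mse = np.zeros(len(c_grid))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            for k, C in enumerate(c_grid):
                errs = []
                for train, test in folds:
                    est = _estimator(stage, C, rep_seed)
                    est.fit(X[train], y[train])
                    p = est.predict_proba(X[test])[:, 1]
                    errs.append(np.mean((p - y[test]) ** 2))
                mse[k] = np.mean(errs)
            # tie -> strongest penalty (smallest C), mirroring lambda.min parsimony
            best = int(np.argmin(mse))
            est = _estimator(stage, c_grid[best], rep_seed)
            est.fit(X, y)
    except (ConvergenceWarning, ValueError, ArithmeticError):
        return None
    coef = est.coef_.ravel()
    if not np.all(np.isfinite(coef)):
        return None
    return coef


def repeated_penalized_selection(matrix: MutationMatrix | pd.DataFrame,
                                 labels: pd.Series | np.ndarray | None,
                                 config: SelectionConfig,
                                 stage: StageConfig) -> SelectionStageResult:
    """Run one repeated penalized stage and apply its retention rule.

    Genes constant across all samples are dropped before fitting.  For
    the ridge stage every gene counts as nonzero (ridge never yields
    exact zeros); for the sparse stages a gene's coefficient is
    accumulated only in repetitions where it is nonzero.  Repetitions
    that fail to converge are excluded; more than
    ``max_failure_fraction`` failures is an error.
    """
    X_df, y = _as_xy(matrix, labels)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least two samples in each class")
    variable = X_df.columns[X_df.nunique() > 1]
    X_df = X_df[variable]
    X = X_df.to_numpy(dtype=float)
    genes = list(X_df.columns)

    c_grid = np.geomspace(*config.penalty_grid, config.n_penalties)
    rng = np.random.default_rng(config.seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=config.n_reps)

    summed = np.zeros(len(genes))
    nonzero = np.zeros(len(genes))
    n_failed = 0
    for rep_seed in rep_seeds:
        coef = _one_repetition(X, y, stage, c_grid, config.cv_folds, int(rep_seed))
        if coef is None:
            n_failed += 1
            continue
        nz = np.ones_like(coef, dtype=bool) if stage.penalty == "ridge" \
            else np.abs(coef) > 1e-10
        summed += np.where(nz, coef, 0.0)
        nonzero += nz
    if n_failed > config.max_failure_fraction * config.n_reps:
        raise RuntimeError(
            f"{n_failed}/{config.n_reps} repetitions failed in stage {stage.penalty}"
        )

    order = np.lexsort((np.arange(len(genes)), -np.abs(summed)))
    rank = np.empty(len(genes), dtype=int)
    rank[order] = np.arange(1, len(genes) + 1)

    nz_mask = np.abs(summed) > 1e-10
    n_nonzero = int(nz_mask.sum())
    if stage.keep_count is not None:
        n_keep = min(stage.keep_count, n_nonzero)
    else:
        n_keep = int(np.ceil(stage.keep_fraction * n_nonzero))
    keep_ranks = set(rank[order[:n_keep]]) if n_keep else set()
    retained = np.array([r in keep_ranks and m for r, m in zip(rank, nz_mask)])

    table = pd.DataFrame({
        "gene": genes,
        "summed_coef": summed,
        "nonzero_freq": nonzero / max(config.n_reps - n_failed, 1),
        "rank": rank,
        "retained": retained,
        "dropped_by": "",
    })
    kept = [g for _, g in sorted(zip(rank, genes)) if table.set_index("gene")
            .loc[g, "retained"]]
    return SelectionStageResult(stage.penalty, table, kept, n_failed)


def spearman_prune(matrix: MutationMatrix | pd.DataFrame, genes: list[str],
                   scores: pd.Series, threshold: float = 0.5
                   ) -> tuple[list[str], pd.DataFrame]:
    """Drop, from each |Spearman r| >= threshold pair, the lower-scored gene.

    Pairs are resolved worst-first (largest |r|; ties broken by gene
    order); correlations among survivors are re-examined until no pair
    exceeds the threshold.  Returns the pruned list (input order) and a
    drop log with the partner and correlation that triggered each drop.
    """
    X_df = _as_xy(matrix, None)[0] if not isinstance(matrix, pd.DataFrame) else matrix
    alive = list(genes)
    dropped: list[tuple[str, str, float]] = []
    while len(alive) > 1:
        sub = X_df[alive].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corr = stats.spearmanr(sub).statistic
        corr = np.atleast_2d(np.nan_to_num(corr))
        np.fill_diagonal(corr, 0.0)
        flat = np.abs(corr)
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        if flat[i, j] < threshold:
            break
        gi, gj = alive[i], alive[j]
        si, sj = abs(scores.get(gi, 0.0)), abs(scores.get(gj, 0.0))
        loser, partner = (gi, gj) if si < sj else (gj, gi)
        dropped.append((loser, partner, float(corr[i, j])))
        alive.remove(loser)
    log = pd.DataFrame(dropped, columns=["gene", "partner", "spearman_r"])
    return alive, log


@dataclass
class CascadeResult:
    stages: list[SelectionStageResult]
    final_genes: list[str]
    lasso_ranks: dict[str, int]
    drop_logs: list[pd.DataFrame] = field(default_factory=list)


def run_cascade(matrix: MutationMatrix | pd.DataFrame,
                labels: pd.Series | np.ndarray | None,
                config: SelectionConfig,
                candidates: list[str] | None = None) -> CascadeResult:
    """Ridge -> elastic net -> lasso, each followed by Spearman pruning.

    The survivors of each stage become the candidate set of the next;
    the returned ``lasso_ranks`` order the final genes for the greedy
    model build.  With the seed fixed, the whole cascade is
    deterministic.
    """
    X_df, y = _as_xy(matrix, labels)
    if candidates is not None:
        X_df = X_df[[g for g in candidates if g in X_df.columns]]
    y_series = pd.Series(y, index=X_df.index)

    rng = np.random.default_rng(config.seed)
    stage_results: list[SelectionStageResult] = []
    drop_logs: list[pd.DataFrame] = []
    current = X_df
    for stage in config.stages:
        stage_cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        res = repeated_penalized_selection(current, y_series, stage_cfg, stage)
        kept, log = spearman_prune(current, res.retained_genes, res.scores(),
                                   threshold=config.spearman_threshold)
        if not log.empty:
            tbl = res.table.set_index("gene")
            tbl.loc[log["gene"], "dropped_by"] = log.set_index("gene")["partner"]
            tbl.loc[log["gene"], "retained"] = False
            res.table = tbl.reset_index()
        res.retained_genes = kept
        stage_results.append(res)
        drop_logs.append(log)
        current = current[kept]
        if len(kept) < 2:
            break

    final = stage_results[-1].retained_genes
    last = stage_results[-1].table.set_index("gene")
    ranks = {g: int(last.loc[g, "rank"]) for g in final}
    return CascadeResult(stage_results, final, ranks, drop_logs)


def _as_xy(matrix, labels) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(matrix, MutationMatrix):
        X_df = matrix.data.astype(float)
        y = matrix.y if labels is None else _label_array(labels, X_df.index)
    else:
        X_df = matrix.astype(float)
        y = None if labels is None else _label_array(labels, X_df.index)
        if y is None:
            raise ValueError("labels are required with a bare DataFrame")
    return X_df, y


def _label_array(labels, index) -> np.ndarray:
    if isinstance(labels, pd.Series):
        labels = labels.reindex(index)
        if labels.isna().any():
            raise ValueError("labels missing for some samples")
        values = labels.to_numpy()
    else:
        values = np.asarray(labels)
    if values.dtype.kind in "USO":
        return (values == "non_responder").astype(int)
    return values.astype(int)
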