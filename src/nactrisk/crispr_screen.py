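"""CRISPR knockout screen analysis: normalization, enrichment, hit calling.

Counts from a pooled loss-of-function screen (3-6 sgRNAs per gene, two
independent experiments, three replicates per arm) are normalized by
median-of-ratios size factors, summarized to gene-level fold changes of
drug-treated over control arms, and passed through a two-tier selection
rule: (i) consistent enrichment (fold > 1, p < 0.1) in both experiments
of a condition, or (ii) strong enrichment (fold > 1.32, p < 0.1) in
either experiment of a condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "control"

COLUMN_LEVELS = ("condition", "experiment", "replicate")


@dataclass
class ScreenCounts:
    """sgRNA count matrix with design metadata.

    ``counts`` is indexed by sgRNA id with a (condition, experiment,
    replicate) column MultiIndex; ``gene_map`` maps each sgRNA to exactly
    one gene.
    """

    counts: pd.DataFrame
    gene_map: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns.names) != list(COLUMN_LEVELS):
            raise ValueError(f"counts columns must be a {COLUMN_LEVELS} MultiIndex")
        values = self.counts.to_numpy()
        if (values < 0).any() or not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)) or (values < 0).any():
                raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        self.gene_map = self.gene_map.reindex(self.counts.index)
        if self.gene_map.isna().any():
            raise ValueError("every sgRNA must map to a gene")

    @property
    def conditions(self) -> list[str]:
        return sorted({c for c in self.counts.columns.get_level_values(0) if c != CONTROL})

    @property
    def experiments(self) -> list:
        return sorted(set(self.counts.columns.get_level_values(1)))

    def to_long(self) -> pd.DataFrame:
        long = self.counts.stack(list(range(3)), future_stack=True).rename("count").reset_index()
        long.columns = ["sgrna", *COLUMN_LEVELS, "count"]
        long.insert(1, "gene", long["sgrna"].map(self.gene_map).to_numpy())
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ScreenCounts":
        gene_map = (long[["sgrna", "gene"]].drop_duplicates().set_index("sgrna")["gene"])
        if gene_map.index.duplicated().any():
            raise ValueError("an sgRNA maps to more than one gene")
        wide = long.pivot_table(index="sgrna", columns=list(COLUMN_LEVELS),
                                values="count", aggfunc="sum")
        wide = wide.reindex(gene_map.index)
        return cls(wide.fillna(0).astype(np.int64), gene_map)


def size_factors(screen: ScreenCounts, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factor per column.

    Each column's factor is the median, over sgRNAs with nonzero counts
    in every column, of the ratio of the column's count to the sgRNA's
    geometric mean across columns.  ``pseudocount`` > 0 is added to all
    counts first, rescuing libraries where no sgRNA is everywhere
    nonzero.
    """
    counts = screen.counts.to_numpy(dtype=float) + pseudocount
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=screen.counts.columns)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no sgRNA has nonzero counts in every column; "
            "pass pseudocount > 0 to size_factors"
        )
    logs = np.log(counts[usable])
    log_gm = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(factors, index=screen.counts.columns, name="size_factor")


def normalized_counts(screen: ScreenCounts, pseudocount: float = 0.0) -> pd.DataFrame:
    return screen.counts / size_factors(screen, pseudocount=pseudocount)


def gene_enrichment(screen: ScreenCounts, condition: str, experiment,
                    pseudocount: float = 0.5,
                    norm: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene fold change and p-value for one condition x experiment.

    Normalized counts are averaged over each gene's sgRNAs within every
    replicate; the fold change is the ratio of treated to control
    replicate means (with ``pseudocount`` substituted when the control
    mean is zero, flagged), and the p-value is a two-sided pooled-variance
    t-test on log2(gene-level normalized count + pseudocount) between the
    treated and control replicates.
    """
    if norm is None:
        norm = normalized_counts(screen)
    cols = norm.columns
    treated = norm.loc[:, (cols.get_level_values(0) == condition)
                       & (cols.get_level_values(1) == experiment)]
    control = norm.loc[:, (cols.get_level_values(0) == CONTROL)
                       & (cols.get_level_values(1) == experiment)]
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(
            f"condition {condition!r} experiment {experiment!r} needs >=2 treated "
            "and >=2 control replicates"
        )
    gene_t = treated.groupby(screen.gene_map).mean()
    gene_c = control.groupby(screen.gene_map).mean()

    mean_t = gene_t.mean(axis=1)
    mean_c = gene_c.mean(axis=1)
    zero_control = mean_c == 0
    fold = (mean_t + pseudocount * zero_control) / (mean_c + pseudocount * zero_control)

    log_t = np.log2(gene_t + pseudocount)
    log_c = np.log2(gene_c + pseudocount)
    tstat, pval = stats.ttest_ind(log_t, log_c, axis=1, equal_var=True)
    pval = np.where(np.isnan(pval), 1.0, pval)

    return pd.DataFrame({
        "gene": gene_t.index,
        "condition": condition,
        "experiment": experiment,
        "fold_change": fold.to_numpy(),
        "log2_fc": np.log2(fold.to_numpy()),
        "p_value": pval,
        "zero_control": zero_control.to_numpy(),
    }).reset_index(drop=True)


def gene_enrichment_all(screen: ScreenCounts, pseudocount: float = 0.5) -> pd.DataFrame:
    """``gene_enrichment`` over every (condition, experiment) pair, stacked."""
    norm = normalized_counts(screen)
    frames = [
        gene_enrichment(screen, cond, exp, pseudocount=pseudocount, norm=norm)
        for cond, exp in itertools.product(screen.conditions, screen.experiments)
    ]
    return pd.concat(frames, ignore_index=True)


def select_hits(results: pd.DataFrame,
                criterion_i_conditions: tuple[str, ...] = ("DDP", "Taxol"),
                criterion_ii_conditions: tuple[str, ...] = ("Taxol", "DDP+Taxol"),
                fc_min: float = 1.0, fc_alt: float = 1.32,
                p_max: float = 0.1) -> pd.DataFrame:
    """Two-tier hit selection over per-gene per-experiment results.

    Criterion (i): within a condition of the first group, fold change
    > ``fc_min`` and p < ``p_max`` in *both* independent experiments.
    Criterion (ii): within a condition of the second group, fold change
    > ``fc_alt`` and p < ``p_max`` in *either* experiment.  A gene is a
    hit if any condition satisfies its criterion; the returned table
    carries one row per (gene, condition, criterion) with the
    per-experiment evidence.  Genes observed in only one experiment are
    evaluated under criterion (ii) only and flagged.
    """
    rows = []
    for (gene, cond), sub in results.groupby(["gene", "condition"], sort=True):
        fc = sub.set_index("experiment")["fold_change"]
        p = sub.set_index("experiment")["p_value"]
        n_exp = len(sub)
        single = n_exp < 2
        ok_each = (fc > fc_min) & (p < p_max)
        strong_each = (fc > fc_alt) & (p < p_max)
        if cond in criterion_i_conditions and not single and ok_each.all():
            rows.append((gene, cond, "i", *_evidence(fc, p), single))
        if cond in criterion_ii_conditions and strong_each.any():
            rows.append((gene, cond, "ii", *_evidence(fc, p), single))
    return pd.DataFrame(rows, columns=["gene", "condition", "criterion",
                                       "fc_exp1", "fc_exp2", "p_exp1", "p_exp2",
                                       "single_experiment"])


def _evidence(fc: pd.Series, p: pd.Series) -> tuple[float, float, float, float]:
    exps = sorted(fc.index)
    f1 = float(fc[exps[0]])
    p1 = float(p[exps[0]])
    f2 = float(fc[exps[1]]) if len(exps) > 1 else np.nan
    p2 = float(p[exps[1]]) if len(exps) > 1 else np.nan
    return f1, f2, p1, p2


def hit_genes(hits: pd.DataFrame) -> list[str]:
    return sorted(hits["gene"].astype(str).unique())
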