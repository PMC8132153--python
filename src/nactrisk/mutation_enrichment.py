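"""Binary mutation matrices and per-gene enrichment testing.

The discovery analysis reduces whole-exome somatic calls to a binary
sample x gene matrix (1 = at least one non-silent somatic mutation) and
asks, gene by gene, whether mutations are over-represented among
chemotherapy non-responders.  Candidate resistance genes are those
mutated in at least ``min_diff`` more non-responders than responders
with an unadjusted two-sided Fisher p below a permissive threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NON_RESPONDER = "non_responder"
RESPONDER = "responder"
LABELS = (RESPONDER, NON_RESPONDER)

#: Variant classes that set the mutation indicator (MAF-style spellings,
#: matched case-insensitively after stripping underscores/spaces).
NONSILENT_CLASSES = frozenset({
    "missense_mutation", "missense",
    "nonsense_mutation", "nonsense",
    "nonstop_mutation", "nonstop",
    "frame_shift_ins", "frame_shift_del", "frameshift_insertion",
    "frameshift_deletion", "frame_shift_indel",
    "in_frame_ins", "in_frame_del", "inframe_insertion", "inframe_deletion",
    "splice_site", "splicing",
})

#: Variant classes known to be silent / non-coding; these never set the
#: indicator.  Anything outside both sets triggers a warning and is
#: treated as silent.
SILENT_CLASSES = frozenset({
    "silent", "synonymous", "synonymous_variant",
    "3'utr", "5'utr", "utr3", "utr5", "3'flank", "5'flank",
    "intron", "intronic", "igr", "rna", "lincrna",
    "translation_start_site",
})


def _canon_class(value: str) -> str:
    return str(value).strip().lower().replace(" ", "_")


@dataclass
class MutationMatrix:
    """Binary sample x gene mutation matrix with response labels.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id, one column per gene, entries in
        {0, 1}.
    labels:
        Series over the same samples with values ``"responder"`` /
        ``"non_responder"``.
    cohort:
        Optional per-sample cohort tag (e.g. ``"training"``).
    """

    data: pd.DataFrame
    labels: pd.Series
    cohort: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate gene ids in matrix")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        self.data = self.data.astype(np.int8)
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"samples without a response label: {missing[:5]}")
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown response labels: {sorted(bad)}")
        if self.cohort is not None:
            self.cohort = self.cohort.reindex(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def y(self) -> np.ndarray:
        """Label vector with the positive class (non-responder) as 1."""
        return (self.labels == NON_RESPONDER).to_numpy(dtype=int)

    def restrict(self, genes) -> "MutationMatrix":
        """Return a copy restricted to ``genes`` (missing genes -> 0 columns)."""
        cols = pd.DataFrame(
            {g: self.data[g] if g in self.data.columns else 0 for g in genes},
            index=self.data.index,
        )
        return MutationMatrix(cols, self.labels.copy(),
                              None if self.cohort is None else self.cohort.copy())


@dataclass
class GeneMutationStat:
    """Per-gene 2x2 association between mutation and non-response."""

    gene: str
    mut_insen: int
    mut_sen: int
    n_insen: int
    n_sen: int
    fisher_p: float = field(default=np.nan)
    odds_ratio: float = field(default=np.nan)

    @property
    def diff(self) -> int:
        return self.mut_insen - self.mut_sen


def build_matrix(variants: pd.DataFrame, roster: pd.DataFrame,
                 af_threshold: float = 0.01) -> MutationMatrix:
    """Collapse a MAF-lite variant table into a binary mutation matrix.

    A (sample, gene) cell is 1 iff at least one variant of a non-silent
    class survives the germline-frequency filter: variants with
    population allele frequency > ``af_threshold`` are discarded as
    presumed germline; a missing frequency is kept (not known-common).

    Parameters
    ----------
    variants:
        Columns ``sample``, ``gene``, ``variant_classification`` and
        optionally ``population_af``.
    roster:
        Columns ``sample``, ``response`` and optionally ``cohort``; every
        variant's sample must appear here, and rostered samples without
        variants get all-zero rows.
    """
    roster = roster.reset_index(drop=True)
    samples = roster["sample"].astype(str).tolist()
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate samples in roster")
    known = set(samples)
    unknown = set(variants["sample"].astype(str)) - known
    if unknown:
        raise ValueError(f"variant samples absent from roster: {sorted(unknown)[:5]}")

    kept = variants.copy()
    kept["sample"] = kept["sample"].astype(str)
    classes = kept["variant_classification"].map(_canon_class)
    unknown_classes = sorted(set(classes) - NONSILENT_CLASSES - SILENT_CLASSES)
    if unknown_classes:
        warnings.warn(
            f"unknown variant classification(s) treated as silent: {unknown_classes}",
            stacklevel=2,
        )
    kept = kept[classes.isin(NONSILENT_CLASSES).to_numpy()]
    if "population_af" in kept.columns:
        af = pd.to_numeric(kept["population_af"], errors="coerce")
        kept = kept[(af.isna() | (af <= af_threshold)).to_numpy()]

    genes = sorted(kept["gene"].astype(str).unique())
    data = pd.DataFrame(0, index=pd.Index(samples, name="sample"), columns=genes,
                        dtype=np.int8)
    for sample, gene in zip(kept["sample"], kept["gene"].astype(str)):
        data.at[sample, gene] = 1

    labels = pd.Series(roster["response"].to_numpy(), index=data.index, name="response")
    cohort = None
    if "cohort" in roster.columns:
        cohort = pd.Series(roster["cohort"].to_numpy(), index=data.index, name="cohort")
    return MutationMatrix(data, labels, cohort)


def fisher_gene_test(mut_insen: int, n_insen: int, mut_sen: int, n_sen: int,
                     gene: str = "") -> GeneMutationStat:
    """Two-sided Fisher exact test for one gene's 2x2 table.

    The table is ``[[mut_insen, n_insen - mut_insen], [mut_sen,
    n_sen - mut_sen]]``; the two-sided p sums all hypergeometric tables
    whose probability does not exceed that of the observed one.  The
    odds ratio is the cross-product with a Haldane-Anscombe 0.5 added to
    every cell when any cell is zero.
    """
    if not (0 <= mut_insen <= n_insen and 0 <= mut_sen <= n_sen):
        raise ValueError("mutation counts must lie within group sizes")
    a, b = mut_insen, n_insen - mut_insen
    c, d = mut_sen, n_sen - mut_sen
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return GeneMutationStat(gene, mut_insen, mut_sen, n_insen, n_sen,
                            fisher_p=float(p), odds_ratio=float(odds))


def gene_stats(matrix: MutationMatrix) -> pd.DataFrame:
    """Per-gene mutation counts, Fisher p and odds ratio for one cohort."""
    y = matrix.y.astype(bool)
    n_insen = int(y.sum())
    n_sen = int((~y).sum())
    rows = []
    values = matrix.data.to_numpy()
    mut_insen = values[y].sum(axis=0)
    mut_sen = values[~y].sum(axis=0)
    for gene, mi, ms in zip(matrix.genes, mut_insen, mut_sen):
        st = fisher_gene_test(int(mi), n_insen, int(ms), n_sen, gene=gene)
        rows.append((st.gene, st.mut_insen, st.mut_sen, st.n_insen, st.n_sen,
                     st.fisher_p, st.odds_ratio))
    return pd.DataFrame(rows, columns=["gene", "mut_insen", "mut_sen", "n_insen",
                                       "n_sen", "fisher_p", "odds_ratio"])


def enrichment_filter(stats_table: pd.DataFrame, min_diff: int = 2,
                      p_max: float = 0.25) -> list[str]:
    """Candidate genes mutated preferentially in non-responders.

    Retains genes with ``mut_insen - mut_sen >= min_diff`` and Fisher
    ``p < p_max`` (strict).  Output is sorted by gene id, so it is
    invariant to the input row order.
    """
    if len(stats_table) == 0:
        return []
    diff = stats_table["mut_insen"] - stats_table["mut_sen"]
    keep = (diff >= min_diff) & (stats_table["fisher_p"] < p_max)
    return sorted(stats_table.loc[keep, "gene"].astype(str))
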