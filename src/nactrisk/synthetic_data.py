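"""Synthetic cohorts and screens with the structure the pipeline assumes.

The study's patient-level data are not public, so every downstream stage
is exercised on simulated inputs: sparse binary mutation matrices in
which a planted set of "resistance" genes is mutated preferentially in
non-responders (the cohorts default to the study shapes, 30/26 training
and 22/80 validation), and negative-binomial sgRNA count matrices with a
planted enriched-gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crispr_screen import CONTROL, COLUMN_LEVELS, ScreenCounts
from .mutation_enrichment import MutationMatrix, NON_RESPONDER, RESPONDER

CLINICAL_COLUMNS = ("sample", "response", "cohort", "age", "stage",
                    "differentiation", "scc_ag")

_STAGES = ("IB1", "IB2", "IIA", "IIB")
_DIFFERENTIATION = ("well", "moderate", "poor")


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n_genes + 1)]


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    ``causal_genes`` lists (gene id, mutation probability in
    non-responders, probability in responders); every other gene uses
    ``background_rate`` in both groups.  ``clinical_effects`` optionally
    tilts covariates by a per-covariate log-odds on non-response.
    """

    n_nonresponder: int = 30
    n_responder: int = 26
    n_genes: int = 744
    causal_genes: list[tuple[str, float, float]] = field(default_factory=list)
    background_rate: float = 0.03
    clinical_effects: dict[str, float] | None = None
    pairwise_correlation: float = 0.0  # optional knob for the pruning stages
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonresponder < 1 or self.n_responder < 1:
            raise ValueError("both groups need at least one sample")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        universe = set(gene_universe(self.n_genes))
        for gene, p_insen, p_sen in self.causal_genes:
            if gene not in universe:
                raise ValueError(f"causal gene {gene!r} outside the gene universe")
            if not (0.0 <= p_insen <= 1.0 and 0.0 <= p_sen <= 1.0):
                raise ValueError(f"causal probabilities for {gene!r} must be in [0, 1]")
        if not 0.0 <= self.pairwise_correlation < 1.0:
            raise ValueError("pairwise_correlation must be in [0, 1)")


def generate_cohort(spec: CohortSpec, cohort: str = "training"
                    ) -> tuple[MutationMatrix, pd.DataFrame]:
    """Draw one cohort: binary mutation matrix plus clinical table.

    Entries are independent Bernoulli draws; causal genes use their
    group-specific probabilities, all others the background rate.  When
    ``pairwise_correlation`` > 0, consecutive causal-gene pairs share
    events with that probability so that the Spearman pruning stages have
    something to remove.  A fixed seed fixes all outputs bit-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_universe(spec.n_genes)
    n = spec.n_nonresponder + spec.n_responder
    labels = np.array([NON_RESPONDER] * spec.n_nonresponder
                      + [RESPONDER] * spec.n_responder)
    samples = ([f"NR{i:03d}" for i in range(1, spec.n_nonresponder + 1)]
               + [f"R{i:03d}" for i in range(1, spec.n_responder + 1)])

    probs = np.full((n, spec.n_genes), spec.background_rate)
    causal_idx: dict[str, int] = {}
    for gene, p_insen, p_sen in spec.causal_genes:
        j = genes.index(gene)
        causal_idx[gene] = j
        probs[:spec.n_nonresponder, j] = p_insen
        probs[spec.n_nonresponder:, j] = p_sen
    data = (rng.random((n, spec.n_genes)) < probs).astype(np.int8)

    if spec.pairwise_correlation > 0 and len(causal_idx) >= 2:
        idx = list(causal_idx.values())
        for a, b in zip(idx[::2], idx[1::2]):
            share = rng.random(n) < spec.pairwise_correlation
            data[share, b] = data[share, a]

    matrix = MutationMatrix(
        pd.DataFrame(data, index=pd.Index(samples, name="sample"), columns=genes),
        pd.Series(labels, index=samples, name="response"),
        pd.Series(cohort, index=samples, name="cohort"),
    )
    clinical = _clinical_table(spec, rng, samples, labels, cohort)
    return matrix, clinical


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _clinical_table(spec: CohortSpec, rng: np.random.Generator,
                    samples: list[str], labels: np.ndarray, cohort: str
                    ) -> pd.DataFrame:
    """Clinical covariates, optionally tilted toward non-response.

    Each effect is applied to a dichotomized latent (old age, advanced
    stage, poor differentiation, high SCC-ag): the probability of the
    "high" state is sigmoid(effect) for non-responders vs 0.5 for
    responders, so the stated value is the log-odds contrast.
    """
    effects = spec.clinical_effects or {}
    n = len(samples)
    is_nr = labels == NON_RESPONDER

    def high(name: str) -> np.ndarray:
        p = np.where(is_nr, _sigmoid(effects.get(name, 0.0)), 0.5)
        return rng.random(n) < p

    age = np.where(high("age"), rng.normal(58, 6, n), rng.normal(44, 5, n))
    age = np.clip(np.round(age), 25, 75).astype(int)
    stage = np.where(high("stage"),
                     rng.choice(_STAGES[2:], n), rng.choice(_STAGES[:2], n))
    diff = np.where(high("differentiation"), "poor",
                    rng.choice(_DIFFERENTIATION[:2], n))
    scc = np.exp(rng.normal(1.0, 0.8, n)) * np.where(high("scc_ag"), 2.5, 1.0)
    return pd.DataFrame({
        "sample": samples, "response": labels, "cohort": cohort,
        "age": age, "stage": stage, "differentiation": diff,
        "scc_ag": np.round(scc, 2),
    })


@dataclass
class ScreenSpec:
    """Parameters of one simulated CRISPR screen."""

    n_genes: int = 100
    sgrnas_per_gene: tuple[int, int] = (3, 6)
    enriched_genes: dict[str, float] = field(default_factory=dict)
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    n_experiments: int = 2
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("DDP", "Taxol", "DDP+Taxol")
    depth_sigma: float = 0.15  # lognormal column-depth variation
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sgrnas_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("sgrnas_per_gene must be a positive (lo, hi) range")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(fold <= 0 for fold in self.enriched_genes.values()):
            raise ValueError("enrichment folds must be > 0")
        universe = set(gene_universe(self.n_genes))
        missing = set(self.enriched_genes) - universe
        if missing:
            raise ValueError(f"enriched genes outside the universe: {sorted(missing)}")


def generate_screen(spec: ScreenSpec) -> ScreenCounts:
    """Draw negative-binomial sgRNA counts for control + treated arms.

    Treated-arm means for sgRNAs of enriched genes are multiplied by the
    gene's enrichment fold; per-column sequencing depth varies
    lognormally so that size-factor normalization is non-trivial.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_universe(spec.n_genes)
    lo, hi = spec.sgrnas_per_gene
    counts_per_gene = rng.integers(lo, hi + 1, size=spec.n_genes)
    sgrnas, gene_of = [], []
    for gene, k in zip(genes, counts_per_gene):
        for j in range(1, k + 1):
            sgrnas.append(f"{gene}_sg{j}")
            gene_of.append(gene)
    fold = np.array([spec.enriched_genes.get(g, 1.0) for g in gene_of])

    columns = [
        (cond, exp, rep)
        for cond in (CONTROL, *spec.conditions)
        for exp in range(1, spec.n_experiments + 1)
        for rep in range(1, spec.n_replicates + 1)
    ]
    mat = np.empty((len(sgrnas), len(columns)), dtype=np.int64)
    for j, (cond, _exp, _rep) in enumerate(columns):
        depth = np.exp(rng.normal(0.0, spec.depth_sigma))
        mu = np.full(len(sgrnas), spec.baseline_mean) * depth
        if cond != CONTROL:
            mu = mu * fold
        if spec.dispersion == 0:
            mat[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / spec.dispersion
            mat[:, j] = rng.negative_binomial(size, size / (size + mu))

    counts = pd.DataFrame(
        mat, index=pd.Index(sgrnas, name="sgrna"),
        columns=pd.MultiIndex.from_tuples(columns, names=COLUMN_LEVELS),
    )
    return ScreenCounts(counts, pd.Series(gene_of, index=counts.index, name="gene"))
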