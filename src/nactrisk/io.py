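"""TSV / JSON readers and writers for the pipeline's artifacts.

Dialect: tab-separated, UTF-8, mandatory header row, "." for missing
clinical values.  Matrices are written with the sample id in the first
column and one 0/1 column per gene; labels travel in a companion table
(sample, response, cohort, clinical covariates).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crispr_screen import ScreenCounts
from .model_build import RiskModel
from .mutation_enrichment import MutationMatrix

MISSING = "."


def write_mutation_matrix(matrix: MutationMatrix, matrix_path,
                          labels_path=None) -> None:
    out = matrix.data.copy()
    out.index.name = "sample"
    out.to_csv(matrix_path, sep="\t")
    if labels_path is not None:
        lab = pd.DataFrame({"sample": matrix.samples,
                            "response": matrix.labels.to_numpy()})
        if matrix.cohort is not None:
            lab["cohort"] = matrix.cohort.to_numpy()
        lab.to_csv(labels_path, sep="\t", index=False)


def read_mutation_matrix(matrix_path, labels_path=None) -> MutationMatrix:
    """Load a binary matrix TSV (+ optional labels TSV), validating cells.

    A cell outside {0, 1} raises an error naming its sample and gene.
    Without a labels file every sample is labeled ``responder`` so the
    matrix can still be scored.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary cell {values[i, j]!r} at sample {df.index[i]!r}, "
            f"gene {df.columns[j]!r}"
        )
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        labels = pd.Series(lab["response"].to_numpy(),
                           index=lab["sample"].to_numpy()).reindex(df.index)
        cohort = None
        if "cohort" in lab.columns:
            cohort = pd.Series(lab["cohort"].to_numpy(),
                               index=lab["sample"].to_numpy()).reindex(df.index)
    else:
        labels = pd.Series("responder", index=df.index)
        cohort = None
    return MutationMatrix(df, labels, cohort)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)


def write_screen_counts(screen: ScreenCounts, path) -> None:
    screen.to_long().to_csv(path, sep="\t", index=False)


def read_screen_counts(path) -> ScreenCounts:
    long = pd.read_csv(path, sep="\t")
    required = {"sgrna", "gene", "condition", "experiment", "replicate", "count"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"screen counts TSV missing columns: {sorted(missing)}")
    return ScreenCounts.from_long(long)


def write_gene_stats(stats_table: pd.DataFrame, path) -> None:
    stats_table.to_csv(path, sep="\t", index=False)


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def save_model(model: RiskModel, path) -> None:
    model.save(path)


def load_model(path) -> RiskModel:
    """Load a risk model JSON; a missing cutoff loads with scoring only."""
    raw = json.loads(Path(path).read_text())
    for key in ("intercept", "coefficients"):
        if key not in raw:
            raise ValueError(f"model JSON missing required field {key!r}")
    return RiskModel.from_dict(raw)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def provenance_block(seed: int, config: dict) -> dict:
    from . import __version__
    return {"tool": "nactrisk", "version": __version__,
            "seed": seed, "config_hash": config_hash(config)}
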