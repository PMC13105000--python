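"""Cytotoxic Immune Score (IS) and cell-type score ingestion.

The IS is a rank-sum statistic over seven cytotoxic-lymphocyte genes (CD247,
CD2, CD3E, GZMH, NKG7, PRF1, GZMK) that proxies CD8 T / NK infiltration in
bulk RNA-seq: each signature gene is ranked across samples within a cohort
(ascending, average ties), per-sample ranks are summed, and the sums are
re-ranked to give the final score. Bottom/top 30th percentiles of the score
define immune-cold and immune-hot classes. Because the score is purely
rank-based it is invariant to any per-gene strictly increasing transform of
expression, so it can be computed on TPM, RSEM, or log scale identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .data_io import ExpressionMatrix
from .errors import ConfigError, DataError

#: The seven-gene cytotoxic signature.
CYTOTOXIC_SIGNATURE = ("CD247", "CD2", "CD3E", "GZMH", "NKG7", "PRF1", "GZMK")

COLD, INTERMEDIATE, HOT = "cold", "intermediate", "hot"


@dataclass
class ImmuneScoreTable:
    """Per-sample IS rank and cold/intermediate/hot class.

    ``table`` has columns ``is_rank`` (tie-averaged rank in [1, n]) and
    ``is_class`` (one of cold/intermediate/hot; intermediate until
    :func:`binarize_immune_score` is applied). Percentile cutoffs and the
    boundary rule used for classification are recorded in ``metadata``.
    """

    table: pd.DataFrame
    signature_genes: tuple
    metadata: dict = field(default_factory=dict)

    @property
    def is_rank(self) -> pd.Series:
        return self.table["is_rank"]

    @property
    def is_class(self) -> pd.Series:
        return self.table["is_class"]


@dataclass
class CellTypeScoreTable:
    """Samples x cell types matrix of non-negative enrichment scores."""

    scores: pd.DataFrame

    def __post_init__(self):
        if (self.scores.to_numpy(dtype=float) < 0).any():
            raise DataError("cell-type enrichment scores must be non-negative")


#: Canonical cell-type vocabulary used by the cell-type regression models.
CELL_TYPES = (
    "cd8_t", "cd4_t", "b_cell", "nk", "anti_tumor_macrophage",
    "pro_tumor_macrophage", "dendritic", "neutrophil", "fibroblast",
    "endothelial",
)

#: Default alias map translating common xCell output labels.
CELL_TYPE_ALIASES = {
    "CD8+ T-cells": "cd8_t",
    "CD8 T": "cd8_t",
    "CD4+ T-cells": "cd4_t",
    "CD4 T": "cd4_t",
    "B-cells": "b_cell",
    "B": "b_cell",
    "NK cells": "nk",
    "NK": "nk",
    "Macrophages M1": "anti_tumor_macrophage",
    "M1": "anti_tumor_macrophage",
    "Macrophages M2": "pro_tumor_macrophage",
    "M2": "pro_tumor_macrophage",
    "DC": "dendritic",
    "Dendritic cells": "dendritic",
    "Neutrophils": "neutrophil",
    "Fibroblasts": "fibroblast",
    "Endothelial cells": "endothelial",
}


def cytotoxic_immune_score(
    expr: ExpressionMatrix,
    signature=CYTOTOXIC_SIGNATURE,
    min_genes: int | None = None,
) -> ImmuneScoreTable:
    """Compute the rank-sum cytotoxic Immune Score.

    Ranks ascend with expression (higher expression -> higher rank -> hotter).
    Ties are averaged at both ranking stages. By default all signature genes
    must be present; ``min_genes`` relaxes this to a minimum count.
    """
    if len(expr.sample_ids) < 2:
        raise DataError("immune score requires at least 2 samples")
    signature = tuple(signature)
    if min_genes is None:
        min_genes = len(signature)
    present = [g for g in signature if g in expr.values.columns]
    missing = [g for g in signature if g not in expr.values.columns]
    if len(present) < min_genes:
        raise DataError(
            f"missing signature genes beyond tolerance "
            f"(need >= {min_genes}, have {len(present)}): missing {missing}"
        )
    sub = expr.values[present]
    per_gene_ranks = sub.rank(axis=0, method="average", ascending=True)
    rank_sums = per_gene_ranks.sum(axis=1)
    is_rank = rank_sums.rank(method="average", ascending=True)
    table = pd.DataFrame(
        {"is_rank": is_rank, "is_class": INTERMEDIATE}, index=expr.values.index
    )
    return ImmuneScoreTable(
        table=table,
        signature_genes=tuple(present),
        metadata={"missing_signature_genes": missing,
                  "rank_direction": "ascending (higher expression = hotter)"},
    )


def binarize_immune_score(
    scores: ImmuneScoreTable, low_pct: float = 30, high_pct: float = 30
) -> ImmuneScoreTable:
    """Assign cold/intermediate/hot classes by IS percentile.

    With n samples, the bottom ``ceil(low_pct/100 * n)`` ranks are cold and
    the top ``ceil(high_pct/100 * n)`` ranks are hot (ceil boundary rule).
    Tie-averaged ranks that fall strictly between the cutoffs stay
    intermediate, so a fully tied cohort is entirely intermediate.
    """
    if low_pct + high_pct >= 100:
        raise ConfigError(
            f"low_pct + high_pct must be < 100 (got {low_pct} + {high_pct})"
        )
    n = len(scores.table)
    if n < 4:
        raise DataError("binarization requires at least 4 samples")
    n_cold = math.ceil(low_pct / 100.0 * n)
    n_hot = math.ceil(high_pct / 100.0 * n)
    rank = scores.table["is_rank"]
    cls = pd.Series(INTERMEDIATE, index=rank.index, dtype=object)
    cls[rank <= n_cold] = COLD
    cls[rank >= n - n_hot + 1] = HOT
    table = scores.table.copy()
    table["is_class"] = cls
    meta = dict(scores.metadata)
    meta.update({
        "low_pct": low_pct, "high_pct": high_pct,
        "boundary_rule": "ceil counts; rank <= ceil(low*n) cold, "
                         "rank >= n - ceil(high*n) + 1 hot",
    })
    return ImmuneScoreTable(table=table, signature_genes=scores.signature_genes,
                            metadata=meta)


def load_celltype_scores(
    path, vocabulary=CELL_TYPES, aliases=None, allow_unknown: bool = False
) -> CellTypeScoreTable:
    """Load an xCell-style sample x cell-type score TSV.

    The file may be oriented either way; the orientation with cell types on
    the axis whose labels resolve against the vocabulary wins. Cell-type
    labels are normalized through the alias map; unknown cell types are an
    error unless ``allow_unknown`` (then they are dropped).
    """
    alias_map = dict(CELL_TYPE_ALIASES)
    if aliases:
        alias_map.update(aliases)
    df = pd.read_csv(path, sep="\t", index_col=0)

    def resolve(labels):
        return [alias_map.get(str(c), str(c)) for c in labels]

    col_hits = sum(c in vocabulary for c in resolve(df.columns))
    row_hits = sum(c in vocabulary for c in resolve(df.index))
    if row_hits > col_hits:
        df = df.T
    df.columns = resolve(df.columns)
    unknown = [c for c in df.columns if c not in vocabulary]
    if unknown and not allow_unknown:
        raise DataError(
            f"unknown cell type(s) without alias: {sorted(set(unknown))[:5]}"
        )
    df = df[[c for c in df.columns if c in vocabulary]]
    return CellTypeScoreTable(scores=df.astype(float))
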