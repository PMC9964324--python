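"""Gene-set potential indices: CPI, FPI and custom directional scores.

A potential index summarises, per sample, the balance between two opposing
transcriptional programmes. Each programme is scored by single-sample GSEA;
the raw index is the difference

    raw = ES(positive components) - ES(negative components)

and the reported index is that difference normalized across the samples of
the call (z-score by default). The cuproptosis potential index (CPI) ships
with a built-in component pair: positive components are the lipoylated
TCA-cycle / lipoic-acid pathway genes promoting copper-induced death
(PDX1, LIAS, LIPT1, DLD, DLAT, PDHA1, PDHB) and negative components are its
suppressors (MTF1, GLS, CDKN2A). The widely cited cuproptosis screen lists
FDX1 rather than PDX1 among the promoters; both variants are shipped as
gene-set data and the PDX1 list is the default. The ferroptosis potential
index (FPI) uses the same machinery with ferroptosis driver/suppressor sets
supplied as data (GMT), not code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from . import ssgsea
from .stats import significance_code, wilcoxon_rank_sum
from .types import ExpressionMatrix, GeneSet, GeneSetPair, SampleMetadata

log = logging.getLogger(__name__)

__all__ = [
    "IndexDefinition",
    "cpi_definition",
    "fpi_definition",
    "bundled_gene_sets",
    "compute_index",
    "compare_groups",
    "index_heatmap_table",
]

CPI_POSITIVE = ("PDX1", "LIAS", "LIPT1", "DLD", "DLAT", "PDHA1", "PDHB")
CPI_NEGATIVE = ("MTF1", "GLS", "CDKN2A")


@dataclass(frozen=True)
class IndexDefinition:
    """A named directional index: gene-set pair plus normalization choice."""

    name: str
    pair: GeneSetPair
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if self.normalization not in ("zscore", "minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def cpi_definition(normalization: str = "zscore") -> IndexDefinition:
    """The bundled cuproptosis potential index definition."""
    pair = GeneSetPair(
        name="CPI",
        positive=GeneSet("CPI_positive", frozenset(CPI_POSITIVE)),
        negative=GeneSet("CPI_negative", frozenset(CPI_NEGATIVE)),
    )
    return IndexDefinition(name="CPI", pair=pair, normalization=normalization)


def bundled_gene_sets() -> dict[str, GeneSet]:
    """Gene sets shipped with the package (GMT), keyed by set name."""
    from .io import read_gmt  # local import to avoid a cycle

    path = resources.files("ferrocup") / "data" / "index_components.gmt"
    with resources.as_file(path) as p:
        return {s.name: s for s in read_gmt(p)}


def fpi_definition(
    positive: GeneSet,
    negative: GeneSet | None,
    normalization: str = "zscore",
) -> IndexDefinition:
    """Build an FPI definition from user-supplied driver/suppressor sets.

    Ferroptosis driver/suppressor memberships are curation-dependent, so the
    FPI ships as configuration (GMT input), not as a hard-coded list.
    """
    pair = GeneSetPair(name="FPI", positive=positive, negative=negative)
    return IndexDefinition(name="FPI", pair=pair, normalization=normalization)


def compute_index(
    expr: ExpressionMatrix,
    defn: IndexDefinition,
    alpha: float = ssgsea.DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-sample index values.

    Returns a frame with columns ``sample_id``, ``raw_difference``
    (ES_pos - ES_neg) and ``index_value`` (normalized across the samples of
    this call). Normalization is deliberately local to the call: score each
    cell line's treated+control panel together to mirror per-line analyses.
    """
    pos, neg = defn.pair.positive, defn.pair.negative
    if not pos.present_in(expr):
        raise ValueError(
            f"no positive-component genes of {defn.name!r} present; "
            f"missing: {sorted(pos.genes)}"
        )
    sets = [pos] + ([neg] if neg is not None and neg.present_in(expr) else [])
    if neg is not None and not neg.present_in(expr):
        raise ValueError(
            f"no negative-component genes of {defn.name!r} present; "
            f"missing: {sorted(neg.genes)}"
        )
    table = ssgsea.ssgsea_scores(expr, sets, alpha=alpha)
    wide = table.pivot(index="sample_id", columns="gene_set", values="es")
    wide = wide.loc[expr.sample_ids]  # preserve sample order
    raw = wide[pos.name] - (wide[neg.name] if neg is not None else 0.0)
    raw = raw.to_numpy(dtype=float)
    if defn.normalization == "zscore":
        sd = raw.std(ddof=1) if raw.size > 1 else 0.0
        index_value = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    elif defn.normalization == "minmax":
        span = raw.max() - raw.min()
        index_value = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    else:
        index_value = raw.copy()
    return pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "raw_difference": raw,
            "index_value": index_value,
        }
    )


def compare_groups(
    results: pd.DataFrame,
    meta: SampleMetadata,
    by: str = "treatment",
    value_col: str = "index_value",
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum comparison of index values.

    One row per group pair with the rank-sum statistic, p-value and a
    significance code (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
    """
    labels = meta.column(by).reindex(results["sample_id"])
    if labels.isna().any():
        missing = list(results.loc[labels.isna().to_numpy(), "sample_id"])
        raise ValueError(f"samples missing metadata label {by!r}: {missing[:5]}")
    values = results[value_col].to_numpy(dtype=float)
    groups = {
        level: values[(labels == level).to_numpy()]
        for level in pd.unique(labels)
    }
    for level, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {level!r} has fewer than 2 samples")
    rows = []
    for a, b in combinations(groups, 2):
        res = wilcoxon_rank_sum(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": groups[a].size,
                "n_b": groups[b].size,
                "statistic": res.statistic,
                "p": res.p,
                "significance": significance_code(res.p),
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def index_heatmap_table(
    expr: ExpressionMatrix,
    defn: IndexDefinition,
) -> tuple[pd.DataFrame, list[str]]:
    """Row-standardized expression of the index's component genes.

    Returns (table, absent_genes): the table holds one row per component gene
    present in the matrix with a ``component`` column (positive/negative) and
    z-scored expression across samples; ``absent_genes`` lists components not
    found in the matrix.
    """
    pos, neg = defn.pair.positive, defn.pair.negative
    members = [(g, "positive") for g in pos.present_in(expr)]
    if neg is not None:
        members += [(g, "negative") for g in neg.present_in(expr)]
    if not members:
        raise ValueError(f"no component genes of {defn.name!r} present")
    absent = sorted(
        (pos.genes | (neg.genes if neg is not None else frozenset()))
        - set(expr.gene_ids)
    )
    if absent:
        log.warning("%d component genes absent from matrix: %s", len(absent), absent)
    sub = expr.subset_genes([g for g, _ in members])
    vals = sub.values
    centered = vals - vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    table = pd.DataFrame(z, index=sub.gene_ids, columns=sub.sample_ids)
    table.insert(0, "component", [c for _, c in members])
    table.insert(0, "gene_id", [g for g, _ in members])
    return table.reset_index(drop=True), absent
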