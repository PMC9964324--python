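"""Per-cell potential-index scoring and subcluster comparison.

Counts are library-size normalized to CPM and log2(1 + x) transformed per
cell before ranking — a minimal, rank-preserving transform, so the per-cell
enrichment scores are invariant to each cell's sequencing depth. Indices are
then computed per cell exactly as for bulk samples, normalized jointly
across all cells of the call, and summarized per subcluster with a
Kruskal-Wallis omnibus test followed (when the omnibus rejects at 0.05) by
BH-adjusted pairwise Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import ssgsea
from .indices import IndexDefinition, compute_index
from .stats import bh_adjust, kruskal_wallis, significance_code, wilcoxon_rank_sum
from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)

__all__ = ["SubclusterIndexSummary", "score_cells", "compare_subclusters"]

OMNIBUS_ALPHA = 0.05
MIN_CELLS = 3


@dataclass
class SubclusterIndexSummary:
    """Per-subcluster medians with omnibus and pairwise significance."""

    summary: pd.DataFrame  # subcluster, n_cells, median, iqr
    omnibus_h: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p, p_adj, significance (may be empty)


def normalize_counts(expr: ExpressionMatrix) -> ExpressionMatrix:
    """CPM + log2(1+x) per cell; drops zero-count cells with a warning."""
    if expr.mode != "counts":
        raise ValueError("count normalization requires counts mode")
    totals = expr.values.sum(axis=0)
    keep = totals > 0
    if not keep.any():
        raise ValueError("every cell has zero total count")
    if not keep.all():
        dropped = [s for s, k in zip(expr.sample_ids, keep) if not k]
        log.warning("dropping %d zero-count cells: %s", len(dropped), dropped[:5])
    vals = expr.values[:, keep]
    cpm = vals / vals.sum(axis=0, keepdims=True) * 1e6
    logged = np.log2(1.0 + cpm)
    return ExpressionMatrix(
        logged,
        list(expr.gene_ids),
        [s for s, k in zip(expr.sample_ids, keep) if k],
        mode="log_intensity",
    )


def score_cells(
    expr: ExpressionMatrix,
    defn: IndexDefinition,
    alpha: float = ssgsea.DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-cell index values on a counts-mode matrix (jointly normalized)."""
    if expr.n_genes == 0 or expr.n_samples == 0:
        raise ValueError("empty expression matrix")
    logged = normalize_counts(expr)
    return compute_index(logged, defn, alpha=alpha)


def compare_subclusters(
    results: pd.DataFrame,
    meta: SampleMetadata,
    label: str = "subcluster",
    value_col: str = "index_value",
) -> SubclusterIndexSummary:
    """Summarize index values per subcluster and test for differences.

    Subclusters with fewer than 3 cells are excluded with a warning. The
    pairwise table is filled only when the Kruskal-Wallis omnibus rejects at
    0.05; BH adjustment spans all pairs jointly.
    """
    labels = meta.column(label).reindex(results["sample_id"])
    values = results[value_col].to_numpy(dtype=float)
    groups: dict[str, np.ndarray] = {}
    for level in sorted(pd.unique(labels.dropna())):
        vals = values[(labels == level).to_numpy()]
        if vals.size < MIN_CELLS:
            log.warning("subcluster %r has %d < %d cells; excluded", level, vals.size, MIN_CELLS)
            continue
        groups[level] = vals
    if len(groups) < 2:
        raise ValueError("need >=2 subclusters with >=3 cells each")

    summary = pd.DataFrame(
        {
            "subcluster": list(groups),
            "n_cells": [g.size for g in groups.values()],
            "median": [float(np.median(g)) for g in groups.values()],
            "iqr": [
                float(np.percentile(g, 75) - np.percentile(g, 25))
                for g in groups.values()
            ],
        }
    )
    omni = kruskal_wallis(list(groups.values()))
    pair_rows = []
    if omni.p < OMNIBUS_ALPHA:
        pairs = list(combinations(groups, 2))
        raw = [wilcoxon_rank_sum(groups[a], groups[b]).p for a, b in pairs]
        adj = bh_adjust(raw)
        for (a, b), p, pa in zip(pairs, raw, adj):
            pair_rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "p": p,
                    "p_adj": float(pa),
                    "significance": significance_code(float(pa)),
                }
            )
    pairwise = pd.DataFrame(
        pair_rows, columns=["group_a", "group_b", "p", "p_adj", "significance"]
    )
    return SubclusterIndexSummary(
        summary=summary,
        omnibus_h=omni.statistic,
        omnibus_p=omni.p,
        pairwise=pairwise,
    )
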