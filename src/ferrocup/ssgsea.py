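"""Single-sample GSEA enrichment scoring.

For each sample, genes are ranked by expression in descending order and given
absolute ranks r in {N, N-1, ..., 1} (highest expression gets N; ties broken
by lexicographic gene id so scores are platform-deterministic). For a gene
set S the enrichment score is the integrated difference between the weighted
in-set rank CDF and the uniform out-of-set CDF:

    ES(S) = sum_{i=1..N} [ P_in(i) - P_out(i) ]

    P_in(i)  = sum_{g in S, pos(g) <= i} r_g^alpha / sum_{g in S} r_g^alpha
    P_out(i) = |{g not in S, pos(g) <= i}| / (N - |S intersect matrix|)

with alpha >= 0 the rank-weighting exponent (default 0.25). Because the score
depends on expression only through within-sample ranks, it is invariant under
any strictly monotone transform of a sample's values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = ["ssgsea_scores", "normalize_scores", "enrichment_score_single"]

DEFAULT_ALPHA = 0.25


def _sample_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices that sort one sample's genes by descending expression,
    gene-id lexicographic order breaking ties."""
    # lexsort keys: last key is primary
    return np.lexsort((gene_ids, -values))


def enrichment_score_single(
    values: np.ndarray,
    gene_ids: list[str] | np.ndarray,
    set_genes: set[str] | frozenset[str],
    alpha: float,
) -> float:
    """ES for one expression vector and one gene set (restricted to genes
    present in the vector). Used by the vectorised scorer; kept public for
    direct verification."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    values = np.asarray(values, dtype=float)
    n = values.size
    order = _sample_order(values, gene_ids)
    in_set = np.isin(gene_ids[order], list(set_genes))
    m = int(in_set.sum())
    if m == 0 or m == n:
        raise ValueError("gene set must hit some but not all matrix genes")
    ranks = np.arange(n, 0, -1, dtype=float)  # position 0 holds rank N
    w = ranks**alpha
    p_in = np.cumsum(np.where(in_set, w, 0.0)) / np.sum(w[in_set])
    p_out = np.cumsum(~in_set) / (n - m)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: list[GeneSet],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Score every (gene set, sample) pair.

    Returns a long-format frame with columns ``gene_set``, ``sample_id``,
    ``es`` and ``n_set_genes_present``. Sets with no gene present in the
    matrix are dropped with a warning.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    n = expr.n_genes
    scored_sets: list[tuple[GeneSet, np.ndarray]] = []
    for s in sets:
        mask = np.isin(gene_ids, list(s.genes))
        m = int(mask.sum())
        if m == 0:
            log.warning("gene set %r has no genes in the matrix; dropped", s.name)
            continue
        if m == n:
            raise ValueError(f"gene set {s.name!r} covers every matrix gene")
        scored_sets.append((s, mask))
    rows = []
    ranks = np.arange(n, 0, -1, dtype=float)
    w_all = ranks**alpha
    for j, sample in enumerate(expr.sample_ids):
        col = expr.values[:, j]
        if np.ptp(col) == 0:
            log.warning("sample %r has all-equal expression; tie rule applies", sample)
        order = _sample_order(col, gene_ids)
        for s, mask in scored_sets:
            in_set = mask[order]
            m = int(in_set.sum())
            p_in = np.cumsum(np.where(in_set, w_all, 0.0)) / np.sum(w_all[in_set])
            p_out = np.cumsum(~in_set) / (n - m)
            rows.append((s.name, sample, float(np.sum(p_in - p_out)), m))
    return pd.DataFrame(rows, columns=["gene_set", "sample_id", "es", "n_set_genes_present"])


def normalize_scores(table: pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Normalize ES values per gene set across samples.

    ``zscore``: (es - mean)/sd; ``minmax``: (es - min)/(max - min);
    ``none``: identity. Zero-variance sets normalize to all zeros (logged).
    """
    if method == "none":
        return table.copy()
    if method not in ("zscore", "minmax"):
        raise ValueError(f"unknown normalization method {method!r}")
    out = table.copy()

    def _norm(es: pd.Series) -> pd.Series:
        if method == "zscore":
            sd = es.std(ddof=1) if len(es) > 1 else 0.0
            if not sd or np.isnan(sd):
                log.warning("zero-variance gene set; normalized scores set to 0")
                return es * 0.0
            return (es - es.mean()) / sd
        span = es.max() - es.min()
        if span == 0:
            log.warning("zero-variance gene set; normalized scores set to 0")
            return es * 0.0
        return (es - es.min()) / span

    out["es"] = out.groupby("gene_set", sort=False)["es"].transform(_norm)
    return out
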