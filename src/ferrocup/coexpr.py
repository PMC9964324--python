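"""Weighted co-expression network modules: soft threshold, TOM, detection.

The network is unsigned: adjacency a_ij = |cor(g_i, g_j)|^beta with beta a
positive soft-thresholding power chosen so the connectivity distribution is
approximately scale-free (default target R^2 = 0.85; the reference analysis
this pipeline mirrors used beta = 21). Similarity between genes is the
topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

modules come from average-linkage hierarchical clustering of 1 - TOM with a
static height cut, small clusters fall into the unassigned "grey" label, and
modules whose eigengenes (first principal component of the standardized
module submatrix) are highly correlated are merged iteratively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stats import pearson_test
from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)

__all__ = [
    "ModuleDetectionParams",
    "ScaleFreeFit",
    "ModuleAssignment",
    "adjacency_matrix",
    "topological_overlap",
    "pick_soft_threshold",
    "detect_modules",
    "module_trait",
]

GREY = "grey"


@dataclass
class ModuleDetectionParams:
    """Parameters of module detection.

    ``tree_cut_height`` places the static dendrogram cut at that relative
    position between the lowest and highest merge heights (a stand-in for
    dynamic tree cutting; see docs). The default 0.6 separates planted
    modules from background across a wide range of soft powers.
    """

    beta: int = 21
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    tree_cut_height: float = 0.6
    network_type: str = "unsigned"

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be a positive integer")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must lie in (0, 1)")
        if not 0.0 < self.tree_cut_height < 1.0:
            raise ValueError("tree_cut_height must lie in (0, 1)")
        if self.network_type != "unsigned":
            raise ValueError("only unsigned networks are implemented")


@dataclass
class ScaleFreeFit:
    beta_candidates: list[int]
    r_squared: list[float]
    mean_connectivity: list[float]
    selected_beta: int
    target_met: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta_candidates,
                "r_squared": self.r_squared,
                "mean_connectivity": self.mean_connectivity,
                "selected": [b == self.selected_beta for b in self.beta_candidates],
            }
        )


@dataclass
class ModuleAssignment:
    """gene -> module label map with eigengenes and module sizes."""

    labels: dict[str, str]
    eigengenes: pd.DataFrame  # samples x modules (unit-norm columns)
    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            self.sizes = dict(pd.Series(list(self.labels.values())).value_counts())

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.labels), "module": list(self.labels.values())}
        )


def _drop_constant_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    sd = expr.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d constant genes before correlation", (~keep).sum())
        kept = [g for g, k in zip(expr.gene_ids, keep) if k]
        return expr.subset_genes(kept)
    return expr


def adjacency_matrix(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    corr = np.corrcoef(expr.values)
    corr = np.clip(np.abs(corr), 0.0, 1.0)
    adj = corr**beta
    np.fill_diagonal(adj, 0.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM similarity from an adjacency matrix with zero diagonal."""
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1)
    shared = a @ a  # diag(a)=0 excludes the i and j terms automatically
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Goodness of the scale-free law p(k) ~ k^-gamma.

    R^2 of log10(density) on log10(mean k) over equal-count connectivity
    bins, where density is the bin's probability mass divided by its width
    (equal-count bins carry identical mass, so the width is what varies).
    Counted only when the fitted slope is negative, as scale-free degree
    distributions decay."""
    k = connectivity[connectivity > 0]
    if k.size < 2 * n_bins:
        return 0.0
    edges = np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return 0.0
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = (counts > 0) & (widths > 0) & (mids > 0)
    if keep.sum() < 3:
        return 0.0
    xs = np.log10(mids[keep])
    ys = np.log10(counts[keep] / (k.size * widths[keep]))
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0
    slope, _ = np.polyfit(xs, ys, 1)
    if slope >= 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return 0.0 if np.isnan(r) else float(r**2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidates: list[int] | None = None,
    target_r2: float = 0.85,
    n_bins: int = 10,
) -> ScaleFreeFit:
    """Scale-free topology fit over candidate powers.

    Selects the smallest power whose fit R^2 reaches ``target_r2``; if none
    does, falls back to the argmax with ``target_met=False``.
    """
    if candidates is None:
        candidates = list(range(1, 21)) + [21]
    if not candidates:
        raise ValueError("no candidate powers supplied")
    if expr.n_samples < 4:
        raise ValueError("need >=4 samples for a meaningful correlation network")
    expr = _drop_constant_genes(expr)
    corr = np.clip(np.abs(np.corrcoef(expr.values)), 0.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    r2s, ks = [], []
    for beta in candidates:
        adj = corr**beta
        k = adj.sum(axis=1)
        r2s.append(_scale_free_r2(k, n_bins=n_bins))
        ks.append(float(k.mean()))
    meeting = [b for b, r2 in zip(candidates, r2s) if r2 >= target_r2]
    if meeting:
        selected = min(meeting)
        target_met = True
    else:
        selected = candidates[int(np.argmax(r2s))]
        target_met = False
        log.warning(
            "no candidate power reached scale-free R^2 %.2f; falling back to "
            "beta=%d (R^2=%.3f)", target_r2, selected, max(r2s),
        )
    return ScaleFreeFit(list(candidates), r2s, ks, selected, target_met)


def _eigengene(values: np.ndarray) -> np.ndarray:
    """Unit-norm first right-singular vector of the gene-standardized
    submatrix, sign-fixed to correlate positively with mean expression."""
    centered = values - values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = values.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    return eig


def detect_modules(
    expr: ExpressionMatrix,
    params: ModuleDetectionParams | None = None,
) -> ModuleAssignment:
    """Detect co-expression modules; unassigned genes are labelled grey.

    Average-linkage clustering of 1 - TOM, static cut at the relative
    position ``tree_cut_height`` between the lowest and highest merge
    heights, minimum-size filter, then iterative merging of modules with
    eigengene correlation >= ``1 - merge_cut_height``.
    """
    params = params or ModuleDetectionParams()
    expr = _drop_constant_genes(expr)
    if expr.n_genes < params.min_module_size:
        raise ValueError("fewer genes than min_module_size")
    if expr.n_samples < 4:
        raise ValueError("need >=4 samples")
    adj = adjacency_matrix(expr, params.beta)
    tom = topological_overlap(adj)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    # guard tiny negative / asymmetric float noise before squareform
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    heights = link[:, 2]
    cut_height = float(
        heights.min() + params.tree_cut_height * (heights.max() - heights.min())
    )
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    genes = np.asarray(expr.gene_ids, dtype=object)
    labels = np.full(expr.n_genes, GREY, dtype=object)
    module_members: dict[str, np.ndarray] = {}
    next_id = 1
    # deterministic order: largest cluster first, ties by smallest raw id
    cluster_ids, counts = np.unique(raw, return_counts=True)
    for cid in cluster_ids[np.lexsort((cluster_ids, -counts))]:
        members = np.where(raw == cid)[0]
        if members.size < params.min_module_size:
            continue
        name = f"m{next_id}"
        next_id += 1
        labels[members] = name
        module_members[name] = members

    # iterative eigengene merging
    def eig_of(members: np.ndarray) -> np.ndarray:
        return _eigengene(expr.values[members, :])

    eigs = {name: eig_of(m) for name, m in module_members.items()}
    merge_threshold = 1.0 - params.merge_cut_height
    while len(module_members) > 1:
        names = sorted(module_members)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                r = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if r >= merge_threshold and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        merged = np.concatenate([module_members[a], module_members[b]])
        module_members[a] = merged
        eigs[a] = eig_of(merged)
        labels[module_members.pop(b)] = a
        eigs.pop(b)

    # relabel by size for stable output naming
    order = sorted(module_members, key=lambda n: (-module_members[n].size, n))
    final_labels: dict[str, str] = {g: GREY for g in genes}
    eig_frame = {}
    sizes: dict[str, int] = {}
    for rank, old in enumerate(order, start=1):
        name = f"m{rank}"
        members = module_members[old]
        for gi in members:
            final_labels[genes[gi]] = name
        eig_frame[name] = eigs[old]
        sizes[name] = int(members.size)
    sizes[GREY] = int(sum(1 for v in final_labels.values() if v == GREY))
    eigengenes = pd.DataFrame(eig_frame, index=expr.sample_ids)
    return ModuleAssignment(labels=final_labels, eigengenes=eigengenes, sizes=sizes)


def module_trait(
    assignment: ModuleAssignment,
    meta: SampleMetadata,
    traits: list[str],
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Binary (two-level string) traits are coded 0/1 in sorted level order.
    Constant traits yield r=0, p=1 with a ``degenerate`` flag.
    """
    if assignment.eigengenes.shape[0] < 3:
        raise ValueError("need >=3 samples for trait correlation")
    rows = []
    sample_ids = list(assignment.eigengenes.index)
    for trait in traits:
        series = meta.column(trait).reindex(sample_ids)
        if series.isna().any():
            raise ValueError(f"trait {trait!r} missing for some samples")
        try:
            vec = series.astype(float).to_numpy()
        except (TypeError, ValueError):
            levels = sorted(series.unique())
            if len(levels) != 2:
                raise ValueError(
                    f"categorical trait {trait!r} must have exactly 2 levels, "
                    f"got {levels}"
                ) from None
            vec = (series == levels[1]).to_numpy(dtype=float)
        for module in assignment.eigengenes.columns:
            res = pearson_test(assignment.eigengenes[module].to_numpy(), vec)
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "r": res.statistic,
                    "p": res.p,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)
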