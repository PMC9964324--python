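"""Empirical-Bayes moderated two-group differential expression.

Each cell line is analysed separately: within a line, curcumin samples are
contrasted against controls on the log2 scale. Gene-wise pooled variances are
shrunk toward a common prior estimated by the method of moments on the log
residual variances (digamma/trigamma matching), yielding the moderated t

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_mod     = log2fc / (s_tilde * sqrt(1/n1 + 1/n2))

with d0 + d degrees of freedom. Genes pass the DEG gate when
|log2 fold change| > 1 and the Benjamini-Hochberg adjusted p-value < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .stats import bh_adjust
from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)

__all__ = [
    "EBayesPrior",
    "estimate_prior",
    "moderated_t_test",
    "intersect_degs",
    "LFC_THRESHOLD",
    "ALPHA",
]

LFC_THRESHOLD = 1.0  # |log2 fold change| gate
ALPHA = 0.05  # BH-adjusted p gate


@dataclass(frozen=True)
class EBayesPrior:
    """Prior degrees of freedom and variance for the moderated t.

    ``d0 = inf`` collapses every moderated variance to ``s0_sq``.
    """

    d0: float
    s0_sq: float


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires positive input")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: int) -> EBayesPrior:
    """Method-of-moments fit of a scaled inverse-chi-square prior to the
    gene-wise residual variances ``s2`` with ``d`` residual df each.

    Falls back to ``d0 = inf`` (all variances shrunk fully to the common
    value) when the moment equation has no positive solution.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.mean(s2)) if s2.size else 1.0)
    z = np.log(positive)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.sum((e - e_mean) ** 2) / (e.size - 1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    try:
        d0 = 2.0 * _trigamma_inverse(excess)
    except (ValueError, FloatingPointError):
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    cell_line: str | None = None,
    treatment_col: str = "treatment",
    treated_level: str = "curcumin",
    control_level: str = "control",
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    prior: EBayesPrior | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression for one cell line.

    Returns one row per gene with columns ``gene_id``, ``log2fc`` (treated
    mean minus control mean), ``t_mod``, ``p``, ``p_adj``, ``is_deg`` and
    ``direction``. ``prior`` overrides the estimated empirical-Bayes prior
    (useful for the d0=0 / d0=inf limiting cases).
    """
    if expr.mode != "log_intensity":
        raise ValueError("differential expression requires log-intensity mode")
    conditions = {treatment_col: treated_level}
    if cell_line is not None:
        conditions["cell_line"] = cell_line
    treated = meta.samples_where(**conditions)
    conditions[treatment_col] = control_level
    control = meta.samples_where(**conditions)
    treated = [s for s in treated if s in expr.sample_ids]
    control = [s for s in control if s in expr.sample_ids]
    n1, n2 = len(treated), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >=2 samples per group, got {n1} treated / {n2} control"
            + (f" in cell line {cell_line!r}" if cell_line else "")
        )
    x1 = expr.subset_samples(treated).values
    x2 = expr.subset_samples(control).values
    d = n1 + n2 - 2
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ss1 + ss2) / d

    if prior is None:
        prior = estimate_prior(s2, d)
    if np.isinf(prior.d0):
        s2_tilde = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * sps.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    zero_var = (ss1 == 0) & (ss2 == 0)
    if zero_var.any():
        log.warning("%d genes with zero variance in both groups: p set to 1", zero_var.sum())
        p = np.where(zero_var, 1.0, p)
        t_mod = np.where(zero_var, 0.0, t_mod)

    p_adj = bh_adjust(p)
    is_deg = (np.abs(log2fc) > lfc_threshold) & (p_adj < alpha)
    direction = np.where(is_deg & (log2fc > 0), "up", np.where(is_deg, "down", "none"))
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "p": p,
            "p_adj": p_adj,
            "is_deg": is_deg,
            "direction": direction,
        }
    )


def intersect_degs(results: dict[str, pd.DataFrame]) -> list[str]:
    """Genes called DEG in every cell line, sorted lexicographically.

    Direction agreement is not required: membership alone decides, mirroring
    an overlap-of-lists comparison across cell lines.
    """
    if not results:
        raise ValueError("no differential-expression results supplied")
    sets = [
        set(frame.loc[frame["is_deg"], "gene_id"]) for frame in results.values()
    ]
    common = set.intersection(*sets)
    return sorted(common)
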