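"""Core in-memory containers shared by every stage of the pipeline.

The canonical substrate is a genes x samples :class:`ExpressionMatrix` in one
of two modes: ``log_intensity`` (bulk microarray-style log2 intensities) or
``counts`` (single-cell UMI counts). Gene identifiers are opaque,
case-sensitive strings; no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSet",
    "GeneSetPair",
    "SurvivalRecord",
]

MODES = ("log_intensity", "counts")


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with axis labels.

    Parameters
    ----------
    values
        2-D float array, genes in rows, samples in columns.
    gene_ids, sample_ids
        Unique ordered labels matching the matrix dimensions.
    mode
        ``"log_intensity"`` for logged bulk data, ``"counts"`` for
        non-negative single-cell counts.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    mode: str = "log_intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.mode == "counts" and (self.values < 0).any():
            raise ValueError("counts mode requires all values >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), list(sample_ids), self.mode
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx, :], list(gene_ids), list(self.sample_ids), self.mode
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: cell line, treatment arm and free-form labels.

    ``extra`` maps label name -> {sample_id -> value}; the single-cell stages
    use it to carry subcluster labels.
    """

    table: pd.DataFrame  # index = sample_id; columns include cell_line, treatment

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        self.table.index = self.table.index.astype(str)

    @classmethod
    def from_columns(
        cls,
        sample_ids: list[str],
        cell_line: list[str] | None = None,
        treatment: list[str] | None = None,
        **extra: list[str],
    ) -> "SampleMetadata":
        data: dict[str, list[str]] = {}
        if cell_line is not None:
            data["cell_line"] = cell_line
        if treatment is not None:
            data["treatment"] = treatment
        data.update(extra)
        return cls(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"metadata has no column {name!r}")
        return self.table[name]

    def samples_where(self, **conditions: str) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.column(col) == val
        return list(self.table.index[mask])


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, matrix: ExpressionMatrix) -> list[str]:
        """Member genes present in the matrix, in lexicographic order."""
        return sorted(self.genes.intersection(matrix.gene_ids))


@dataclass(frozen=True)
class GeneSetPair:
    """Directional gene-set pair defining a potential index.

    ``positive`` holds genes whose enrichment raises the index (e.g. the
    lipoylation-pathway promoters of cuproptosis), ``negative`` genes whose
    enrichment lowers it (cuproptosis suppressors).
    """

    name: str
    positive: GeneSet
    negative: GeneSet | None = None

    def __post_init__(self) -> None:
        if self.negative is not None and self.positive.genes & self.negative.genes:
            overlap = sorted(self.positive.genes & self.negative.genes)
            raise ValueError(
                f"positive and negative components of {self.name!r} overlap: {overlap}"
            )


@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored survival observation with a continuous covariate."""

    subject_id: str
    time: float
    event: bool
    covariate: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.subject_id!r}")
        if self.event not in (0, 1, True, False):
            raise ValueError("event indicator must be 0/1")
        object.__setattr__(self, "event", bool(self.event))
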