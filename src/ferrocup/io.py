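"""Readers and writers for the plain-text formats the pipeline consumes.

Dense expression matrices travel as TSV/CSV with genes in rows (first column
holds gene ids, header holds sample ids). Sparse single-cell matrices travel
as MatrixMarket triplets with two sidecar one-column name files. Gene sets use
the standard GMT layout (name, description, member genes, tab-separated).
Metadata and survival tables are TSVs with required named columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ExpressionMatrix, GeneSet, SampleMetadata, SurvivalRecord

log = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_mtx_expression",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "read_survival",
    "write_table",
    "read_table",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene id, the row with the highest mean."""
    if not frame.index.has_duplicates:
        return frame
    dupes = frame.index[frame.index.duplicated()].unique().tolist()
    log.warning("collapsing %d duplicated gene ids (keeping highest-mean row)", len(dupes))
    means = frame.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    deduped = frame.iloc[order]
    deduped = deduped[~deduped.index.duplicated(keep="first")]
    # restore first-occurrence file order
    return deduped.loc[frame.index.unique()]


def read_expression(
    path: str | Path,
    mode: str = "log_intensity",
    drop_missing: bool = False,
) -> ExpressionMatrix:
    """Load a dense genes x samples TSV/CSV into an :class:`ExpressionMatrix`.

    Duplicate gene ids are collapsed to the row with the highest mean. Missing
    values raise unless ``drop_missing`` is set, in which case genes with any
    missing value are dropped (and logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if frame.columns.size == 0:
        raise ValueError(f"{path}: no sample columns found (malformed header?)")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}"
                + (f", row {bad[0]!r}" if len(bad) else "")
            )
    frame.index = frame.index.astype(str)
    frame = _collapse_duplicate_genes(frame)
    if frame.isna().any().any():
        if drop_missing:
            n0 = len(frame)
            frame = frame.dropna(axis=0)
            log.warning("dropped %d genes with missing values", n0 - len(frame))
        else:
            bad = frame.index[frame.isna().any(axis=1)]
            raise ValueError(f"{path}: missing values in genes {list(bad[:5])}")
    return ExpressionMatrix(
        frame.to_numpy(dtype=float),
        list(frame.index),
        [str(c) for c in frame.columns],
        mode=mode,
    )


def read_mtx_expression(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    mode: str = "counts",
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Load a MatrixMarket triplet with one-column gene/sample name sidecars.

    ``genes_in_rows=False`` transposes cells x genes input into the canonical
    genes x samples orientation.
    """
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if not genes_in_rows:
        mat = mat.T
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    if mat.shape != (len(genes), len(samples)):
        raise ValueError(
            f"MTX shape {mat.shape} does not match sidecars: "
            f"{len(genes)} genes, {len(samples)} samples"
        )
    frame = _collapse_duplicate_genes(pd.DataFrame(mat, index=genes, columns=samples))
    return ExpressionMatrix(
        frame.to_numpy(), list(frame.index), list(frame.columns), mode=mode
    )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of gene sets, preserving file order."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
        name, _description, *genes = fields
        genes = [g for g in genes if g]
        if len(set(genes)) != len(genes):
            log.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
        sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV; requires a ``sample_id`` column."""
    table = pd.read_csv(path, sep=_sep_for(Path(path)), dtype=str)
    if "sample_id" not in table.columns:
        raise ValueError(f"{path}: metadata requires a 'sample_id' column")
    return SampleMetadata(table.set_index("sample_id"))


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read survival records from a TSV with subject_id/time/event[/covariate]."""
    table = pd.read_csv(path, sep=_sep_for(Path(path)))
    required = {"subject_id", "time", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: survival table missing columns {sorted(missing)}")
    has_cov = "covariate" in table.columns
    return [
        SurvivalRecord(
            subject_id=str(row.subject_id),
            time=float(row.time),
            event=bool(int(row.event)),
            covariate=float(row.covariate) if has_cov else float("nan"),
        )
        for row in table.itertuples()
    ]


def write_table(result: pd.DataFrame | ExpressionMatrix, path: str | Path) -> None:
    """Write a tabular result as TSV: stable column order, header, 6 s.f. floats."""
    if isinstance(result, ExpressionMatrix):
        frame = result.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t", float_format="%.6g")
        return
    result.to_csv(path, sep="\t", float_format="%.6g", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
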