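"""End-to-end orchestration: one validated config runs every stage in order.

Stage order mirrors the analysis the pipeline packages: per-line
differential expression -> DEG intersection -> co-expression modules ->
potential indices with group comparisons; the survival screen and the
single-cell scoring run independently. Outputs are TSVs plus a JSON manifest
recording the config hash, the seed, and per-stage row counts, so a re-run
of the same config is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cells import compare_subclusters, score_cells
from .coexpr import ModuleDetectionParams, detect_modules, module_trait, pick_soft_threshold
from .diffexpr import moderated_t_test, intersect_degs
from .indices import (
    IndexDefinition,
    compare_groups,
    compute_index,
    cpi_definition,
    index_heatmap_table,
)
from .io import read_expression, read_gmt, read_metadata, read_survival, write_table
from .simulate import (
    BulkSimConfig,
    SingleCellSimConfig,
    SurvivalSimConfig,
    simulate_bulk,
    simulate_single_cell,
    simulate_survival,
)
from .survival import dichotomize_by_expression, km_fit, logrank_test
from .types import ExpressionMatrix, GeneSet, GeneSetPair, SampleMetadata

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_STAGE_KEYS = {
    "output_dir",
    "seed",
    "bulk",
    "single_cell",
    "survival",
    "diffexpr",
    "modules",
    "index",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``bulk``/``single_cell``/``survival`` each either point at input files
    (``expr``/``meta``/``records`` paths) or carry a ``synthetic`` block of
    generator parameters. Stage parameter blocks (``diffexpr``, ``modules``,
    ``index``) override stage defaults.
    """

    output_dir: str
    seed: int = 0
    bulk: dict = field(default_factory=dict)
    single_cell: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    diffexpr: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for block_name in ("bulk", "single_cell", "survival"):
            block = getattr(self, block_name)
            if block and "synthetic" not in block:
                for key in ("expr", "meta", "records"):
                    if key in block and not Path(block[key]).exists():
                        raise ValueError(
                            f"{block_name}.{key}: input path {block[key]!r} does not exist"
                        )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _STAGE_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ValueError("config requires output_dir")
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.from_dict(raw or {})


def _index_definition(cfg: PipelineConfig) -> IndexDefinition:
    block = dict(cfg.index)
    normalization = block.get("normalization", "zscore")
    name = block.get("name", "CPI")
    if "pos_gmt" in block:
        pos = read_gmt(block["pos_gmt"])[0]
        neg = read_gmt(block["neg_gmt"])[0] if "neg_gmt" in block else None
        return IndexDefinition(
            name=name,
            pair=GeneSetPair(name=name, positive=pos, negative=neg),
            normalization=normalization,
        )
    return cpi_definition(normalization=normalization)


def _load_bulk(cfg: PipelineConfig):
    block = cfg.bulk
    if "synthetic" in block:
        params = dict(block["synthetic"])
        params.setdefault("seed", cfg.seed)
        if "index_shift" in params:
            params["index_shift"] = {
                tuple(k.split("/")): tuple(v) for k, v in params["index_shift"].items()
            }
        if "planted_modules" in params:
            params["planted_modules"] = tuple(
                tuple(m) for m in params["planted_modules"]
            )
        if params.pop("cpi_components", False):
            params["index_pair"] = cpi_definition().pair
        sim = BulkSimConfig(**params)
        expr, meta, truth = simulate_bulk(sim)
        return expr, meta, truth
    expr = read_expression(block["expr"], mode="log_intensity")
    meta = read_metadata(block["meta"])
    return expr, meta, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, started: float, **counts: int) -> None:
        manifest["stages"][stage] = dict(counts)
        log.info("stage %s done in %.2fs: %s", stage, time.time() - started, counts)

    defn = _index_definition(cfg)

    if cfg.bulk:
        t0 = time.time()
        expr, meta, truth = _load_bulk(cfg)
        write_table(expr, out / "bulk_expression.tsv")
        meta_out = meta.table.reset_index()
        write_table(meta_out, out / "bulk_metadata.tsv")
        if truth is not None:
            write_table(
                pd.DataFrame(
                    {"gene_id": truth.de_genes,
                     "log2fc": [truth.de_log2fc[g] for g in truth.de_genes]}
                ),
                out / "bulk_truth_de.tsv",
            )
        record("bulk_input", t0, n_genes=expr.n_genes, n_samples=expr.n_samples)

        # differential expression per cell line + intersection
        t0 = time.time()
        de_kwargs = dict(cfg.diffexpr)
        lines = sorted(meta.column("cell_line").unique())
        de_results = {}
        for line in lines:
            res = moderated_t_test(expr, meta, cell_line=line, **de_kwargs)
            de_results[line] = res
            write_table(res, out / f"diffexpr_{line}.tsv")
        common = intersect_degs(de_results)
        write_table(pd.DataFrame({"gene_id": common}), out / "common_degs.tsv")
        record(
            "diffexpr", t0,
            n_lines=len(lines),
            n_common_degs=len(common),
            **{f"n_degs_{k}": int(v["is_deg"].sum()) for k, v in de_results.items()},
        )

        # co-expression modules + trait correlation
        t0 = time.time()
        mod_block = dict(cfg.modules)
        candidates = mod_block.pop("beta_candidates", None)
        fit = pick_soft_threshold(expr, candidates=candidates)
        params = ModuleDetectionParams(**{"beta": fit.selected_beta, **mod_block})
        assignment = detect_modules(expr, params)
        write_table(fit.to_frame(), out / "scale_free_fit.tsv")
        write_table(assignment.to_frame(), out / "module_assignment.tsv")
        eig = assignment.eigengenes.reset_index(names="sample_id")
        write_table(eig, out / "module_eigengenes.tsv")
        traits = module_trait(assignment, meta, ["treatment"])
        write_table(traits, out / "module_trait.tsv")
        record(
            "modules", t0,
            n_modules=len([m for m in assignment.sizes if m != "grey"]),
            n_grey=assignment.sizes.get("grey", 0),
        )

        # potential indices per cell line
        t0 = time.time()
        alpha = cfg.index.get("alpha", 0.25)
        all_idx, all_cmp = [], []
        for line in lines:
            samples = meta.samples_where(cell_line=line)
            sub = expr.subset_samples(samples)
            idx = compute_index(sub, defn, alpha=alpha)
            idx.insert(0, "cell_line", line)
            cmp_ = compare_groups(idx, meta, by="treatment")
            cmp_.insert(0, "cell_line", line)
            all_idx.append(idx)
            all_cmp.append(cmp_)
            heat, _absent = index_heatmap_table(sub, defn)
            write_table(heat, out / f"index_heatmap_{line}.tsv")
        write_table(pd.concat(all_idx, ignore_index=True), out / "index_values.tsv")
        write_table(pd.concat(all_cmp, ignore_index=True), out / "index_comparisons.tsv")
        record("indices", t0, n_samples=sum(len(i) for i in all_idx))

    if cfg.survival:
        t0 = time.time()
        block = cfg.survival
        if "synthetic" in block:
            params = dict(block["synthetic"])
            params.setdefault("seed", cfg.seed + 1)
            records = simulate_survival(SurvivalSimConfig(**params))
        else:
            records = read_survival(block["records"])
        groups = dichotomize_by_expression(records)
        curves = []
        for g in ("low", "high"):
            members = [r for r, gg in zip(records, groups) if gg == g]
            curve = km_fit(members, group=g)
            tab = curve.table.copy()
            tab.insert(0, "group", g)
            curves.append(tab)
        write_table(pd.concat(curves, ignore_index=True), out / "km_curves.tsv")
        lr = logrank_test(records, groups)
        write_table(
            pd.DataFrame(
                [{"chi_sq": lr.chi_sq, "p": lr.p, "df": lr.df, **{
                    f"n_{k}": v for k, v in lr.group_sizes.items()}}]
            ),
            out / "logrank.tsv",
        )
        record("survival", t0, n_subjects=len(records))

    if cfg.single_cell:
        t0 = time.time()
        block = cfg.single_cell
        if "synthetic" in block:
            params = dict(block["synthetic"])
            params.setdefault("seed", cfg.seed + 2)
            if "subcluster_shift" in params:
                params["subcluster_shift"] = {
                    k: tuple(v) for k, v in params["subcluster_shift"].items()
                }
            if params.pop("cpi_components", False):
                params["index_pair"] = cpi_definition().pair
            sc_expr, sc_meta, _truth = simulate_single_cell(
                SingleCellSimConfig(**params)
            )
        else:
            sc_expr = read_expression(block["expr"], mode="counts")
            sc_meta = read_metadata(block["meta"])
        alpha = cfg.index.get("alpha", 0.25)
        cell_idx = score_cells(sc_expr, defn, alpha=alpha)
        write_table(cell_idx, out / "cell_index_values.tsv")
        summary = compare_subclusters(cell_idx, sc_meta)
        write_table(summary.summary, out / "subcluster_summary.tsv")
        write_table(summary.pairwise, out / "subcluster_pairwise.tsv")
        write_table(
            pd.DataFrame(
                [{"omnibus_h": summary.omnibus_h, "omnibus_p": summary.omnibus_p}]
            ),
            out / "subcluster_omnibus.tsv",
        )
        record("single_cell", t0, n_cells=sc_expr.n_samples)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
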