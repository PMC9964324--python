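"""Per-cell CPI scoring with subcluster comparison.

Simulates a single-cell counts matrix with 8 malignant subclusters, one of
which carries a +2 SD shift on the positive CPI components, scores every
cell, and tests for differences across subclusters.
"""

import ferrocup as fc

pair = fc.cpi_definition().pair
cfg = fc.SingleCellSimConfig(
    n_genes=300,
    n_cells=400,
    n_subclusters=8,
    index_pair=pair,
    subcluster_shift={"SC03": (2.0, 0.0)},
    seed=9,
)
expr, meta, truth = fc.simulate_single_cell(cfg)

idx = fc.score_cells(expr, fc.cpi_definition())
summary = fc.compare_subclusters(idx, meta)
print(summary.summary.sort_values("median", ascending=False).to_string(index=False))
print(f"\nKruskal-Wallis omnibus: H={summary.omnibus_h:.1f}, p={summary.omnibus_p:.3g}")
sig = summary.pairwise[summary.pairwise["p_adj"] < 0.05]
print(f"significant pairs after BH: {len(sig)} of {len(summary.pairwise)}")
print("The shifted subcluster (SC03) tops the median per-cell CPI and drives "
      "the significant pairwise contrasts.")
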