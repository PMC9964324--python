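"""Compute the cuproptosis potential index (CPI) on a simulated study.

Simulates three HCC cell lines with treated/control triplicates where the
treated arms carry a +2 SD shift on the positive CPI components, scores each
line separately, and compares treated vs control per line and pooled.
"""

import pandas as pd

import ferrocup as fc

pair = fc.cpi_definition().pair
cfg = fc.BulkSimConfig(
    n_genes=400,
    index_pair=pair,
    index_shift={(line, "curcumin"): (2.0, 0.0) for line in ("PLC", "KMCH", "Huh7")},
    seed=42,
)
expr, meta, truth = fc.simulate_bulk(cfg)

per_line = []
for line in ("PLC", "KMCH", "Huh7"):
    sub = expr.subset_samples(meta.samples_where(cell_line=line))
    idx = fc.compute_index(sub, fc.cpi_definition())
    idx.insert(0, "cell_line", line)
    per_line.append(idx)
    means = idx.join(meta.table["treatment"], on="sample_id").groupby("treatment")[
        "index_value"
    ].mean()
    print(f"{line}: mean CPI control={means['control']:+.2f} "
          f"curcumin={means['curcumin']:+.2f}")

pooled = pd.concat(per_line, ignore_index=True)
cmp_ = fc.compare_groups(pooled, meta, by="treatment")
row = cmp_.iloc[0]
print(
    f"\npooled treated-vs-control rank-sum: p={row.p:.4g} ({row.significance}) — "
    "the planted positive-component shift raises the treated CPI."
)
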