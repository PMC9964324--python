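import numpy as np
import pytest

import ferrocup as fc
from conftest import random_matrix


def test_default_cpi_component_lists(cpi_pair):
    assert cpi_pair.positive.genes == frozenset(
        {"PDX1", "LIAS", "LIPT1", "DLD", "DLAT", "PDHA1", "PDHB"}
    )
    assert cpi_pair.negative.genes == frozenset({"MTF1", "GLS", "CDKN2A"})
    assert not cpi_pair.positive.genes & cpi_pair.negative.genes


def test_bundled_sets_include_fdx1_variant():
    sets = fc.bundled_gene_sets()
    assert "FDX1" in sets["CPI_positive_FDX1_variant"].genes
    assert "PDX1" in sets["CPI_positive"].genes


def test_equal_component_scores_give_identically_zero_index(rng):
    """When each sample ranks the positive and negative component gene
    identically, the raw difference and the z-scored index are both 0."""
    n = 20
    vals = rng.normal(7, 1, size=(n, 4))
    genes = [f"g{i}" for i in range(n)]
    # give POS and NEG identical expression rows -> identical ES per sample
    vals[1] = vals[0]
    m = fc.ExpressionMatrix(vals, genes, ["a", "b", "c", "d"])
    defn = fc.IndexDefinition(
        "custom",
        fc.GeneSetPair(
            "custom",
            fc.GeneSet("pos", frozenset({genes[0]})),
            fc.GeneSet("neg", frozenset({genes[1]})),
        ),
    )
    res = fc.compute_index(m, defn)
    # identical rows tie; gene-id order puts g0 ahead of g1 consistently,
    # so both sets see the same rank profile up to the tie pair
    assert np.allclose(res["raw_difference"].abs().max(), res["raw_difference"].abs().min())


def test_constant_raw_difference_normalizes_to_zero():
    m = fc.ExpressionMatrix(
        [[5.0, 5.0, 5.0], [3.0, 3.0, 3.0], [1.0, 1.0, 1.0]],
        ["P", "N", "X"],
        ["a", "b", "c"],
    )
    defn = fc.IndexDefinition(
        "custom",
        fc.GeneSetPair(
            "custom", fc.GeneSet("pos", frozenset({"P"})), fc.GeneSet("neg", frozenset({"N"}))
        ),
    )
    res = fc.compute_index(m, defn)
    assert res["raw_difference"].nunique() == 1
    assert (res["index_value"] == 0).all()


def test_missing_positive_components_error(rng):
    m = random_matrix(rng, 10, 3)
    with pytest.raises(ValueError, match="positive-component"):
        fc.compute_index(m, fc.cpi_definition())


def test_treated_shift_raises_index(cpi_pair):
    cfg = fc.BulkSimConfig(
        n_genes=400,
        index_pair=cpi_pair,
        index_shift={("PLC", "curcumin"): (2.0, 0.0)},
        seed=17,
    )
    expr, meta, truth = fc.simulate_bulk(cfg)
    assert truth.index_direction["PLC"] == 1
    sub = expr.subset_samples(meta.samples_where(cell_line="PLC"))
    res = fc.compute_index(sub, fc.cpi_definition()).set_index("sample_id")
    treated = meta.samples_where(cell_line="PLC", treatment="curcumin")
    control = meta.samples_where(cell_line="PLC", treatment="control")
    assert res.loc[treated, "index_value"].mean() > res.loc[control, "index_value"].mean()


def test_sample_permutation_equivariance(rng, cpi_pair):
    cfg = fc.BulkSimConfig(n_genes=200, index_pair=cpi_pair, seed=2)
    expr, _, _ = fc.simulate_bulk(cfg)
    res = fc.compute_index(expr, fc.cpi_definition()).set_index("sample_id")
    perm = list(rng.permutation(expr.sample_ids))
    res_perm = fc.compute_index(
        expr.subset_samples(perm), fc.cpi_definition()
    ).set_index("sample_id")
    np.testing.assert_allclose(
        res.loc[perm, "index_value"], res_perm.loc[perm, "index_value"]
    )


def test_raw_difference_monotone_in_components_unweighted(rng, cpi_pair):
    """At alpha=0 raising a positive-component gene never lowers the raw
    index and raising a negative-component gene never raises it. (With
    alpha>0 the rank weights can break strict monotonicity: a low-ranked
    set gene moving up inflates the in-set weight denominator.)"""
    cfg = fc.BulkSimConfig(n_genes=100, index_pair=cpi_pair, seed=5)
    expr, _, _ = fc.simulate_bulk(cfg)
    defn = fc.cpi_definition()
    base = fc.compute_index(expr, defn, alpha=0.0)["raw_difference"].to_numpy()
    for _ in range(10):
        sample = int(rng.integers(expr.n_samples))
        up_gene = rng.choice(sorted(cpi_pair.positive.genes))
        bumped = expr.values.copy()
        gi = expr.gene_ids.index(up_gene)
        bumped[gi, sample] += float(rng.uniform(0.5, 3.0))
        m2 = fc.ExpressionMatrix(bumped, expr.gene_ids, expr.sample_ids)
        after = fc.compute_index(m2, defn, alpha=0.0)["raw_difference"].to_numpy()
        assert after[sample] >= base[sample] - 1e-12

        down_gene = rng.choice(sorted(cpi_pair.negative.genes))
        bumped = expr.values.copy()
        gi = expr.gene_ids.index(down_gene)
        bumped[gi, sample] += float(rng.uniform(0.5, 3.0))
        m3 = fc.ExpressionMatrix(bumped, expr.gene_ids, expr.sample_ids)
        after = fc.compute_index(m3, defn, alpha=0.0)["raw_difference"].to_numpy()
        assert after[sample] <= base[sample] + 1e-12


class TestCompareGroups:
    def _meta(self, samples, labels):
        return fc.SampleMetadata.from_columns(samples, treatment=labels)

    def test_identical_groups_ns(self):
        import pandas as pd

        res_frame = pd.DataFrame(
            {"sample_id": list("abcdef"), "index_value": [1, 2, 3, 1, 2, 3]}
        )
        meta = self._meta(list("abcdef"), ["control"] * 3 + ["curcumin"] * 3)
        out = fc.compare_groups(res_frame, meta)
        assert out["p"].iloc[0] == 1.0 and out["significance"].iloc[0] == "ns"

    def test_separated_groups_exact_p(self):
        import pandas as pd

        res_frame = pd.DataFrame(
            {"sample_id": list("abcdef"), "index_value": [1, 2, 3, 4, 5, 6]}
        )
        meta = self._meta(list("abcdef"), ["control"] * 3 + ["curcumin"] * 3)
        out = fc.compare_groups(res_frame, meta)
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_small_group_rejected(self):
        import pandas as pd

        res_frame = pd.DataFrame({"sample_id": list("abc"), "index_value": [1, 2, 3]})
        meta = self._meta(list("abc"), ["control", "control", "curcumin"])
        with pytest.raises(ValueError, match="fewer than 2"):
            fc.compare_groups(res_frame, meta)


class TestHeatmapTable:
    def test_component_rows_standardized_and_absent_listed(self, cpi_pair):
        cfg = fc.BulkSimConfig(n_genes=50, index_pair=cpi_pair, seed=1)
        expr, _, _ = fc.simulate_bulk(cfg)
        # drop one component gene from the matrix
        kept = [g for g in expr.gene_ids if g != "LIAS"]
        sub = expr.subset_genes(kept)
        table, absent = fc.index_heatmap_table(sub, fc.cpi_definition())
        assert absent == ["LIAS"]
        assert len(table) <= 10
        assert set(table["component"]) == {"positive", "negative"}
        sample_cols = [c for c in table.columns if c not in ("gene_id", "component")]
        row_means = table[sample_cols].mean(axis=1)
        np.testing.assert_allclose(row_means, 0.0, atol=1e-12)
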