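import numpy as np
import pytest

import ferrocup as fc
from ferrocup.coexpr import adjacency_matrix, topological_overlap
from oracles import tom_bruteforce
from conftest import random_matrix, scale_free_matrix


def _rand_index(labels_a, labels_b):
    """Adjusted Rand index between two label sequences (contingency form)."""
    from scipy.special import comb

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    classes_a, ia = np.unique(a, return_inverse=True)
    classes_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((classes_a.size, classes_b.size), dtype=int)
    for i, j in zip(ia, ib):
        table[i, j] += 1
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    n_pairs = comb(a.size, 2)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2.0
    return (sum_comb - expected) / (max_index - expected)


class TestTOM:
    def test_two_gene_closed_form(self):
        a = np.array([[0.0, 0.3], [0.3, 0.0]])
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(0.3)
        assert tom[0, 0] == 1.0

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 20, 8)
            adj = adjacency_matrix(m, 6)
            np.testing.assert_allclose(
                topological_overlap(adj), tom_bruteforce(adj), atol=1e-12
            )

    def test_adjacency_and_tom_bounded(self, rng):
        m = random_matrix(rng, 30, 10)
        adj = adjacency_matrix(m, 4)
        tom = topological_overlap(adj)
        assert (adj >= 0).all() and (adj <= 1).all()
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()


class TestSoftThreshold:
    def test_single_candidate_always_selected(self, rng):
        m = random_matrix(rng, 50, 6)
        fit = fc.pick_soft_threshold(m, candidates=[21])
        assert fit.selected_beta == 21

    def test_scale_free_construction_reaches_target(self):
        m = scale_free_matrix(seed=11)
        fit = fc.pick_soft_threshold(m, candidates=[6], target_r2=0.85)
        assert fit.target_met
        assert fit.r_squared[0] >= 0.9

    def test_noise_genes_fall_back_with_flag(self, rng):
        m = random_matrix(rng, 200, 20)
        fit = fc.pick_soft_threshold(m, candidates=[2, 4, 6], target_r2=0.85)
        assert not fit.target_met
        assert fit.selected_beta in (2, 4, 6)

    def test_smallest_qualifying_beta_selected(self):
        m = scale_free_matrix(seed=13)
        fit = fc.pick_soft_threshold(m, candidates=[6, 8, 10], target_r2=0.5)
        assert fit.selected_beta == 6

    def test_too_few_samples_rejected(self, rng):
        m = random_matrix(rng, 30, 3)
        with pytest.raises(ValueError, match="samples"):
            fc.pick_soft_threshold(m, candidates=[6])


class TestDetectModules:
    def test_planted_module_recovery(self, bulk_with_modules):
        expr, _, truth = bulk_with_modules
        asn = fc.detect_modules(
            expr, fc.ModuleDetectionParams(beta=6, min_module_size=20)
        )
        non_grey = [g for g, m in asn.labels.items() if m != "grey"]
        pred = [asn.labels[g] for g in non_grey]
        true = [truth.module_labels.get(g, 0) for g in non_grey]
        assert _rand_index(true, pred) >= 0.8

    def test_labels_partition_gene_universe(self, bulk_with_modules):
        expr, _, _ = bulk_with_modules
        asn = fc.detect_modules(
            expr, fc.ModuleDetectionParams(beta=6, min_module_size=20)
        )
        assert set(asn.labels) == set(expr.gene_ids)
        assert sum(asn.sizes.values()) == expr.n_genes
        non_grey = [m for m in asn.sizes if m != "grey"]
        assert all(asn.sizes[m] >= 20 for m in non_grey)

    def test_shared_factor_modules_merge(self, rng):
        ns = 18
        f = rng.normal(size=ns)
        rows, genes = [], []
        for m in range(2):
            for i in range(30):
                rows.append(2.0 * f + rng.normal(0, 0.7, ns))
                genes.append(f"M{m}_{i}")
        for i in range(100):
            rows.append(rng.normal(0, 1, ns))
            genes.append(f"N{i}")
        expr = fc.ExpressionMatrix(
            np.array(rows) + 7, genes, [f"s{j}" for j in range(ns)]
        )
        asn = fc.detect_modules(expr, fc.ModuleDetectionParams(beta=6, min_module_size=20))
        planted = [asn.labels[g] for g in genes if g.startswith("M")]
        non_grey = {m for m in planted if m != "grey"}
        assert len(non_grey) == 1

    def test_eigengene_rayleigh_property(self, rng, bulk_with_modules):
        """The eigengene captures at least as much variance as any random
        unit-norm linear combination of the module's genes."""
        expr, _, _ = bulk_with_modules
        asn = fc.detect_modules(expr, fc.ModuleDetectionParams(beta=6, min_module_size=20))
        module = next(m for m in asn.sizes if m != "grey")
        members = asn.genes_in(module)
        sub = expr.subset_genes(members).values
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        eig = asn.eigengenes[module].to_numpy()
        var_eig = ((z @ eig) ** 2).sum()
        for _ in range(20):
            probe = rng.normal(size=eig.size)
            probe /= np.linalg.norm(probe)
            assert var_eig >= ((z @ probe) ** 2).sum() - 1e-9

    def test_eigengene_sign_tracks_module_mean(self, bulk_with_modules):
        expr, _, _ = bulk_with_modules
        asn = fc.detect_modules(expr, fc.ModuleDetectionParams(beta=6, min_module_size=20))
        for module in (m for m in asn.sizes if m != "grey"):
            members = asn.genes_in(module)
            mean_profile = expr.subset_genes(members).values.mean(axis=0)
            r = np.corrcoef(asn.eigengenes[module], mean_profile)[0, 1]
            assert r > 0

    def test_too_few_genes_rejected(self, rng):
        m = random_matrix(rng, 10, 6)
        with pytest.raises(ValueError, match="min_module_size"):
            fc.detect_modules(m, fc.ModuleDetectionParams(beta=6, min_module_size=30))


class TestModuleTrait:
    def test_eigengene_equal_to_trait_gives_r_one(self):
        import pandas as pd
        from ferrocup.coexpr import ModuleAssignment

        samples = [f"s{i}" for i in range(6)]
        trait = [0.0, 1.0, 0.0, 1.0, 1.0, 0.0]
        asn = ModuleAssignment(
            labels={"g1": "m1"},
            eigengenes=pd.DataFrame({"m1": trait}, index=samples),
            sizes={"m1": 1},
        )
        meta = fc.SampleMetadata.from_columns(
            samples, treatment=["control" if t == 0 else "curcumin" for t in trait]
        )
        out = fc.module_trait(asn, meta, ["treatment"])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_trait_gives_zero_r(self):
        import pandas as pd
        from ferrocup.coexpr import ModuleAssignment

        samples = list("abcd")
        asn = ModuleAssignment(
            labels={"g1": "m1"},
            eigengenes=pd.DataFrame({"m1": [1.0, 1.0, -1.0, -1.0]}, index=samples),
            sizes={"m1": 1},
        )
        meta = fc.SampleMetadata.from_columns(samples, grp=["1", "0", "1", "0"])
        out = fc.module_trait(asn, meta, ["grp"])
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_constant_trait_flagged_degenerate(self):
        import pandas as pd
        from ferrocup.coexpr import ModuleAssignment

        samples = list("abcd")
        asn = ModuleAssignment(
            labels={"g1": "m1"},
            eigengenes=pd.DataFrame({"m1": [1.0, 2.0, 3.0, 4.0]}, index=samples),
            sizes={"m1": 1},
        )
        meta = fc.SampleMetadata.from_columns(samples, grp=["1", "1", "1", "1"])
        out = fc.module_trait(asn, meta, ["grp"])
        assert out["degenerate"].iloc[0]

    def test_treatment_responsive_module_attains_largest_r(self, rng):
        """A module whose latent factor follows the treatment contrast
        dominates the module-trait correlation for treatment."""
        ns = 12
        treatment = np.array([0, 1] * 6, dtype=float)
        rows, genes = [], []
        for i in range(40):  # treatment-driven module
            rows.append(2.0 * treatment + rng.normal(0, 0.5, ns))
            genes.append(f"T{i}")
        f = rng.normal(size=ns)
        for i in range(40):  # treatment-independent module
            rows.append(2.0 * f + rng.normal(0, 0.5, ns))
            genes.append(f"U{i}")
        for i in range(80):
            rows.append(rng.normal(0, 1, ns))
            genes.append(f"N{i}")
        samples = [f"s{j}" for j in range(ns)]
        expr = fc.ExpressionMatrix(np.array(rows) + 7, genes, samples)
        meta = fc.SampleMetadata.from_columns(
            samples,
            treatment=["control" if t == 0 else "curcumin" for t in treatment],
        )
        asn = fc.detect_modules(expr, fc.ModuleDetectionParams(beta=6, min_module_size=20))
        out = fc.module_trait(asn, meta, ["treatment"])
        best = out.loc[out["r"].abs().idxmax(), "module"]
        t_labels = {asn.labels[g] for g in genes if g.startswith("T")}
        assert best in t_labels
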