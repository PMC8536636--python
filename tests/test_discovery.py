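import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmap import discovery, eigengenes, simulate
from coexmap.types import ValidationError

from conftest import make_fc


def planted_blocks(seed=0, n_blocks=2, block_size=10, n_cond=80, cor=0.9, n_noise=0):
    """Factor-model fixture with known block partition."""
    rng = np.random.default_rng(seed)
    loading = np.sqrt(cor)
    noise_sd = np.sqrt(1 - cor)
    cols, labels = [], []
    for b in range(n_blocks):
        act = rng.standard_normal(n_cond)
        for _ in range(block_size):
            cols.append(loading * act + rng.normal(0, noise_sd, n_cond))
            labels.append(b + 1)
    for _ in range(n_noise):
        cols.append(rng.standard_normal(n_cond))
        labels.append(0)
    return make_fc(np.column_stack(cols)), np.array(labels)


class TestFilterGenes:
    def test_single_hit_kept(self):
        fc = make_fc(
            [[1.0, 1.0], [1.0, 1.0]],
            adj_p=[[0.0005, 0.9], [0.9, 0.9]],
        )
        assert discovery.filter_genes(fc) == ["g0"]

    def test_no_hits_empty(self):
        fc = make_fc([[1.0], [1.0]], adj_p=[[0.01], [0.5]])
        assert discovery.filter_genes(fc) == []

    def test_boundary_strict(self):
        fc = make_fc([[1.0], [1.0]], adj_p=[[0.001], [0.5]])
        assert discovery.filter_genes(fc) == []

    def test_missing_adjp_instructs(self):
        fc = make_fc([[1.0], [1.0]])
        with pytest.raises(ValidationError, match="skip filtering"):
            discovery.filter_genes(fc)

    def test_order_preserved(self):
        fc = make_fc(
            np.ones((2, 3)),
            genes=["z", "a", "m"],
            adj_p=[[1e-5, 1e-5, 1e-5], [0.9, 0.9, 0.9]],
        )
        assert discovery.filter_genes(fc) == ["z", "a", "m"]


class TestSelectSoftPower:
    def test_single_candidate(self):
        fc = make_fc(np.random.default_rng(1).standard_normal((20, 12)))
        assert discovery.select_soft_power(fc, candidates=[5]) == 5

    def test_scale_free_fixture_reaches_target(self):
        # hub-structured correlations give a heavy-tailed connectivity
        rng = np.random.default_rng(2)
        n_cond, n_genes = 150, 120
        hub = rng.standard_normal(n_cond)
        cols = []
        for i in range(n_genes):
            w = 0.95 * (i < 6) + 0.35 * (i >= 6)  # few hubs, many periphery
            cols.append(w * hub + rng.normal(0, np.sqrt(1 - w**2), n_cond))
        fc = make_fc(np.column_stack(cols))
        beta = discovery.select_soft_power(fc, candidates=list(range(1, 13)))
        absC = np.abs(np.corrcoef(fc.values.to_numpy(), rowvar=False))
        np.fill_diagonal(absC, 0)
        fit = discovery.scale_free_fit((absC**beta).sum(axis=0))
        assert fit >= 0.8

    def test_degenerate_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(12)
        # all genes identical profile -> equal correlations -> one bin
        X = np.column_stack([base + rng.normal(0, 1e-12, 12) for _ in range(15)])
        fc = make_fc(X)
        with pytest.warns(UserWarning):
            beta = discovery.select_soft_power(fc, candidates=[2, 3])
        assert beta in (2, 3)

    def test_too_few_genes(self):
        fc = make_fc(np.random.default_rng(4).standard_normal((20, 5)))
        with pytest.raises(ValidationError):
            discovery.select_soft_power(fc, candidates=[1, 2])

    def test_fit_matches_bruteforce_regression(self):
        """scale_free_fit agrees with an independent binned regression."""
        rng = np.random.default_rng(5)
        k = rng.pareto(2.0, size=400) + 0.5
        got = discovery.scale_free_fit(k, n_bins=10)
        # brute-force oracle over the same equal-width bins
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            sel = idx == b
            if sel.sum():
                xs.append(np.log10(k[sel].mean()))
                ys.append(np.log10(sel.sum() / k.size))
        xs, ys = np.array(xs), np.array(ys)
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        r2 = 1 - resid.var() / ys.var()
        expected = r2 if slope < 0 else -r2
        assert got == pytest.approx(expected, abs=1e-10)


class TestBuildNetwork:
    def test_pairwise_adjacency_arithmetic(self):
        rng = np.random.default_rng(6)
        n = 2000
        a = rng.standard_normal(n)
        b = -0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        fc = make_fc(np.column_stack([a, b, rng.standard_normal(n)]))
        net = discovery.build_network(fc, beta=5)
        r = np.corrcoef(a, b)[0, 1]
        assert net.adjacency[0, 1] == pytest.approx(abs(r) ** 5, rel=1e-10)
        assert abs(net.adjacency[0, 1] - 0.6**5) < 0.02  # ~0.07776

    def test_diagonal(self):
        fc = make_fc(np.random.default_rng(7).standard_normal((30, 6)))
        net = discovery.build_network(fc, beta=3)
        assert np.allclose(np.diag(net.adjacency), 1.0)
        assert np.allclose(np.diag(net.tom_dissimilarity), 0.0)

    def test_tom_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        fc = make_fc(rng.standard_normal((50, 4)))
        net = discovery.build_network(fc, beta=2)
        A = net.adjacency
        n = A.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(A[i, u] for u in range(n) if u != i)
                k_j = sum(A[j, u] for u in range(n) if u != j)
                tom = (l_ij + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                assert 1 - net.tom_dissimilarity[i, j] == pytest.approx(tom, abs=1e-10)

    def test_symmetry_and_range(self):
        fc = make_fc(np.random.default_rng(9).standard_normal((40, 15)))
        net = discovery.build_network(fc, beta=6)
        assert np.abs(net.adjacency - net.adjacency.T).max() < 1e-10
        assert np.abs(net.tom_dissimilarity - net.tom_dissimilarity.T).max() < 1e-10
        assert net.adjacency.min() >= 0 and net.adjacency.max() <= 1
        assert net.tom_dissimilarity.min() >= 0 and net.tom_dissimilarity.max() <= 1

    def test_zero_variance_gene_named(self):
        fc = make_fc([[1.0, 3.0], [2.0, 3.0], [3.0, 3.0]], genes=["ok", "flat"])
        with pytest.raises(ValidationError, match="flat"):
            discovery.build_network(fc, beta=5)

    def test_too_few_conditions(self):
        fc = make_fc(np.random.default_rng(9).standard_normal((2, 5)))
        with pytest.raises(ValidationError):
            discovery.build_network(fc, beta=5)


class TestDetectModules:
    def test_two_planted_blocks(self):
        fc, labels = planted_blocks(seed=10)
        net = discovery.build_network(fc, beta=5)
        assign = discovery.detect_modules(net, min_size=5)
        assert len(set(assign.labels) - {0}) == 2
        assert adjusted_rand_score(labels, assign.labels) == 1.0

    def test_min_size_rule(self):
        fc, _ = planted_blocks(seed=11, n_blocks=1, block_size=3, n_noise=20)
        net = discovery.build_network(fc, beta=5)
        assign = discovery.detect_modules(net, min_size=5)
        assert set(assign.labels[:3]) == {0}

    def test_pure_noise_mostly_gray(self):
        rng = np.random.default_rng(12)
        fc = make_fc(rng.standard_normal((100, 200)))
        net = discovery.build_network(fc, beta=5)
        assign = discovery.detect_modules(net, min_size=5)
        assert (assign.labels == 0).mean() >= 0.9

    def test_min_size_validation(self):
        fc, _ = planted_blocks(seed=13)
        net = discovery.build_network(fc, beta=5)
        with pytest.raises(ValueError):
            discovery.detect_modules(net, min_size=1)


class TestMergeAndLabel:
    def _two_correlated_modules(self, cross_cor, seed=14, n_cond=200):
        """Two planted modules whose activities correlate at cross_cor."""
        rng = np.random.default_rng(seed)
        act1 = rng.standard_normal(n_cond)
        act2 = cross_cor * act1 + np.sqrt(1 - cross_cor**2) * rng.standard_normal(n_cond)
        cols, genes = [], []
        for i, act in ((1, act1), (2, act2)):
            for j in range(8):
                cols.append(0.95 * act + rng.normal(0, 0.2, n_cond))
                genes.append(f"m{i}_{j}")
        fc = make_fc(np.column_stack(cols), genes=genes)
        assign = discovery.ModuleAssignment(
            gene_ids=genes, labels=np.array([1] * 8 + [2] * 8)
        )
        return fc, assign

    def test_high_correlation_merges(self):
        fc, assign = self._two_correlated_modules(0.97)
        ms = discovery.merge_and_label(assign, fc, merge_cor=0.8)
        assert len(ms.modules) == 1
        assert ms.modules[0].size == 16

    def test_low_correlation_unchanged(self):
        fc, assign = self._two_correlated_modules(0.3)
        ms = discovery.merge_and_label(assign, fc, merge_cor=0.8)
        assert sorted(m.size for m in ms.modules) == [8, 8]

    def test_labels_by_decreasing_size(self):
        rng = np.random.default_rng(15)
        sizes = [7, 40, 12]
        cols, genes, labels = [], [], []
        for lab, size in enumerate(sizes, start=1):
            act = rng.standard_normal(150)
            for j in range(size):
                cols.append(0.9 * act + rng.normal(0, 0.3, 150))
                genes.append(f"m{lab}_{j}")
                labels.append(lab)
        fc = make_fc(np.column_stack(cols), genes=genes)
        assign = discovery.ModuleAssignment(gene_ids=genes, labels=np.array(labels))
        ms = discovery.merge_and_label(assign, fc, merge_cor=0.99)
        got = [m.size for m in sorted(ms.modules, key=lambda m: m.id)]
        assert got == [40, 12, 7]

    def test_merge_order_independent(self):
        fc, assign = self._two_correlated_modules(0.9)
        flipped = discovery.ModuleAssignment(
            gene_ids=assign.gene_ids, labels=np.where(assign.labels == 1, 2, 1)
        )
        a = discovery.merge_and_label(assign, fc)
        b = discovery.merge_and_label(flipped, fc)
        assert [sorted(m.gene_ids) for m in a.modules] == [
            sorted(m.gene_ids) for m in b.modules
        ]


class TestPlantedRecoveryProperty:
    @pytest.mark.parametrize("seed", [21, 22])
    def test_ari_at_least_090(self, seed):
        fc, truth = simulate.generate_reference(
            n_genes=500,
            n_modules=12,
            module_size_range=(8, 50),
            n_conditions=150,
            loading_range=(0.7, 0.95),
            noise_sd=0.5,
            seed=seed,
        )
        modules, _ = discovery.build_modules(fc)
        lab = modules.labels()
        det = lab[lab > 0]
        tru = truth.module_partition.reindex(det.index)
        assert adjusted_rand_score(tru.to_numpy(), det.to_numpy()) >= 0.9
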