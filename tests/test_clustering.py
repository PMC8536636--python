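import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmap import cluster
from coexmap.types import EigengeneMatrix, ValidationError


def egs_from_array(arr, module_ids=None, condition_ids=None):
    arr = np.asarray(arr, dtype=float)
    module_ids = module_ids or list(range(1, arr.shape[0] + 1))
    condition_ids = condition_ids or [f"C{i:03d}_MED_24 hr" for i in range(arr.shape[1])]
    return EigengeneMatrix(
        scores=pd.DataFrame(arr, index=module_ids, columns=condition_ids)
    )


class TestConditionSimilarity:
    def test_self_correlation(self):
        egs = egs_from_array(np.random.default_rng(0).standard_normal((5, 4)))
        c = egs.condition_ids[0]
        assert cluster.condition_similarity(egs, c, c) == pytest.approx(1.0)

    def test_monotone_transform_spearman(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(10)
        b = np.exp(a)  # strictly monotone
        egs = egs_from_array(np.column_stack([a, b]), condition_ids=["x", "y"])
        assert cluster.condition_similarity(egs, "x", "y", "spearman") == pytest.approx(1.0)
        assert cluster.condition_similarity(egs, "x", "y", "pearson") <= 1.0

    def test_analog_vs_independent(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        analog = x + rng.normal(0, 0.3, 100)
        indep = rng.standard_normal(100)
        egs = egs_from_array(
            np.column_stack([x, analog, indep]), condition_ids=["x", "analog", "indep"]
        )
        assert cluster.condition_similarity(egs, "x", "analog") > 0.9
        assert abs(cluster.condition_similarity(egs, "x", "indep")) < 0.3

    def test_symmetric_bounded(self):
        egs = egs_from_array(np.random.default_rng(3).standard_normal((6, 5)))
        a, b = egs.condition_ids[:2]
        r1 = cluster.condition_similarity(egs, a, b)
        r2 = cluster.condition_similarity(egs, b, a)
        assert r1 == pytest.approx(r2)
        assert -1 <= r1 <= 1

    def test_too_few_modules(self):
        egs = egs_from_array(np.random.default_rng(4).standard_normal((2, 4)))
        with pytest.raises(ValidationError):
            cluster.condition_similarity(egs, *egs.condition_ids[:2])


class TestImputeConditions:
    def test_complete_matrix_unchanged(self):
        egs = egs_from_array(np.random.default_rng(5).standard_normal((6, 8)))
        out = cluster.impute_conditions(egs, drop_time=None)
        pd.testing.assert_frame_equal(out.scores, egs.scores)

    def test_drops_two_hour_conditions(self):
        arr = np.random.default_rng(6).standard_normal((4, 6))
        conds = [f"C{i}_LO_2 hr" for i in range(3)] + [f"C{i}_LO_24 hr" for i in range(3)]
        egs = egs_from_array(arr, condition_ids=conds)
        out = cluster.impute_conditions(egs, drop_time="2 hr")
        assert all("2 hr" not in c for c in out.condition_ids)
        assert len(out.condition_ids) == 3

    def test_low_rank_recovery(self):
        rng = np.random.default_rng(7)
        U = rng.standard_normal((100, 3))
        V = rng.standard_normal((3, 60))
        X = U @ V
        mask = rng.uniform(size=X.shape) < 0.10
        Xm = X.copy()
        Xm[mask] = np.nan
        egs = egs_from_array(Xm)
        out = cluster.impute_conditions(egs, drop_time=None, rank=3, tol=1e-4)
        rmse = np.sqrt(np.mean((out.scores.to_numpy()[mask] - X[mask]) ** 2))
        assert rmse < 0.1 * X.std()

    def test_observed_entries_untouched(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 12))
        mask = rng.uniform(size=X.shape) < 0.2
        Xm = X.copy()
        Xm[mask] = np.nan
        out = cluster.impute_conditions(egs_from_array(Xm), drop_time=None, rank=2)
        got = out.scores.to_numpy()
        np.testing.assert_allclose(got[~mask], X[~mask], atol=1e-14)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((20, 15))
        X[rng.uniform(size=X.shape) < 0.1] = np.nan
        once = cluster.impute_conditions(egs_from_array(X), drop_time=None, rank=3)
        twice = cluster.impute_conditions(once, drop_time=None, rank=3)
        pd.testing.assert_frame_equal(once.scores, twice.scores)

    def test_fully_missing_condition_errors(self):
        X = np.random.default_rng(10).standard_normal((4, 5))
        X[:, 2] = np.nan
        with pytest.raises(ValidationError):
            cluster.impute_conditions(egs_from_array(X), drop_time=None)


class TestExpandSeedModules:
    def _egs(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal(200)

        def noisy(target_r):
            return target_r * base + np.sqrt(1 - target_r**2) * rng.standard_normal(200)

        rows = [base, noisy(0.75), noisy(0.69), rng.standard_normal(200)]
        # empirical correlations drift; rescale rows 2,3 to hit targets closely
        return egs_from_array(
            np.vstack(rows),
            module_ids=[1, 2, 3, 4],
            condition_ids=[f"c{i}" for i in range(200)],
        )

    def test_threshold_semantics(self):
        egs = self._egs()
        C = np.corrcoef(egs.scores.to_numpy())
        res = cluster.expand_seed_modules(egs, seeds=[1], r_min=0.7)
        for mid in (2, 3, 4):
            if C[0, mid - 1] >= 0.7:
                assert mid in res.addin_ids
            else:
                assert mid not in res.addin_ids

    def test_exact_boundary_inclusive(self):
        a = np.array([1.0, 0.0, -1.0, 0.5, -0.5] * 4)
        b = 0.7 * a + np.sqrt(1 - 0.49) * np.array([0.3, -1.2, 0.9, 0.1, -0.4] * 4)
        # force exact r = 0.7 via Gram-Schmidt
        resid = b - np.polyval(np.polyfit(a, b, 1), a)
        resid = resid / np.std(resid, ddof=0)
        az = (a - a.mean()) / a.std(ddof=0)
        exact = 0.7 * az + np.sqrt(1 - 0.49) * resid
        egs = egs_from_array(
            np.vstack([a, exact]), module_ids=[1, 2], condition_ids=[f"c{i}" for i in range(20)]
        )
        r = np.corrcoef(a, exact)[0, 1]
        assert r == pytest.approx(0.7, abs=1e-12)
        res = cluster.expand_seed_modules(egs, seeds=[1], r_min=0.7)
        assert 2 in res.addin_ids

    def test_seeds_always_included(self):
        egs = self._egs()
        res = cluster.expand_seed_modules(egs, seeds=[4], r_min=0.99)
        assert res.seed_ids == [4]
        assert 4 in res.member_ids

    def test_missing_seed_errors(self):
        with pytest.raises(ValidationError):
            cluster.expand_seed_modules(self._egs(), seeds=[99])


class TestClusterModules:
    def test_perfectly_correlated_merge_first(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(50)
        arr = np.vstack([a, a * 2.0, rng.standard_normal(50)])
        egs = egs_from_array(arr, condition_ids=[f"c{i}" for i in range(50)])
        res = cluster.cluster_modules(egs, k=2)
        assert res.cluster_labels[1] == res.cluster_labels[2]
        assert res.cluster_labels[3] != res.cluster_labels[1]
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_anticorrelated_groups_recovered(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal(150)
        rows, truth = [], []
        for grp, sign in ((0, 1.0), (1, -1.0)):
            for _ in range(5):
                rows.append(sign * base + rng.normal(0, 0.3, 150))
                truth.append(grp)
        egs = egs_from_array(np.vstack(rows), condition_ids=[f"c{i}" for i in range(150)])
        res = cluster.cluster_modules(egs, k=2)
        labels = [res.cluster_labels[m] for m in sorted(res.cluster_labels)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_merge_heights_monotone(self):
        egs = egs_from_array(np.random.default_rng(14).standard_normal((8, 40)))
        res = cluster.cluster_modules(egs, k=3)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-10).all()

    def test_member_order_invariance(self):
        rng = np.random.default_rng(15)
        egs = egs_from_array(rng.standard_normal((7, 60)))
        a = cluster.cluster_modules(egs, members=[1, 2, 3, 4, 5, 6, 7], k=3)
        b = cluster.cluster_modules(egs, members=[7, 3, 5, 1, 6, 2, 4], k=3)
        assert a.cluster_labels == b.cluster_labels

    def test_eight_planted_groups(self):
        rng = np.random.default_rng(16)
        rows, truth = [], []
        for grp in range(8):
            base = rng.standard_normal(200)
            for _ in range(6):
                rows.append(base * 0.95 + rng.normal(0, 0.3, 200))
                truth.append(grp)
        egs = egs_from_array(np.vstack(rows), condition_ids=[f"c{i}" for i in range(200)])
        res = cluster.cluster_modules(egs, k=8)
        labels = [res.cluster_labels[m] for m in sorted(res.cluster_labels)]
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_constant_module_named_in_error(self):
        arr = np.vstack([np.ones(10), np.random.default_rng(17).standard_normal(10)])
        egs = egs_from_array(arr, module_ids=[7, 8])
        with pytest.raises(ValidationError, match="7"):
            cluster.cluster_modules(egs, k=2)

    def test_k_xor_height(self):
        egs = egs_from_array(np.random.default_rng(18).standard_normal((4, 20)))
        with pytest.raises(ValueError):
            cluster.cluster_modules(egs, k=2, height=0.5)
        with pytest.raises(ValueError):
            cluster.cluster_modules(egs)

    def test_cluster_ids_by_decreasing_size(self):
        rng = np.random.default_rng(19)
        base1, base2 = rng.standard_normal(100), rng.standard_normal(100)
        rows = [base1 + rng.normal(0, 0.2, 100) for _ in range(5)]
        rows += [base2 + rng.normal(0, 0.2, 100) for _ in range(2)]
        egs = egs_from_array(np.vstack(rows), condition_ids=[f"c{i}" for i in range(100)])
        res = cluster.cluster_modules(egs, k=2)
        sizes = {cid: len(ms) for cid, ms in res.clusters().items()}
        assert sizes[1] >= sizes[2]
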