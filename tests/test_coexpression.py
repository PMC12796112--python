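import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from turbomap import (CoexprConfig, IntensityMatrix, TraitTable, bicor,
                      bicor_matrix, detect_modules, merge_modules,
                      module_eigengene, module_trait_correlation,
                      signed_adjacency, topological_overlap)
from turbomap.coexpression import NetworkModel, _recompute_eigengenes, kme_table


def _im(X):
    X = np.asarray(X, dtype=float)
    return IntensityMatrix([f"P{i}" for i in range(X.shape[0])],
                           [f"s{j}" for j in range(X.shape[1])],
                           X, np.ones_like(X, dtype=bool))


class TestBicor:
    def test_affine_invariance(self):
        x = np.random.default_rng(0).normal(size=50)
        assert bicor(x, 2 * x + 3) == pytest.approx(1.0, abs=1e-12)
        assert bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=2000)
        b = bicor(z[:, 0], z[:, 1])
        p = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        assert abs(b - p) < 0.03

    def test_robust_to_gross_outlier(self):
        rng = np.random.default_rng(2)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=300)
        x, y = z[:, 0].copy(), z[:, 1].copy()
        x[0], y[0] = 30.0, -30.0
        b = bicor(x, y)
        p = np.corrcoef(x, y)[0, 1]
        assert abs(b - 0.6) < abs(p - 0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bicor(np.ones(10), np.arange(10.0))

    def test_zero_mad_falls_back_to_pearson(self, caplog):
        # mostly-constant vector: MAD = 0 but variance > 0
        x = np.array([1.0] * 8 + [2.0, 3.0])
        y = np.arange(10.0)
        with caplog.at_level("INFO", logger="turbomap"):
            b = bicor(x, y)
        assert np.isfinite(b)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        r = bicor_matrix(rng.normal(size=(12, 30)))
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.all((r >= -1) & (r <= 1))


class TestAdjacency:
    def test_range_endpoints(self):
        r = np.array([[1.0, -1.0], [-1.0, 1.0]])
        a = signed_adjacency(r, beta=9)
        assert a[0, 1] == 0.0
        assert a[0, 0] == 1.0

    def test_zero_correlation_closed_form(self):
        r = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(r, 9)[0, 1] == pytest.approx(0.5 ** 9)

    def test_strictly_monotone(self):
        rng = np.random.default_rng(4)
        rs = np.sort(rng.uniform(-1, 1, 20))
        a = ((1 + rs) / 2) ** 9
        assert np.all(np.diff(a) > 0)


def brute_force_tom(a, denominator="mean"):
    n = len(a)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            den = (ki + kj) / 2 if denominator == "mean" else min(ki, kj)
            tom[i, j] = (l + a[i, j]) / (den - a[i, j] + 1)
    return tom


class TestTom:
    def test_two_node_equals_adjacency(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert topological_overlap(a)[0, 1] == pytest.approx(0.3)

    def test_three_node_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        assert topological_overlap(a)[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("denominator", ["mean", "min"])
    def test_matches_triple_loop(self, denominator):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(topological_overlap(a, denominator),
                                   brute_force_tom(a, denominator),
                                   atol=1e-12)


class TestEigengene:
    def test_identical_profiles_return_standardized_profile(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=30)
        X = np.tile(z, (5, 1))
        me = module_eigengene(X, range(5))
        zstd = (z - z.mean()) / z.std()
        np.testing.assert_allclose(me, zstd, atol=1e-8)

    def test_sign_orientation_under_global_flip(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 40))
        me1 = module_eigengene(X, range(10))
        me2 = module_eigengene(-X, range(10))
        np.testing.assert_allclose(me1, -me2, atol=1e-8)
        assert np.corrcoef(me1, X.mean(axis=0))[0, 1] > 0

    def test_factor_recovery(self):
        rng = np.random.default_rng(8)
        seed = rng.normal(size=60)
        X = 2.0 * seed[None, :] + rng.normal(0, 1, size=(50, 60))
        me = module_eigengene(X, range(50))
        assert abs(np.corrcoef(me, seed)[0, 1]) >= 0.95

    def test_constant_members_rejected(self):
        with pytest.raises(ValueError):
            module_eigengene(np.ones((3, 10)), range(3))


def _planted(n_noise=120, sizes=(60, 40), cor=0.9, n_s=60, seed=0):
    rng = np.random.default_rng(seed)
    lam = np.sqrt(cor / (1 - cor))
    n_p = n_noise + sum(sizes)
    X = rng.normal(size=(n_p, n_s))
    truth = np.zeros(n_p, dtype=int)
    pos = 0
    for mi, s in enumerate(sizes):
        X[pos:pos + s] += lam * rng.normal(size=n_s)
        truth[pos:pos + s] = mi + 1
        pos += s
    return _im(X), truth


class TestDetection:
    def test_planted_modules_recovered(self):
        m, truth = _planted(seed=1)
        model = detect_modules(m, CoexprConfig())
        pred = model.module_of.map(lambda s: 0 if s == "M0" else int(s[1:]))
        assert adjusted_rand_score(truth, pred.to_numpy()) >= 0.9

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(9)
        m = _im(rng.normal(size=(200, 50)))
        model = detect_modules(m, CoexprConfig())
        assert (model.module_of == "M0").mean() >= 0.9

    def test_min_module_size_enforced_and_labels_partition(self):
        m, _ = _planted(seed=2)
        model = detect_modules(m, CoexprConfig())
        sizes = model.module_of.value_counts()
        for mod, n in sizes.items():
            if mod != "M0":
                assert n >= model.config.min_module_size
        assert sizes.sum() == m.n_proteins
        # labels ordered by size descending
        mods = model.modules()
        assert [len(model.members(x)) for x in mods] == \
            sorted([len(model.members(x)) for x in mods], reverse=True)

    def test_row_order_invariance(self):
        m, truth = _planted(seed=3)
        model1 = detect_modules(m, CoexprConfig())
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_proteins)
        m2 = m.subset_proteins(perm)
        model2 = detect_modules(m2, CoexprConfig())
        a1 = model1.module_of.reindex(m.protein_ids).to_numpy()
        a2 = model2.module_of.reindex(m.protein_ids).to_numpy()
        assert adjusted_rand_score(a1, a2) == pytest.approx(1.0)

    def test_determinism(self):
        m, _ = _planted(seed=4)
        a = detect_modules(m, CoexprConfig()).module_of
        b = detect_modules(m, CoexprConfig()).module_of
        assert (a == b).all()


class TestMerge:
    def _model_with_two_modules(self, shared_seed: bool, seed=10):
        rng = np.random.default_rng(seed)
        n_s = 60
        s1 = rng.normal(size=n_s)
        s2 = s1 if shared_seed else rng.normal(size=n_s)
        X = np.vstack([
            3.0 * s1[None, :] + rng.normal(0, 1, (40, n_s)),
            3.0 * s2[None, :] + rng.normal(0, 1, (40, n_s)),
        ])
        m = _im(X)
        model = NetworkModel(m.protein_ids, m.sample_ids, X, None, None, None)
        import pandas as pd
        model.module_of = pd.Series(["M1"] * 40 + ["M2"] * 40,
                                    index=m.protein_ids)
        _recompute_eigengenes(model)
        return model

    def test_same_seed_modules_merge(self):
        model = self._model_with_two_modules(shared_seed=True)
        merged = merge_modules(model, cut_height=0.07)
        assert len(merged.modules()) == 1

    def test_independent_modules_do_not_merge(self):
        model = self._model_with_two_modules(shared_seed=False)
        merged = merge_modules(model, cut_height=0.07)
        assert len(merged.modules()) == 2

    def test_post_merge_min_dissimilarity_respects_cut(self):
        for seed in range(5):
            m, _ = _planted(sizes=(50, 40, 30), seed=seed)
            model = detect_modules(m, CoexprConfig())
            mods = model.modules()
            if len(mods) < 2:
                continue
            ME = model.eigengenes.loc[mods].to_numpy()
            dis = 1 - np.corrcoef(ME)
            np.fill_diagonal(dis, np.inf)
            assert dis.min() >= model.config.merge_cut_height


class TestKme:
    def test_injected_eigengene_has_unit_kme(self):
        m, _ = _planted(seed=11)
        model = detect_modules(m, CoexprConfig())
        mod = model.modules()[0]
        me = model.eigengenes.loc[mod].to_numpy()
        X2 = np.vstack([model.expr, me[None, :]])
        model2 = NetworkModel(model.protein_ids + ["ME_PROBE"],
                              model.sample_ids, X2, None, None, None)
        model2.module_of = model.module_of.copy()
        model2.module_of.loc["ME_PROBE"] = mod
        model2.eigengenes = model.eigengenes
        k = kme_table(model2)
        assert k.loc["ME_PROBE", mod] == pytest.approx(1.0, abs=1e-6)

    def test_hub_outranks_peripheral_member(self):
        rng = np.random.default_rng(12)
        n_s = 80
        seed = rng.normal(size=n_s)
        hub = 1.0 * seed + 0.1 * rng.normal(size=n_s)
        peripheral = 0.4 * seed + rng.normal(size=n_s)
        body = 2.0 * seed[None, :] + rng.normal(0, 1, (40, n_s))
        X = np.vstack([hub[None, :], peripheral[None, :], body,
                       rng.normal(size=(60, n_s))])
        model = detect_modules(_im(X), CoexprConfig())
        mod = model.module_of.iloc[0]
        assert mod != "M0"
        assert model.kme.loc["P0", mod] > model.kme.loc["P1", mod]

    def test_noise_proteins_have_small_kme(self):
        m, truth = _planted(n_noise=150, sizes=(60,), n_s=120, seed=13)
        model = detect_modules(m, CoexprConfig())
        noise = [pid for pid, t in zip(m.protein_ids, truth) if t == 0
                 and model.module_of[pid] == "M0"]
        assert model.kme.loc[noise].abs().to_numpy().max() < 0.5


class TestModuleTrait:
    def test_trait_equal_to_eigengene_correlates_perfectly(self):
        import pandas as pd
        m, _ = _planted(seed=14)
        model = detect_modules(m, CoexprConfig())
        mod = model.modules()[0]
        traits = TraitTable(pd.DataFrame(
            {"mftau": model.eigengenes.loc[mod].to_numpy()},
            index=pd.Index(model.sample_ids, name="sample_id")))
        mt = module_trait_correlation(model, traits)
        r = mt[(mt["module"] == mod) & (mt["trait"] == "mftau")]["r"].iloc[0]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_trait_skipped(self, caplog):
        import pandas as pd
        m, _ = _planted(seed=15)
        model = detect_modules(m, CoexprConfig())
        traits = TraitTable(pd.DataFrame(
            {"flat": np.ones(len(model.sample_ids))},
            index=pd.Index(model.sample_ids, name="sample_id")))
        with caplog.at_level("WARNING", logger="turbomap"):
            mt = module_trait_correlation(model, traits)
        assert mt.empty

    def test_planted_trait_effect_detected(self, cohort_data):
        from turbomap import median_polish_normalize
        (m, d, traits, truth), cfg = cohort_data
        mn = median_polish_normalize(m, d)
        model = detect_modules(mn, design=d)
        mt = module_trait_correlation(model, traits)
        braak = mt[mt["trait"] == "braak"].set_index("module")
        best = braak["r"].abs().idxmax()
        # the planted Braak module is the largest (size 150) -> M1
        assert best == "M1"
        assert braak.loc[best, "p"] < 0.001
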