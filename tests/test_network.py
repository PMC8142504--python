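import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncosubtype.network import (CoexpressionNetwork, NetworkConfig,
                                 adjacency_matrix, detect_modules,
                                 hub_and_intersect, module_stats,
                                 pick_soft_threshold, scale_free_fit,
                                 tom_matrix)


def modular_data(seed, sizes=(40, 30, 20), n_noise=30, n_samples=50,
                 within_cor=0.7):
    """Planted-module expression: shared latent factor per module."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    lam = np.sqrt(within_cor / (1 - within_cor))
    for m, size in enumerate(sizes, start=1):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(lam * f + rng.standard_normal(n_samples))
            truth.append(m)
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        truth.append(0)
    genes = [f"g{i:03d}" for i in range(len(rows))]
    return (pd.DataFrame(rows, index=genes,
                         columns=[f"s{i}" for i in range(n_samples)]),
            pd.Series(truth, index=genes))


def tom_oracle(a):
    n = a.shape[0]
    k = a.sum(axis=0)
    t = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


class TestAdjacencyAndTom:
    def test_power_one_is_absolute_correlation(self):
        vals, _ = modular_data(0, sizes=(10,), n_noise=5, n_samples=30)
        a = adjacency_matrix(vals, 1).to_numpy()
        c = np.abs(np.corrcoef(vals.to_numpy()))
        np.fill_diagonal(c, 0)
        assert np.allclose(a, c)

    def test_complete_graph_tom(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        t = tom_matrix(a)
        off = t[~np.eye(n, dtype=bool)]
        assert np.allclose(off, 1.0)  # (n-2+1)/(n-1)

    def test_empty_graph_tom(self):
        t = tom_matrix(np.zeros((5, 5)))
        assert np.allclose(t[~np.eye(5, dtype=bool)], 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        assert np.allclose(tom_matrix(a), tom_oracle(a), atol=1e-12)

    def test_tom_bounds_and_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.random((12, 12)) * 0.9
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        t = tom_matrix(a)
        assert np.allclose(t, t.T)
        assert (t >= -1e-12).all() and (t <= 1 + 1e-12).all()

    def test_asymmetric_input_error(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_matrix(a)


class TestSoftThreshold:
    def test_scale_free_fit_matches_regression_oracle(self):
        rng = np.random.default_rng(0)
        k = rng.pareto(2.0, 400) + 0.5  # heavy-tailed degrees
        r2 = scale_free_fit(k, n_bins=10)
        # independent least-squares recomputation with the same binning rule
        edges = np.unique(np.quantile(k, np.linspace(0, 1, 11)))
        idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0,
                      len(edges) - 2)
        xs, ys = [], []
        for b in range(len(edges) - 1):
            sel = idx == b
            if sel.sum():
                xs.append(np.log10(k[sel].mean()))
                ys.append(np.log10(sel.mean() / (edges[b + 1] - edges[b])))
        xs, ys = np.array(xs), np.array(ys)
        X = np.column_stack([np.ones_like(xs), xs])
        coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
        resid = ys - X @ coef
        r2_direct = 1 - resid @ resid / np.sum((ys - ys.mean()) ** 2)
        expected = r2_direct if coef[1] <= 0 else -r2_direct
        assert r2 == pytest.approx(expected, abs=1e-10)

    def test_modular_data_reaches_target_at_moderate_power(self):
        vals, _ = modular_data(1, sizes=(50, 35, 25), n_noise=60, n_samples=60)
        pick = pick_soft_threshold(vals, NetworkConfig(powers=tuple(range(1, 13)),
                                                       scale_free_r2_target=0.8))
        assert pick["r2"][pick["beta"]] >= 0.8 or max(pick["r2"].values()) < 0.8
        assert any(v >= 0.8 for v in pick["r2"].values())

    def test_mean_connectivity_decreases_with_power(self):
        vals, _ = modular_data(2)
        pick = pick_soft_threshold(vals, NetworkConfig(powers=(1, 3, 6)))
        mk = pick["mean_connectivity"]
        assert mk[1] > mk[3] > mk[6]


class TestModules:
    def test_two_disconnected_blocks(self):
        a = np.zeros((30, 30))
        a[:15, :15] = 0.9
        a[15:, 15:] = 0.9
        np.fill_diagonal(a, 0)
        diss = 1 - tom_matrix(a)
        genes = [f"g{i}" for i in range(30)]
        mods = detect_modules(pd.DataFrame(diss, index=genes, columns=genes),
                              NetworkConfig(min_module_size=5))
        labels = mods.labels
        assert len(mods.module_ids()) == 2
        assert labels.iloc[:15].nunique() == 1
        assert labels.iloc[15:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_planted_three_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        vals, truth = modular_data(3)
        net = CoexpressionNetwork(config=NetworkConfig(
            min_module_size=10, powers=tuple(range(1, 13))))
        indicator = pd.Series(np.zeros(vals.shape[1]), index=vals.columns)
        indicator.iloc[::2] = 1.0
        net.fit(vals.T, indicator)
        planted = truth[truth > 0]
        found = net.modules_.labels.loc[planted.index]
        assert adjusted_rand_score(planted, found) >= 0.8

    def test_too_few_genes_all_unassigned(self):
        genes = [f"g{i}" for i in range(5)]
        diss = pd.DataFrame(np.ones((5, 5)) - np.eye(5), index=genes,
                            columns=genes)
        with pytest.warns(UserWarning):
            mods = detect_modules(diss, NetworkConfig(min_module_size=30))
        assert (mods.labels == 0).all()

    def test_labels_invariant_to_gene_order(self):
        vals, _ = modular_data(4, sizes=(20, 15), n_noise=10)
        cfg = NetworkConfig(min_module_size=5)
        a1 = adjacency_matrix(vals, 6)
        m1 = detect_modules(1 - tom_matrix(a1), cfg)
        shuffled = vals.sample(frac=1, random_state=0)
        a2 = adjacency_matrix(shuffled, 6)
        m2 = detect_modules(1 - tom_matrix(a2), cfg)
        # same partition up to label names
        from sklearn.metrics import adjusted_rand_score

        common = vals.index
        assert adjusted_rand_score(m1.labels.loc[common],
                                   m2.labels.loc[common]) == pytest.approx(1.0)


class TestModuleStats:
    def test_identical_gene_module(self):
        profile = np.sin(np.arange(20))
        vals = pd.DataFrame([profile] * 5 + [np.random.default_rng(0).standard_normal(20)
                                             for _ in range(3)],
                            index=[f"g{i}" for i in range(8)],
                            columns=[f"s{i}" for i in range(20)])
        from oncosubtype.network import ModuleSet

        mods = ModuleSet(pd.Series([1] * 5 + [0] * 3, index=vals.index))
        indicator = pd.Series((profile > 0).astype(float), index=vals.columns)
        st = module_stats(vals, mods, indicator)
        eig = st["eigengenes"][1].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
        assert np.allclose(st["MM"].loc[[f"g{i}" for i in range(5)], 1], 1.0)

    def test_eigengene_equals_first_right_singular_vector(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.standard_normal((10, 25)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(25)])
        from oncosubtype.network import ModuleSet

        mods = ModuleSet(pd.Series(1, index=vals.index))
        indicator = pd.Series(rng.integers(0, 2, 25).astype(float),
                              index=vals.columns)
        st = module_stats(vals, mods, indicator)
        Z = ((vals.T - vals.mean(1)) / vals.std(1, ddof=0)).T.to_numpy()
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        e = st["eigengenes"][1].to_numpy()
        assert min(np.abs(e - vt[0]).max(),
                   np.abs(e + vt[0]).max()) < 1e-9
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_eigengene_beats_random_projections(self):
        rng = np.random.default_rng(2)
        vals, _ = modular_data(5, sizes=(15,), n_noise=0, n_samples=30)
        from oncosubtype.network import ModuleSet

        mods = ModuleSet(pd.Series(1, index=vals.index))
        ind = pd.Series(rng.integers(0, 2, 30).astype(float),
                        index=vals.columns)
        st = module_stats(vals, mods, ind)
        Z = ((vals.T - vals.mean(1)) / vals.std(1, ddof=0)).T.to_numpy()
        e = st["eigengenes"][1].to_numpy()
        var_e = np.sum((Z @ e) ** 2)
        for _ in range(50):
            w = rng.standard_normal(30)
            w /= np.linalg.norm(w)
            assert np.sum((Z @ w) ** 2) <= var_e + 1e-9


class TestHubs:
    def _fake_stats(self, genes, module, mm, gs, r=0.9):
        return {
            "module_trait": pd.DataFrame({"r": [r], "p": [1e-6], "size":
                                          [len(genes)]}, index=[module]),
            "MM": pd.DataFrame({module: mm}, index=genes),
            "GS": pd.Series(gs, index=genes),
        }

    def test_identical_lists_intersect_to_themselves(self):
        from oncosubtype.network import ModuleSet

        genes = ["a", "b", "c"]
        st = self._fake_stats(genes, 1, [0.9, 0.95, 0.85], [0.8, 0.9, 0.7])
        mods = ModuleSet(pd.Series(1, index=genes))
        out = hub_and_intersect({"c1": st, "c2": st}, {"c1": mods, "c2": mods})
        assert out["intersection"] == genes

    def test_disjoint_lists_empty_intersection(self):
        from oncosubtype.network import ModuleSet

        st1 = self._fake_stats(["a", "b"], 1, [0.9, 0.9], [0.8, 0.8])
        st2 = self._fake_stats(["c", "d"], 1, [0.9, 0.9], [0.8, 0.8])
        m1 = ModuleSet(pd.Series(1, index=["a", "b"]))
        m2 = ModuleSet(pd.Series(1, index=["c", "d"]))
        out = hub_and_intersect({"c1": st1, "c2": st2}, {"c1": m1, "c2": m2})
        assert out["intersection"] == []

    def test_thresholds_applied(self):
        from oncosubtype.network import ModuleSet

        genes = ["a", "b", "c"]
        st = self._fake_stats(genes, 1, [0.9, 0.5, 0.85], [0.8, 0.9, 0.2])
        mods = ModuleSet(pd.Series(1, index=genes))
        out = hub_and_intersect({"c": st}, {"c": mods})
        assert out["hubs"]["c"] == ["a"]

    def test_shared_program_hubs_are_planted_genes(self, cohort_factory):
        """Hubs of the trait module are planted-program genes in every cohort."""
        from oncosubtype import io
        from oncosubtype.dge import call_degs

        stats_per, modules_per, planted = {}, {}, None
        for seed in (1, 2):
            c = cohort_factory(seed)
            planted = set(c.program_gene_ids) | set(c.program2_gene_ids)
            lab = c.true_labels.labels
            deg = call_degs(c.expression, lab)
            genes = deg.index[deg.is_deg].tolist()
            X = io.log2cpm(c.expression, genes=genes).T
            net = CoexpressionNetwork(config=NetworkConfig(min_module_size=10))
            net.fit(X, (lab == "sub1").astype(float).loc[X.index])
            stats_per[f"c{seed}"] = net.stats_
            modules_per[f"c{seed}"] = net.modules_
        out = hub_and_intersect(stats_per, modules_per)
        for hubs in out["hubs"].values():
            assert len(hubs) > 0
            assert set(hubs) <= planted
        assert set(out["intersection"]) <= planted
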