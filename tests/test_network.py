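"""Network contracts: signed adjacency closed forms, topological overlap
oracle, branch-cut module detection, eigengenes, kME and trait links."""

import numpy as np
import pandas as pd
import pytest

from devnet import network, synthetic


def _probes(arr, prefix="p"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])])


def _tom_bruteforce(A):
    """Independent triple-loop topological overlap."""
    n = A.shape[0]
    k = np.array([sum(A[i, u] for u in range(n) if u != i) for i in range(n)])
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            denom = min(k[i], k[j]) + 1 - A[i, j]
            out[i, j] = 0.0 if abs(denom) < 1e-12 else (shared + A[i, j]) / denom
    return out


class TestSignedAdjacency:
    def test_closed_forms_at_r_one_minus_one_zero(self):
        x = np.arange(8.0)
        rng = np.random.default_rng(0)
        X = _probes(np.vstack([x, x, -x]))
        a = network.signed_adjacency(X, beta=16)
        assert a.iloc[0, 1] == 1.0
        assert a.iloc[0, 2] == 0.0
        # orthogonal pair: r = 0 exactly by construction
        u = np.array([1.0, -1, -1, 1, 1, -1, -1, 1])
        X0 = _probes(np.vstack([x - x.mean(), u]))
        a0 = network.signed_adjacency(X0, beta=16)
        assert a0.iloc[0, 1] == pytest.approx(0.5**16, abs=1e-18)

    def test_symmetric_unit_interval(self, rng):
        for _ in range(20):
            X = _probes(rng.standard_normal((12, 9)))
            a = network.signed_adjacency(X).to_numpy()
            assert np.allclose(a, a.T)
            assert (a >= 0).all() and (a <= 1).all()

    def test_higher_beta_weakens_connections(self, rng):
        X = _probes(rng.standard_normal((10, 15)))
        a16 = network.signed_adjacency(X, beta=16).to_numpy()
        a24 = network.signed_adjacency(X, beta=24).to_numpy()
        off = ~np.eye(10, dtype=bool)
        assert (a24[off] <= a16[off] + 1e-15).all()

    def test_constant_probe_raises(self, rng):
        X = _probes(rng.standard_normal((5, 8)))
        X.iloc[2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            network.signed_adjacency(X)


class TestTopologicalOverlap:
    def test_complete_graph_gives_unit_overlap(self):
        A = pd.DataFrame(np.ones((3, 3)))
        to = network.topological_overlap(A).to_numpy()
        np.testing.assert_allclose(to, 1.0)

    def test_empty_graph_gives_zero_overlap(self):
        A = pd.DataFrame(np.eye(4))
        to = network.topological_overlap(A).to_numpy()
        np.testing.assert_allclose(to, np.eye(4))

    def test_matches_bruteforce_triple_loop(self, rng):
        for _ in range(5):
            raw = rng.uniform(size=(10, 10))
            A = (raw + raw.T) / 2
            np.fill_diagonal(A, 1.0)
            got = network.topological_overlap(pd.DataFrame(A)).to_numpy()
            np.testing.assert_allclose(got, _tom_bruteforce(A), atol=1e-12)

    def test_symmetric_unit_interval(self, rng):
        raw = rng.uniform(size=(15, 15))
        A = (raw + raw.T) / 2
        np.fill_diagonal(A, 1.0)
        to = network.topological_overlap(pd.DataFrame(A)).to_numpy()
        assert np.allclose(to, to.T)
        assert (to >= 0).all() and (to <= 1 + 1e-12).all()


def _block_data(rng, sizes=(50, 50), n_noise=0, n_samples=40, signal=3.0):
    rows, labels = [], []
    for b, size in enumerate(sizes):
        latent = rng.standard_normal(n_samples)
        rows.append(signal * latent + rng.standard_normal((size, n_samples)))
        labels += [f"M{b+1}"] * size
    if n_noise:
        rows.append(rng.standard_normal((n_noise, n_samples)))
        labels += ["unassigned"] * n_noise
    X = _probes(np.vstack(rows))
    return X, pd.Series(labels, index=X.index)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        X, truth = _block_data(rng)
        tom = network.topological_overlap(network.signed_adjacency(X))
        modules = network.detect_modules(tom)
        assert adjusted_rand_score(truth, modules.labels) == 1.0
        assert len(modules.modules) == 2

    def test_pure_noise_stays_unassigned(self):
        assigned = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _probes(rng.standard_normal((200, 60)))
            tom = network.topological_overlap(network.signed_adjacency(X))
            modules = network.detect_modules(tom, min_module_size=30)
            assigned.append((modules.labels != "unassigned").mean())
        assert np.mean(assigned) <= 0.05

    def test_min_size_above_block_size_assigns_nothing(self, rng):
        X, _ = _block_data(rng, sizes=(40, 40))
        tom = network.topological_overlap(network.signed_adjacency(X))
        modules = network.detect_modules(tom, min_module_size=41)
        assert (modules.labels == "unassigned").all()

    def test_labels_ordered_by_descending_size(self, rng):
        X, _ = _block_data(rng, sizes=(30, 80))
        tom = network.topological_overlap(network.signed_adjacency(X))
        modules = network.detect_modules(tom)
        sizes = [modules.module_sizes[m] for m in modules.modules]
        assert sizes == sorted(sizes, reverse=True)

    def test_merge_by_eigengene_correlation(self, rng):
        # two blocks with strongly correlated latents: detected separately,
        # then unified when merging by eigengene correlation is enabled
        latent = rng.standard_normal(40)
        latent2 = 0.8 * latent + 0.6 * rng.standard_normal(40)
        X = _probes(np.vstack([
            3 * latent + rng.standard_normal((40, 40)),
            3 * latent2 + rng.standard_normal((40, 40)),
        ]))
        tom = network.topological_overlap(network.signed_adjacency(X))
        split = network.detect_modules(tom)
        merged = network.detect_modules(tom, merge_cut_height=0.4, values=X)
        assert len(split.modules) == 2
        assert len(merged.modules) == 1

    def test_tiny_min_module_size_rejected(self, rng):
        X, _ = _block_data(rng, sizes=(30,))
        tom = network.topological_overlap(network.signed_adjacency(X))
        with pytest.raises(ValueError):
            network.detect_modules(tom, min_module_size=2)


class TestModuleEigengenes:
    def test_identical_probes_give_perfect_pc1(self, rng):
        base = rng.standard_normal(25)
        X = _probes(np.vstack([2 * base + 1, 5 * base - 3, base]))
        modules = network.ModuleAssignment(
            labels=pd.Series("M1", index=X.index), dendrogram=np.empty((0, 4))
        )
        me = network.module_eigengenes(X, modules)
        assert me.variance_explained["M1"] == pytest.approx(1.0)
        z = (base - base.mean()) / base.std(ddof=1)
        r = np.corrcoef(me.scores.loc["M1"], z)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert r > 0  # sign convention: follows the module mean profile

    def test_recovers_latent_eigengene_of_planted_module(self):
        cfg = synthetic.SyntheticConfig(
            n_probes=200, module_sizes=(60,), within_module_noise_sd=0.5,
            n_age_de=0, n_region_de=0, seed=6,
        )
        expr, _, _, _, truth = synthetic.generate_dataset(cfg)
        modules = network.ModuleAssignment(
            labels=truth.module_labels, dendrogram=np.empty((0, 4))
        )
        me = network.module_eigengenes(expr, modules)
        r = np.corrcoef(me.scores.loc["M1"], truth.eigengenes.loc["M1"])[0, 1]
        assert abs(r) >= 0.9

    def test_sign_convention_follows_mean_profile(self, rng):
        base = rng.standard_normal(20)
        X = _probes(3 * base + rng.normal(0, 0.2, (10, 20)))
        modules = network.ModuleAssignment(
            labels=pd.Series("M1", index=X.index), dendrogram=np.empty((0, 4))
        )
        for data in (X, -X):
            me = network.module_eigengenes(data, modules)
            sub = data.to_numpy()
            sub = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(me.scores.loc["M1"], sub.mean(0))[0, 1] >= 0

    def test_invariant_to_probe_reordering(self, rng):
        X, truth = _block_data(rng, sizes=(30,))
        modules = network.ModuleAssignment(labels=truth, dendrogram=np.empty((0, 4)))
        me1 = network.module_eigengenes(X, modules)
        shuffled = X.sample(frac=1.0, random_state=0)
        modules2 = network.ModuleAssignment(
            labels=truth[shuffled.index], dendrogram=np.empty((0, 4))
        )
        me2 = network.module_eigengenes(shuffled, modules2)
        np.testing.assert_allclose(me1.scores, me2.scores, atol=1e-10)

    def test_singleton_module_raises(self, rng):
        X = _probes(rng.standard_normal((1, 10)))
        modules = network.ModuleAssignment(
            labels=pd.Series("M1", index=X.index), dendrogram=np.empty((0, 4))
        )
        with pytest.raises(ValueError):
            network.module_eigengenes(X, modules)


class TestModuleMembership:
    @pytest.fixture()
    def fitted(self, rng):
        X, truth = _block_data(rng, sizes=(40, 40), n_noise=20)
        modules = network.ModuleAssignment(labels=truth, dendrogram=np.empty((0, 4)))
        me = network.module_eigengenes(X, modules)
        return X, modules, me

    def test_probe_equal_to_its_eigengene_is_a_hub(self, fitted):
        X, modules, me = fitted
        X2 = pd.concat([X, pd.DataFrame(me.scores.loc[["M1"]].to_numpy(),
                                        index=["clone"], columns=X.columns)])
        labels = pd.concat([modules.labels, pd.Series({"clone": "M1"})])
        modules2 = network.ModuleAssignment(labels=labels, dendrogram=np.empty((0, 4)))
        kme = network.module_membership(X2, me, modules2)
        assert kme.at["clone", "kME_M1"] == pytest.approx(1.0, abs=1e-10)
        assert bool(kme.at["clone", "hub"])

    def test_noise_probes_are_nonhubs(self, fitted):
        X, modules, me = fitted
        kme = network.module_membership(X, me, modules)
        noise = modules.labels.index[modules.labels == "unassigned"]
        assert np.abs(kme.loc[noise, ["kME_M1", "kME_M2"]].to_numpy()).max() < 0.6

    def test_matches_direct_correlation_loop(self, fitted):
        X, modules, me = fitted
        kme = network.module_membership(X, me, modules)
        for probe in X.index[:10]:
            for module in ("M1", "M2"):
                expected = np.corrcoef(X.loc[probe], me.scores.loc[module])[0, 1]
                assert kme.at[probe, f"kME_{module}"] == pytest.approx(
                    expected, abs=1e-12
                )


class TestModuleTraitCorrelation:
    def _me_from(self, vec, samples):
        scores = pd.DataFrame([vec], index=["M1"], columns=samples)
        return network.EigengeneMatrix(
            scores=scores, variance_explained=pd.Series({"M1": 1.0})
        )

    def test_indicator_eigengene_correlates_perfectly(self, toy_meta):
        design = network.trait_design(toy_meta)
        ind = design["region_HIP"].to_numpy()
        me = self._me_from((ind - ind.mean()) / ind.std(), design.index)
        corr, p = network.module_trait_correlation(me, design)
        assert corr.at["M1", "region_HIP"] == pytest.approx(1.0)
        assert p.at["M1", "region_HIP"] < 1e-12

    def test_orthogonal_trait_gives_zero_correlation(self, toy_meta):
        design = network.trait_design(toy_meta)
        region = design["region_HIP"].to_numpy()
        # alternate within each region group: orthogonal to the indicator
        vec = np.tile([1.0, -1.0], len(region) // 2)
        me = self._me_from(vec, design.index)
        corr, p = network.module_trait_correlation(me, design)
        assert corr.at["M1", "region_HIP"] == pytest.approx(0.0, abs=1e-12)
        assert p.at["M1", "region_HIP"] == pytest.approx(1.0, abs=1e-9)

    def test_planted_ramp_module_tracks_numeric_age(self):
        wins = 0
        for seed in range(20):
            cfg = synthetic.SyntheticConfig(
                n_probes=150, module_sizes=(50,),
                module_trait_profiles=({"age_ramp": 3.0},),
                n_age_de=0, n_region_de=0, seed=seed,
            )
            expr, meta, _, _, truth = synthetic.generate_dataset(cfg)
            modules = network.ModuleAssignment(
                labels=truth.module_labels, dendrogram=np.empty((0, 4))
            )
            me = network.module_eigengenes(expr, modules)
            design = network.trait_design(meta)
            corr, _ = network.module_trait_correlation(me, design)
            row = corr.loc["M1"].abs()
            if row.idxmax() == "age_months":
                wins += 1
        assert wins >= 18

    def test_constant_trait_raises(self, toy_meta):
        design = network.trait_design(toy_meta)
        design["flat"] = 1.0
        me = self._me_from(np.arange(len(design), dtype=float), design.index)
        with pytest.raises(ValueError, match="flat"):
            network.module_trait_correlation(me, design)


class TestExportTopEdges:
    @pytest.fixture()
    def small_module(self, rng):
        X, truth = _block_data(rng, sizes=(3,))
        modules = network.ModuleAssignment(labels=truth, dendrogram=np.empty((0, 4)))
        tom = network.topological_overlap(network.signed_adjacency(X))
        return tom, modules

    def test_small_module_returns_all_edges(self, small_module):
        tom, modules = small_module
        edges = network.export_top_edges(tom, modules, "M1", n=200)
        assert len(edges) == 3

    def test_n_one_returns_strongest_pair(self, small_module):
        tom, modules = small_module
        edges = network.export_top_edges(tom, modules, "M1", n=1)
        members = modules.members("M1")
        best = max(
            (tom.at[a, b] for i, a in enumerate(members) for b in members[i + 1:])
        )
        assert edges.at[0, "weight"] == pytest.approx(best)

    def test_matches_bruteforce_sort(self, rng):
        X, truth = _block_data(rng, sizes=(12,))
        modules = network.ModuleAssignment(labels=truth, dendrogram=np.empty((0, 4)))
        tom = network.topological_overlap(network.signed_adjacency(X))
        edges = network.export_top_edges(tom, modules, "M1", n=10)
        members = modules.members("M1")
        all_edges = sorted(
            (
                (-tom.at[a, b], *sorted((a, b)))
                for i, a in enumerate(members)
                for b in members[i + 1:]
            )
        )
        expected = [(b, c, -w) for w, b, c in all_edges[:10]]
        got = list(edges[["probe1", "probe2", "weight"]].itertuples(index=False,
                                                                    name=None))
        for (g1, g2, gw), (e1, e2, ew) in zip(got, expected):
            assert (g1, g2) == (e1, e2)
            assert gw == pytest.approx(ew)

    def test_undersized_module_raises(self, rng):
        X = _probes(rng.standard_normal((2, 10)))
        modules = network.ModuleAssignment(
            labels=pd.Series(["M1", "unassigned"], index=X.index),
            dendrogram=np.empty((0, 4)),
        )
        tom = network.topological_overlap(network.signed_adjacency(X))
        with pytest.raises(ValueError):
            network.export_top_edges(tom, modules, "M1")
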