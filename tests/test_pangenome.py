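"""Pangenome: minbit, Markov clustering vs an independent oracle, cluster
partitioning, and completeness-aware core/accessory classification."""

import math

import numpy as np
import pandas as pd
import pytest

import digitalmicrobe as dm
from digitalmicrobe.errors import ValidationError
from digitalmicrobe.pangenome import GenomeEntry, SimilarityEdge, subset_pangenome
from digitalmicrobe.synthetic import FixtureSpec, simulate_pangenome, simulate_protein_families


def edge(a, b, score, self_a=1.0, self_b=1.0):
    return SimilarityEdge(("G", a), ("G", b), score, self_a, self_b)


class TestMinbit:
    def test_identical_proteins_minbit_one(self):
        genomes = simulate_protein_families(0, n_genomes=2, n_shared=1, n_unique=0)
        edges = dm.compute_similarity_graph(genomes)
        assert len(edges) == 1
        assert edges[0].minbit == pytest.approx(1.0)

    def test_minbit_formula(self):
        e = SimilarityEdge(("g1", "a"), ("g2", "b"), 50.0, 100.0, 80.0)
        assert e.minbit == pytest.approx(0.625)  # 50 / min(100, 80)

    def test_unrelated_proteins_dropped(self):
        genomes = simulate_protein_families(3, n_genomes=2, n_shared=0, n_unique=2)
        edges = dm.compute_similarity_graph(genomes, minbit_threshold=0.5)
        assert edges == []


def reference_mcl(n, weighted_edges, inflation=2.0, max_iter=100, tol=1e-8):
    """Independent Markov-clustering oracle: plain-Python matrix iteration.

    Same process definition (self-loops of 1, column-normalize, expansion,
    inflation) implemented without numpy, run to convergence; clusters are
    connected components of the converged flow matrix.
    """
    M = [[0.0] * n for _ in range(n)]
    for i, j, w in weighted_edges:
        M[i][j] = max(M[i][j], w)
        M[j][i] = M[i][j]
    for i in range(n):
        M[i][i] = 1.0
    for j in range(n):
        s = sum(M[i][j] for i in range(n))
        for i in range(n):
            M[i][j] /= s
    for _ in range(max_iter):
        exp = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)] for i in range(n)]
        inf = [[exp[i][j] ** inflation for j in range(n)] for i in range(n)]
        new = [[0.0] * n for _ in range(n)]
        for j in range(n):
            s = sum(inf[i][j] for i in range(n)) or 1.0
            for i in range(n):
                new[i][j] = inf[i][j] / s
        delta = max(abs(new[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = new
        if delta < tol:
            break
    # connected components over entries > 1e-6
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            for v in range(n):
                if v not in comp and (M[u][v] > 1e-6 or M[v][u] > 1e-6):
                    stack.append(v)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestMCL:
    def test_two_disconnected_cliques(self):
        edges = []
        for clique in (["a", "b", "c"], ["x", "y", "z"]):
            for i in range(3):
                for j in range(i + 1, 3):
                    edges.append(edge(clique[i], clique[j], 1.0))
        clusters = dm.mcl_cluster(edges)
        assert len(clusters) == 2
        names = sorted(frozenset(g for _, g in c) for c in clusters)
        assert set(names) == {frozenset("abc"), frozenset("xyz")}

    def test_singleton_node(self):
        clusters = dm.mcl_cluster([], nodes=[("G", "lonely")])
        assert clusters == [{("G", "lonely")}]

    def test_empty_graph(self):
        assert dm.mcl_cluster([]) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_independent_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        weighted = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.2:
                    weighted.append((i, j, float(rng.uniform(0.3, 1.0))))
        edges = [
            edge(f"{i:02d}", f"{j:02d}", w) for i, j, w in weighted
        ]
        nodes = [("G", f"{i:02d}") for i in range(n)]
        ours = {
            frozenset(int(g) for _, g in c)
            for c in dm.mcl_cluster(edges, nodes=nodes)
        }
        assert ours == reference_mcl(n, weighted)


class TestBuildPangenome:
    def test_shared_plus_unique_gives_11_clusters(self):
        genomes = simulate_protein_families(1, n_genomes=3, n_shared=5, n_unique=2)
        store = dm.build_pangenome(genomes)
        sizes = sorted(len(c.members) for c in store.clusters.values())
        assert sizes == [1] * 6 + [3] * 5  # 6 singletons + 5 shared triads
        # the shared clusters contain one gene from every genome
        for cluster in store.clusters.values():
            if len(cluster.members) == 3:
                assert {g for g, _ in cluster.members} == set(store.genome_ids)

    def test_single_genome_rejected(self):
        genomes = simulate_protein_families(1, n_genomes=1)
        with pytest.raises(ValidationError, match="at least 2"):
            dm.build_pangenome(genomes)

    def test_duplicate_gene_within_genome_presence_binary(self):
        genomes = simulate_protein_families(2, n_genomes=2, n_shared=1, n_unique=0)
        # duplicate the shared protein inside genome 1
        genomes["G01"].proteins["shared_0_copy"] = genomes["G01"].proteins["shared_0"]
        store = dm.build_pangenome(genomes)
        assert len(store.clusters) == 1
        presence = store.presence_matrix()
        assert presence.to_numpy().tolist() == [[1, 1]]

    def test_partition_property(self):
        genomes = simulate_protein_families(4, n_genomes=3, n_shared=4, n_unique=3)
        store = dm.build_pangenome(genomes)
        total_genes = sum(len(g.proteins) for g in genomes.values())
        assert sum(len(c.members) for c in store.clusters.values()) == total_genes

    def test_clusters_per_genome_counts(self):
        genomes = simulate_protein_families(1, n_genomes=3, n_shared=5, n_unique=2)
        store = dm.build_pangenome(genomes)
        assert store.clusters_per_genome().tolist() == [7, 7, 7]


class TestBayesianPanCore:
    def test_present_everywhere_is_core(self):
        presence = pd.DataFrame(np.ones((1, 30), dtype=int),
                                index=["gc1"], columns=[f"g{i}" for i in range(30)])
        comp = {f"g{i}": 0.9 for i in range(30)}
        result = dm.bayesian_pan_core(presence, comp)
        assert result.loc["gc1", "label"] == "core"

    def test_core_loglikelihood_closed_form(self):
        # N=2, c=0.9 both, present in both: LL_core = 2 ln 0.9
        presence = pd.DataFrame([[1, 1], [1, 0], [0, 1]], columns=["a", "b"],
                                index=["gc1", "gc2", "gc3"])
        comp = {"a": 0.9, "b": 0.9}
        X = presence.to_numpy()
        c = np.array([0.9, 0.9])
        ll_core = X @ np.log(c) + (1 - X) @ np.log1p(-c)
        assert ll_core[0] == pytest.approx(2 * math.log(0.9))
        assert ll_core[0] == pytest.approx(-0.21072, abs=1e-4)

    def test_rare_cluster_is_accessory(self):
        X = np.zeros((10, 30), dtype=int)
        X[:9, :] = 1  # core background so the accessory model has a pool
        X[9, 0] = 1  # cluster present in 1 of 30 genomes
        presence = pd.DataFrame(X, index=[f"gc{i}" for i in range(10)],
                                columns=[f"g{i}" for i in range(30)])
        comp = {f"g{i}": 0.95 for i in range(30)}
        result = dm.bayesian_pan_core(presence, comp)
        assert result.loc["gc9", "label"] == "accessory"

    def test_completeness_one_limit_exact(self):
        spec = FixtureSpec(seed=5, n_genomes=20, n_core_clusters=50,
                           n_accessory_clusters=200, completeness_range=(1.0, 1.0))
        presence, comp, truth = simulate_pangenome(spec)
        assert (comp == 1.0).all()
        result = dm.bayesian_pan_core(presence, comp)
        full = presence.sum(axis=1) == presence.shape[1]
        assert (result.loc[full, "label"] == "core").all()
        assert (result.loc[~full, "label"] == "accessory").all()

    def test_recovery_under_dropout(self):
        presence, comp, truth = simulate_pangenome(FixtureSpec(seed=11))
        result = dm.bayesian_pan_core(presence, comp)
        core = truth == "core"
        sens = (result.loc[core[core].index, "label"] == "core").mean()
        false_core = (result.loc[core[~core].index, "label"] == "core").mean()
        assert sens >= 0.95
        assert false_core <= 0.05

    def test_invalid_inputs(self):
        presence = pd.DataFrame([[2]], columns=["a"], index=["gc"])
        with pytest.raises(ValidationError):
            dm.bayesian_pan_core(presence, {"a": 0.9})
        with pytest.raises(ValidationError):
            dm.bayesian_pan_core(pd.DataFrame([[1]], columns=["a"], index=["gc"]),
                                 {"a": 0.0})


class TestSubset:
    def _store(self):
        genomes = simulate_protein_families(1, n_genomes=3, n_shared=5, n_unique=2)
        store = dm.build_pangenome(genomes)
        dm.classify_pangenome(store)
        return store

    def test_core_predicate_selects_core(self):
        store = self._store()
        sub = subset_pangenome(store, lambda c: c.label == "core", "core only")
        assert all(c.label == "core" for c in sub.clusters.values())
        assert set(sub.genomes) == set(store.genomes)

    def test_subset_of_subset_equals_conjunction(self):
        store = self._store()
        p1 = lambda c: len(c.members) >= 3
        p2 = lambda c: c.label == "core"
        twice = subset_pangenome(subset_pangenome(store, p1), p2)
        once = subset_pangenome(store, lambda c: p1(c) and p2(c))
        assert set(twice.clusters) == set(once.clusters)

    def test_empty_subset_allowed(self):
        store = self._store()
        sub = subset_pangenome(store, lambda c: False, "nothing")
        assert sub.clusters == {}
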