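import numpy as np
import pytest

from funcgsr import (
    assign_elements,
    fit_efa,
    map_to_dag,
    merged_elements,
    parallel_analysis,
    promax_rotate,
)
from funcgsr.efa_gotree import FactorSolution
from funcgsr.io_formats import GoDag


def block_data(seed, n=300, k=3, m_per=10, loading=0.8):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, k))
    L = np.zeros((k * m_per, k))
    for b in range(k):
        L[b * m_per : (b + 1) * m_per, b] = loading
    X = F @ L.T + rng.standard_normal((n, k * m_per)) * np.sqrt(1 - loading**2)
    truth = np.repeat(np.arange(k), m_per)
    return X, truth


class TestParallelAnalysis:
    def test_pure_noise_retains_at_most_one_factor(self):
        hits = 0
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((200, 30))
            hits += parallel_analysis(X, seed=seed) <= 1
        assert hits >= 18

    def test_three_factor_structure_recovered(self):
        hits = 0
        for seed in range(20):
            X, _ = block_data(seed)
            hits += parallel_analysis(X, seed=seed) == 3
        assert hits >= 18

    def test_row_duplication_leaves_count_unchanged(self):
        X, _ = block_data(0, n=150)
        n1 = parallel_analysis(X, seed=0)
        n2 = parallel_analysis(np.vstack([X, X]), seed=0)
        assert n1 == n2

    def test_constant_column_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 5))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            parallel_analysis(X)


class TestPrincipalAxis:
    def test_one_factor_loadings_recovered(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((500, 1))
        L = 0.8 * np.ones((8, 1))
        X = F @ L.T + rng.standard_normal((500, 8)) * 0.6
        sol = fit_efa(X, 1)
        assert np.all(np.abs(np.abs(sol.loadings) - 0.8) < 0.1)

    def test_two_block_structure_has_no_cross_loadings(self):
        # blocks of unequal size/strength so the top eigenvalues are distinct
        # (equal blocks leave the leading eigenspace degenerate and the
        # unrotated axes free to mix)
        rng = np.random.default_rng(2)
        n = 400
        F = rng.standard_normal((n, 2))
        L = np.zeros((16, 2))
        L[:10, 0] = 0.85
        L[10:, 1] = 0.7
        X = F @ L.T + rng.standard_normal((n, 16)) * np.sqrt(1 - (L**2).sum(axis=1))
        truth = np.array([0] * 10 + [1] * 6)
        sol = fit_efa(X, 2)
        match = _match_factors(sol.loadings, truth, 2)
        for i, b in enumerate(truth):
            for kk in range(2):
                if kk != match[b]:
                    assert abs(sol.loadings[i, kk]) < 0.2

    def test_reproduced_correlations_fit_observed(self):
        X, _ = block_data(3)
        sol = fit_efa(X, 3)
        R = np.corrcoef(X, rowvar=False)
        R_hat = sol.loadings @ sol.loadings.T
        np.fill_diagonal(R_hat, 1.0)
        off = ~np.eye(len(R), dtype=bool)
        rmse = np.sqrt(np.mean((R[off] - R_hat[off]) ** 2))
        assert rmse < 0.05

    def test_factor_count_bounds_enforced(self):
        X, _ = block_data(4, k=2, m_per=4)
        with pytest.raises(ValueError):
            fit_efa(X, 8)


def _match_factors(loadings, truth, k):
    match = {}
    for b in range(k):
        block_rows = np.where(truth == b)[0]
        match[b] = int(np.abs(loadings[block_rows]).mean(axis=0).argmax())
    return match


class TestPromax:
    def test_single_factor_is_identity(self):
        X, _ = block_data(5, k=3)
        sol = fit_efa(X, 1)
        rot = promax_rotate(sol)
        np.testing.assert_allclose(rot.loadings, sol.loadings)
        np.testing.assert_allclose(rot.factor_correlations, np.eye(1))

    def test_simple_structure_is_preserved(self):
        X, truth = block_data(6)
        rot = promax_rotate(fit_efa(X, 3))
        match = _match_factors(rot.loadings, truth, 3)
        assert len(set(match.values())) == 3
        for i, b in enumerate(truth):
            for kk in range(3):
                if kk != match[b]:
                    assert abs(rot.loadings[i, kk]) < 0.15

    def test_communalities_preserved_by_rotation(self):
        X, _ = block_data(7)
        sol = fit_efa(X, 3)
        rot = promax_rotate(sol)
        h_unrot = (sol.loadings**2).sum(axis=1)
        P, Phi = rot.loadings, rot.factor_correlations
        h_rot = np.einsum("ik,kl,il->i", P, Phi, P)
        np.testing.assert_allclose(h_rot, h_unrot, atol=1e-6)


class TestAssignment:
    def _solution(self, rows):
        rows = np.asarray(rows, float)
        return FactorSolution(
            term_names=[f"t{i}" for i in range(len(rows))],
            n_factors=rows.shape[1],
            loadings=rows,
        )

    def test_threshold_rule_and_multi_assignment(self):
        sol = self._solution([[0.7, 0.1], [0.5, -0.6], [0.2, 0.3]])
        assign = assign_elements(sol, threshold=0.4)
        assert assign[0] == ["t0", "t1"]
        assert assign[1] == ["t1"]
        assert assign[-1] == ["t2"]
        assert merged_elements(assign) == ["t0", "t1"]

    def test_all_below_threshold_yields_empty_assignment(self):
        sol = self._solution([[0.1, 0.2], [0.3, 0.1]])
        assign = assign_elements(sol, threshold=0.4)
        assert assign[0] == [] and assign[1] == []
        assert assign[-1] == ["t0", "t1"]

    def test_nonpositive_threshold_rejected(self):
        sol = self._solution([[0.5]])
        with pytest.raises(ValueError):
            assign_elements(sol, threshold=0.0)


class TestGoTreeMapping:
    def _dag(self, edges, terms=None):
        if terms is None:
            terms = sorted({t for e in edges for t in e})
        return GoDag(terms={t: t for t in terms}, edges=edges)

    def test_siblings_cluster_under_common_parent(self):
        dag = self._dag([("B", "A"), ("C", "A")])
        clusters = map_to_dag(["B", "C"], dag)
        assert len(clusters) == 1
        assert clusters[0].ancestor_ids == ["A"]
        assert clusters[0].member_terms == ["B", "C"]

    def test_disconnected_subtrees_give_two_clusters(self):
        dag = self._dag([("B", "A"), ("D", "C")])
        clusters = map_to_dag(["B", "D"], dag)
        assert len(clusters) == 2

    def test_singleton_term_labels_itself(self):
        dag = self._dag([("B", "A")])
        clusters = map_to_dag(["B"], dag)
        assert clusters[0].ancestor_ids == ["B"]
        assert clusters[0].member_terms == ["B"]

    def test_minimal_common_ancestor_is_lowest(self):
        # chain D -> C -> B -> A plus sibling E -> C: MCA of {D, E} is C, not A/B
        dag = self._dag([("D", "C"), ("C", "B"), ("B", "A"), ("E", "C")])
        clusters = map_to_dag(["D", "E"], dag)
        assert clusters[0].ancestor_ids == ["C"]

    def test_members_reachable_from_ancestor(self):
        rng = np.random.default_rng(8)
        from funcgsr import gen_godag

        terms = [f"T{i}" for i in range(30)]
        dag = gen_godag(terms, branching=2, seed=1)
        chosen = [terms[i] for i in rng.choice(30, size=10, replace=False)]
        g = dag.to_networkx()
        import networkx as nx

        for cluster in map_to_dag(chosen, dag):
            for anc in cluster.ancestor_ids:
                for member in cluster.member_terms:
                    # edges run child -> parent, so walking "descendants"
                    # from a member reaches its ancestors
                    assert anc == member or anc in nx.descendants(g, member)

    def test_unknown_terms_skipped_but_empty_input_rejected(self):
        dag = self._dag([("B", "A")])
        clusters = map_to_dag(["B", "ZZZ"], dag)
        assert clusters[0].member_terms == ["B"]
        with pytest.raises(ValueError):
            map_to_dag([], dag)
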