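import itertools

import numpy as np
import pytest

from funcgsr import (
    ExpressionDataset,
    GeneSetCollection,
    build_rank_template,
    compute_functionome,
    integrate_common_genes,
    prune_gene_sets,
    rank_matching_score,
)
from funcgsr.gsr_core import RankTemplate


def brute_force_score(profile: dict, template: RankTemplate) -> float:
    """Independent oracle: loop every unordered pair explicitly."""
    genes = template.genes
    matches, total, k = 0, 0, 0
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            observed = profile[genes[i]] > profile[genes[j]]
            if observed == bool(template.pair_bits[k]):
                matches += 1
            total += 1
            k += 1
    return matches / total


def make_dataset(gene_ids, values, group="control"):
    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(
        platform_id="p",
        gene_ids=list(gene_ids),
        sample_ids=sample_ids,
        values=values,
        sample_labels={
            s: {"group": group, "disease": "D", "tissue": "t"} for s in sample_ids
        },
    )


def total_order_template(genes):
    """Template consistent with genes[0] > genes[1] > ... > genes[-1]."""
    g = len(genes)
    iu, ju = np.triu_indices(g, k=1)
    return RankTemplate(set_name="S", genes=list(genes), pair_bits=np.ones(len(iu), bool))


class TestRankMatchingScore:
    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            g = int(rng.integers(3, 9))
            genes = [f"g{i}" for i in range(g)]
            bits = rng.integers(0, 2, size=g * (g - 1) // 2).astype(bool)
            tmpl = RankTemplate(set_name="S", genes=genes, pair_bits=bits)
            profile = {gi: float(v) for gi, v in zip(genes, rng.normal(size=g))}
            assert rank_matching_score(profile, tmpl) == brute_force_score(profile, tmpl)

    @pytest.mark.parametrize("g", [3, 5, 8])
    def test_consistent_profile_scores_one_and_reversal_zero(self, g):
        genes = [f"g{i}" for i in range(g)]
        tmpl = total_order_template(genes)
        consistent = {gi: float(g - i) for i, gi in enumerate(genes)}
        reversed_ = {gi: float(i) for i, gi in enumerate(genes)}
        assert rank_matching_score(consistent, tmpl) == 1.0
        assert rank_matching_score(reversed_, tmpl) == 0.0

    @pytest.mark.parametrize("g", [3, 4, 6, 8])
    def test_adjacent_transposition_costs_exactly_one_pair(self, g):
        genes = [f"g{i}" for i in range(g)]
        tmpl = total_order_template(genes)
        values = [float(g - i) for i in range(g)]
        for k in range(g - 1):
            swapped = values.copy()
            swapped[k], swapped[k + 1] = swapped[k + 1], swapped[k]
            profile = dict(zip(genes, swapped))
            expected = 1.0 - 1.0 / (g * (g - 1) / 2)
            assert rank_matching_score(profile, tmpl) == pytest.approx(expected)

    def test_worked_three_gene_example(self):
        # template A>B>C; sample B=5, A=3, C=1: (A,B) flipped, (A,C), (B,C) kept
        tmpl = total_order_template(["A", "B", "C"])
        assert rank_matching_score({"A": 3, "B": 5, "C": 1}, tmpl) == pytest.approx(2 / 3)

    def test_missing_gene_is_an_error(self):
        tmpl = total_order_template(["A", "B", "C"])
        with pytest.raises(ValueError, match="missing"):
            rank_matching_score({"A": 1, "B": 2}, tmpl)

    def test_profile_tie_counts_against_strict_ordering(self):
        # tie A==B fails "A > B" and therefore matches the complementary bit
        tmpl = RankTemplate(set_name="S", genes=["A", "B"], pair_bits=np.array([True]))
        assert rank_matching_score({"A": 1.0, "B": 1.0}, tmpl) == 0.0
        tmpl2 = RankTemplate(set_name="S", genes=["A", "B"], pair_bits=np.array([False]))
        assert rank_matching_score({"A": 1.0, "B": 1.0}, tmpl2) == 1.0


class TestBuildRankTemplate:
    def test_majority_vote_worked_example(self):
        # (A,B) across samples: (5,3), (4,5), (1,2) -> A>B in 1 of 3 -> bit: B>A
        ds = make_dataset(["A", "B"], [[5, 4, 1], [3, 5, 2]])
        tmpl = build_rank_template(ds, "S", ["A", "B"])
        assert tmpl.pair_bits.tolist() == [False]

    def test_unanimous_ordering_is_reproduced(self):
        ds = make_dataset(["A", "B", "C"], [[3, 30], [2, 20], [1, 10]])
        tmpl = build_rank_template(ds, "S", ["A", "B", "C"])
        assert tmpl.pair_bits.tolist() == [True, True, True]

    def test_even_split_breaks_lexicographically(self):
        ds = make_dataset(["B", "A"], [[1, 2], [2, 1]])  # one vote each way
        tmpl = build_rank_template(ds, "S", ["B", "A"])
        # pair (B, A): even split; lexicographically earlier gene A wins "higher"
        assert tmpl.pair_bits.tolist() == [False]

    def test_absent_gene_is_an_error(self):
        ds = make_dataset(["A", "B"], [[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="absent"):
            build_rank_template(ds, "S", ["A", "Z"])

    def test_majority_template_maximises_mean_control_score(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(["a", "b", "c", "d", "e"], rng.normal(size=(5, 9)))
        tmpl = build_rank_template(ds, "S", ["a", "b", "c", "d", "e"])
        profiles = [
            dict(zip(ds.gene_ids, ds.values[:, j])) for j in range(ds.n_samples)
        ]
        best = np.mean([rank_matching_score(p, tmpl) for p in profiles])
        for _ in range(100):
            alt = RankTemplate(
                set_name="S",
                genes=tmpl.genes,
                pair_bits=rng.integers(0, 2, size=len(tmpl.pair_bits)).astype(bool),
            )
            alt_score = np.mean([rank_matching_score(p, alt) for p in profiles])
            assert best >= alt_score


class TestIntegration:
    def _ds(self, genes, n=2, platform="p1"):
        rng = np.random.default_rng(abs(hash(platform)) % 2**31)
        ds = make_dataset(genes, rng.normal(size=(len(genes), n)))
        ds.platform_id = platform
        ds.sample_ids = [f"{platform}_{s}" for s in ds.sample_ids]
        ds.sample_labels = {
            f"{platform}_s{i}": {"group": "control", "disease": "D", "tissue": "t"}
            for i in range(n)
        }
        return ds

    def test_intersection_of_gene_universes(self):
        a = self._ds(["A", "B", "C", "D", "E"], platform="p1")
        b = self._ds(["C", "D", "E", "F", "G"], platform="p2")
        merged = integrate_common_genes([a, b], min_common_genes=2)
        assert merged.gene_ids == ["C", "D", "E"]
        assert merged.n_samples == 4

    def test_below_threshold_rejected_naming_dataset(self):
        a = self._ds(["A", "B", "C", "D"], platform="p1")
        b = self._ds(["C", "D", "E", "F"], platform="p2")
        with pytest.raises(ValueError, match="p2"):
            integrate_common_genes([a, b], min_common_genes=4)

    def test_single_dataset_returned_unchanged(self):
        a = self._ds(["A", "B"], platform="p1")
        assert integrate_common_genes([a]) is a


class TestPruning:
    def test_restriction_and_drop_rules(self):
        coll = GeneSetCollection(
            sets={
                "keep": {"description": "", "genes": ["X", "Y", "Z"]},
                "drop": {"description": "", "genes": ["Z", "Q"]},
            }
        )
        pruned = prune_gene_sets(coll, {"X", "Y"}, min_set_size=2)
        assert pruned.names() == ["keep"]
        assert pruned.genes_of("keep") == ["X", "Y"]

    def test_no_available_genes_yields_empty_collection(self):
        coll = GeneSetCollection(sets={"s": {"description": "", "genes": ["X", "Y"]}})
        assert len(prune_gene_sets(coll, set())) == 0


class TestComputeFunctionome:
    def test_entries_bounded_and_controls_perfect_without_noise(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        mu = rng.uniform(0, 10, 20)
        vals = np.tile(mu[:, None], (1, 6))
        ds = make_dataset(genes, vals)
        coll = GeneSetCollection(
            sets={"S1": {"description": "", "genes": genes[:5]},
                  "S2": {"description": "", "genes": genes[5:12]}}
        )
        fm = compute_functionome(ds, coll)
        assert fm.gsr.min() >= 0 and fm.gsr.max() <= 1
        np.testing.assert_allclose(fm.gsr, 1.0)

    def test_requires_controls_for_template_learning(self):
        genes = ["a", "b", "c"]
        ds = make_dataset(genes, np.random.default_rng(0).normal(size=(3, 4)), group="case")
        coll = GeneSetCollection(sets={"S": {"description": "", "genes": genes}})
        with pytest.raises(ValueError, match="control"):
            compute_functionome(ds, coll)

    def test_matches_scalar_scorer(self, small_cohort, small_functionome):
        _, collection, cohort = small_cohort
        fm = small_functionome
        tmpl = fm.templates["GO_SET_0005"]
        j = 3
        profile = dict(zip(cohort.gene_ids, cohort.values[:, j]))
        k = fm.set_names.index("GO_SET_0005")
        assert fm.gsr[j, k] == pytest.approx(rank_matching_score(profile, tmpl))
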