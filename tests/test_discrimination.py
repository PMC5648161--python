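"""The greedy cluster-to-group matching statistic and its permutation null.

Oracles: the optimal injective cluster-to-group assignment (Hungarian
algorithm / brute force over maps) bounds the greedy accuracy from above,
and exhaustive enumeration of label permutations gives the exact p-value on
small instances.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from ampdisc import (
    DiscriminationModel,
    SampleMetadata,
    ValidationError,
    assess_dataset,
    greedy_accuracy,
    kmeans_pc,
    permutation_pvalue,
)
from ampdisc.discrimination import _greedy_from_contingency
from ampdisc.ordination import OrdinationResult


def optimal_misassigned(cont: np.ndarray) -> int:
    """Hungarian-optimal assignment oracle: fewest mis-assigned samples."""
    rows, cols = linear_sum_assignment(-cont)
    return int(cont.sum() - cont[rows, cols].sum())


def labels_from_lists(cluster_members):
    """[['A','A'], ['B']] -> (cluster_labels, group_labels)."""
    clusters, groups = [], []
    for c, members in enumerate(cluster_members):
        for g in members:
            clusters.append(c)
            groups.append(g)
    return clusters, groups


class TestGreedyAccuracy:
    def test_pure_clusters_are_perfect(self):
        clusters, groups = labels_from_lists([["A"] * 3, ["B"] * 3])
        acc, mapping, mis = greedy_accuracy(clusters, groups)
        assert acc == 1.0 and mis == 0
        assert mapping == {0: "A", 1: "B"}

    def test_half_misassigned_is_fifty_percent(self):
        clusters, groups = labels_from_lists([["A", "A", "B", "B"], ["B", "B", "A", "A"]])
        acc, _, mis = greedy_accuracy(clusters, groups)
        assert acc == 0.5 and mis == 4

    def test_fallback_when_top_group_taken(self):
        # clusters {g1:2, g2:1} and {g1:2}: the larger claims g1 (1 mis);
        # the smaller falls to g2 (2 mis) -> accuracy (5-3)/5 = 0.4
        clusters, groups = labels_from_lists([["g1", "g1", "g2"], ["g1", "g1"]])
        acc, mapping, mis = greedy_accuracy(clusters, groups)
        assert acc == pytest.approx(0.4) and mis == 3
        assert mapping == {0: "g1", 1: "g2"}

    def test_single_cluster_scores_largest_group_share(self):
        clusters, groups = labels_from_lists([["A", "A", "A", "B", "C"]])
        acc, _, _ = greedy_accuracy(clusters, groups)
        assert acc == pytest.approx(3 / 5)

    def test_mapping_is_injective(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            clusters = rng.integers(0, 4, size=30)
            groups = rng.choice(["a", "b", "c", "d"], size=30)
            _, mapping, _ = greedy_accuracy(clusters, groups)
            assert len(set(mapping.values())) == len(mapping)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(1)
        clusters = rng.integers(0, 3, size=40)
        groups = rng.choice(["x", "y", "z"], size=40)
        acc, _, mis = greedy_accuracy(clusters, groups)
        assert acc == pytest.approx(1 - mis / 40)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            greedy_accuracy([0, 1], ["A"])

    def test_metadata_interface(self, four_group_metadata):
        samples = four_group_metadata.sample_ids
        clusters = [0] * len(samples)
        acc, _, _ = greedy_accuracy(clusters, four_group_metadata, sample_ids=samples)
        assert acc == pytest.approx(23 / 70)  # largest group share

    def test_greedy_bounded_by_optimal_exhaustive(self):
        # every 3x3 contingency table with 1..8 samples, enumerated as
        # compositions of n into 9 cells (stars and bars)
        def compositions(n, cells):
            if cells == 1:
                yield (n,)
                return
            for first in range(n + 1):
                for rest in compositions(n - first, cells - 1):
                    yield (first, *rest)

        total_checked = 0
        for n in range(1, 9):
            for cells in compositions(n, 9):
                cont = np.asarray(cells).reshape(3, 3)
                mis_greedy, _ = _greedy_from_contingency(cont)
                mis_opt = optimal_misassigned(cont)
                assert mis_greedy >= mis_opt
                pure = (np.count_nonzero(cont, axis=1) <= 1).all()
                exclusive = (np.count_nonzero(cont, axis=0) <= 1).all()
                if pure and exclusive:
                    # groups in exclusive pure clusters: greedy is optimal (0 mis)
                    assert mis_greedy == mis_opt == 0
                total_checked += 1
        assert total_checked > 20000


class TestPermutationPvalue:
    def exact_p(self, clusters, groups):
        obs, _, _ = greedy_accuracy(clusters, groups)
        accs = [
            greedy_accuracy(list(perm), groups)[0]
            for perm in itertools.permutations(clusters)
        ]
        return sum(a > obs for a in accs) / len(accs)

    @pytest.mark.parametrize(
        "clusters,groups",
        [
            ([0, 0, 1, 1, 2, 2], ["A", "A", "B", "B", "C", "C"]),
            ([0, 0, 0, 1, 1, 1], ["A", "B", "A", "B", "A", "B"]),
            ([0, 1, 1, 1, 0], ["A", "B", "B", "A", "A"]),
        ],
    )
    def test_monte_carlo_matches_enumeration(self, clusters, groups):
        p_exact = self.exact_p(clusters, groups)
        B = 600
        p_mc, _ = permutation_pvalue(clusters, groups, n_permutations=B, seed=3)
        tol = 3 * np.sqrt(max(p_exact * (1 - p_exact), 1e-9) / B) + 1e-9
        assert abs(p_mc - p_exact) <= tol

    def test_strict_never_exceeds_add_one(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            clusters = rng.integers(0, 4, size=40)
            groups = rng.choice(["a", "b", "c", "d"], size=40)
            p_strict, _ = permutation_pvalue(clusters, groups, 300, seed=seed)
            p_add, _ = permutation_pvalue(
                clusters, groups, 300, seed=seed, mode="add_one"
            )
            assert p_strict <= p_add

    def test_constant_groups_divergence(self):
        # one group: every permutation ties the observed accuracy of 1.0
        clusters = [0, 0, 1, 1]
        groups = ["A", "A", "A", "A"]
        p_strict, _ = permutation_pvalue(clusters, groups, 100, seed=0)
        p_add, _ = permutation_pvalue(clusters, groups, 100, seed=0, mode="add_one")
        assert p_strict == 0.0 and p_add == 1.0

    def test_invariant_to_cluster_relabelling(self):
        # distinct cluster sizes, so processing order is size-determined
        clusters = np.array([0] * 10 + [1] * 7 + [2] * 4)
        rng = np.random.default_rng(6)
        groups = rng.choice(["a", "b", "c"], size=21)
        relabel = np.array([2, 0, 1])[clusters]
        p1, _ = permutation_pvalue(clusters, groups, 400, seed=9)
        p2, _ = permutation_pvalue(relabel, groups, 400, seed=9)
        assert p1 == pytest.approx(p2, abs=0.06)

    def test_seeded_reproducibility(self):
        clusters = [0, 1, 0, 1, 2, 2, 0]
        groups = ["a", "b", "a", "b", "c", "c", "a"]
        first = permutation_pvalue(clusters, groups, 200, seed=4)
        second = permutation_pvalue(clusters, groups, 200, seed=4)
        assert first[0] == second[0]
        assert np.array_equal(first[1], second[1])


def blob_ordination(centers, n_per, spread=0.05, seed=0):
    rng = np.random.default_rng(seed)
    points, ids = [], []
    for i, c in enumerate(centers):
        points.append(rng.normal(c, spread, size=(n_per, len(c))))
        ids += [f"S{i}_{j}" for j in range(n_per)]
    X = np.vstack(points)
    scores = pd.DataFrame(X, index=ids, columns=[f"PC{k+1}" for k in range(X.shape[1])])
    return OrdinationResult(
        scores=scores,
        loadings=pd.DataFrame(
            np.eye(X.shape[1]), columns=scores.columns,
            index=[f"v{k}" for k in range(X.shape[1])],
        ),
        variance_explained=np.full(X.shape[1], 1 / X.shape[1]),
    )


class TestKmeans:
    def test_separated_blobs_recovered(self):
        centers = [(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10)]
        result = blob_ordination(centers, 6)
        labels = kmeans_pc(result, k=4, seed=1)
        # each blob is one cluster: labels constant within, distinct across
        blobs = np.repeat(np.arange(4), 6)
        frame = pd.crosstab(blobs, labels)
        assert (frame.to_numpy() > 0).sum() == 4

    def test_k_equals_n_gives_singletons(self):
        result = blob_ordination([(i * 3, 0) for i in range(5)], 1)
        labels = kmeans_pc(result, k=5, n_components=2, seed=0)
        assert len(set(labels)) == 5

    def test_deterministic_given_seed(self):
        result = blob_ordination([(0, 0), (3, 3)], 10, spread=1.0)
        a = kmeans_pc(result, k=2, n_components=2, seed=5)
        b = kmeans_pc(result, k=2, n_components=2, seed=5)
        assert np.array_equal(a, b)

    def test_too_few_samples_rejected(self):
        result = blob_ordination([(0, 0)], 2)
        with pytest.raises(ValidationError):
            kmeans_pc(result, k=4)


class TestModelSurface:
    def _setup(self):
        centers = [(0, 0, 0), (8, 0, 0), (0, 8, 0), (0, 0, 8)]
        sizes = [23, 15, 10, 22]
        groups = ["upper_before", "upper_after", "middle_before", "lower_after"]
        rng = np.random.default_rng(12)
        rows, pairs = [], []
        for c, n, g in zip(centers, sizes, groups):
            for j in range(n):
                sid = f"{g}_{j}"
                rows.append(rng.normal(c, 0.3))
                pairs.append((sid, g))
        scores = pd.DataFrame(
            rows, index=[p[0] for p in pairs], columns=["PC1", "PC2", "PC3"]
        )
        return scores, SampleMetadata(pairs)

    def test_fit_on_separated_groups(self):
        scores, meta = self._setup()
        res = DiscriminationModel(scores, meta, k=4).fit(seed=2, n_permutations=500)
        assert res.accuracy == 1.0 and res.n_misassigned == 0
        assert res.p_value == 0.0
        assert res.p_value_text == "< 0.002"
        assert len(set(res.cluster_to_group.values())) == len(res.cluster_to_group)

    def test_summary_mentions_key_quantities(self):
        scores, meta = self._setup()
        res = DiscriminationModel(scores, meta, k=4).fit(seed=2, n_permutations=100)
        text = res.summary()
        assert "accuracy: 100.0%" in text
        assert "cluster" in text and "p (strict" in text

    def test_samples_without_metadata_rejected(self):
        scores, meta = self._setup()
        bad = scores.rename(index={scores.index[0]: "mystery"})
        with pytest.raises(ValidationError):
            DiscriminationModel(bad, meta)

    def test_assess_dataset_minimal_separable_case(self):
        # four singleton groups, each isolated in PC space
        result = blob_ordination([(0, 0, 0), (6, 0, 0), (0, 6, 0), (0, 0, 6)], 1)
        meta = SampleMetadata(
            list(zip(result.sample_ids,
                     ["upper_before", "upper_after", "middle_before", "lower_after"]))
        )
        res = assess_dataset(result, meta, k=4, seed=0, n_permutations=50)
        assert res.accuracy == 1.0
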