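"""Cluster-to-group discrimination accuracy with a permutation null.

This is the pipeline's core statistic.  Samples are clustered by k-means on
their leading principal-component scores with no knowledge of the group
labels, and each cluster is then matched to a sample group greedily:
clusters are processed from largest to smallest, and each claims its most
frequent group among those not already claimed by a larger cluster (falling
down the cluster's group-frequency ranking when its top groups are taken).
Cluster members not belonging to the claimed group count as mis-assigned,
and

    accuracy = 1 - (mis-assigned samples) / (total samples).

Two pure clusters of two groups score 100%; a configuration in which half
the samples sit in a cluster claimed by another group scores 50%.

Significance comes from a permutation null: the cluster-label vector is
randomly reshuffled over samples many times (group labels fixed), the
greedy accuracy recomputed each time, and the proportion of permutations
that recapitulate the groups *more* accurately than the observed clustering
is reported as the p-value ("strict" mode; an add-one variant
``(#{>=} + 1) / (B + 1)`` is available because the strict estimate can be
exactly zero).

The user-facing surface is :class:`DiscriminationModel`, whose ``fit()``
returns a :class:`DiscriminationResults` carrying the labels, the
cluster-to-group map, the accuracy, the permutation p-value and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import SampleMetadata, ValidationError
from .ordination import OrdinationResult

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# greedy matching
# --------------------------------------------------------------------------

def _contingency(
    cluster_labels: np.ndarray, group_codes: np.ndarray, k: int, n_groups: int
) -> np.ndarray:
    """k x n_groups table of co-occurrence counts."""
    return np.bincount(
        cluster_labels * n_groups + group_codes, minlength=k * n_groups
    ).reshape(k, n_groups)


def _greedy_from_contingency(cont: np.ndarray) -> tuple[int, dict[int, int]]:
    """Run the greedy matching on a cluster x group contingency table.

    Returns (n_misassigned, cluster -> group-column map).  Tie-breaks are
    deterministic: equal-size clusters in ascending cluster index; equal
    group frequencies in ascending group column (columns are ordered by
    group label upstream, so this is lexicographic on labels).  A cluster
    whose present groups are all claimed falls to the first unclaimed
    absent group; if no group remains unclaimed the cluster stays unmapped
    and contributes all its members as mis-assigned.
    """
    k, n_groups = cont.shape
    sizes = cont.sum(axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    taken: set[int] = set()
    mapping: dict[int, int] = {}
    mis = 0
    for c in order:
        row = cont[c]
        ranking = sorted(range(n_groups), key=lambda g: (-row[g], g))
        chosen = next(
            (g for g in ranking if g not in taken and row[g] > 0),
            None,
        )
        if chosen is None:  # every present group already claimed
            chosen = next((g for g in range(n_groups) if g not in taken), None)
        if chosen is None:
            mis += int(sizes[c])
            continue
        taken.add(chosen)
        mapping[c] = chosen
        mis += int(sizes[c] - row[chosen])
    return mis, mapping


def greedy_accuracy(
    cluster_labels: Sequence[int],
    groups: Sequence[str] | SampleMetadata,
    sample_ids: Sequence[str] | None = None,
) -> tuple[float, dict[int, str], int]:
    """Greedy largest-cluster-first matching accuracy.

    Parameters
    ----------
    cluster_labels : sequence of int
        Per-sample cluster indices in ``[0, k)``.
    groups : sequence of str, or SampleMetadata
        Per-sample group labels aligned with ``cluster_labels``; when a
        :class:`SampleMetadata` is given, ``sample_ids`` must supply the
        alignment and every sample must be present in the metadata.

    Returns
    -------
    (accuracy, cluster_to_group, n_misassigned)
        ``cluster_to_group`` is injective on the mapped clusters.
    """
    clusters = np.asarray(cluster_labels, dtype=int)
    if isinstance(groups, SampleMetadata):
        if sample_ids is None:
            raise ValidationError("sample_ids required when groups is SampleMetadata")
        if len(sample_ids) != len(clusters):
            raise ValidationError(
                f"{len(clusters)} cluster labels vs {len(sample_ids)} samples"
            )
        group_array = groups.labels_for(sample_ids)
    else:
        group_array = np.asarray(list(groups), dtype=object)
        if len(group_array) != len(clusters):
            raise ValidationError(
                f"{len(clusters)} cluster labels vs {len(group_array)} group labels"
            )
    if clusters.size == 0:
        raise ValidationError("empty input")
    group_names = sorted(set(group_array.tolist()))
    codes = np.asarray([group_names.index(g) for g in group_array])
    k = int(clusters.max()) + 1
    cont = _contingency(clusters, codes, k, len(group_names))
    mis, mapping = _greedy_from_contingency(cont)
    accuracy = 1.0 - mis / clusters.size
    return accuracy, {c: group_names[g] for c, g in mapping.items()}, mis


# --------------------------------------------------------------------------
# permutation null
# --------------------------------------------------------------------------

def permutation_pvalue(
    cluster_labels: Sequence[int],
    groups: Sequence[str] | SampleMetadata,
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "strict",
    sample_ids: Sequence[str] | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the greedy accuracy.

    The cluster-label vector is reshuffled over samples ``n_permutations``
    times with the group labels fixed and the greedy accuracy recomputed.
    ``strict`` mode reports the proportion of permutations scoring strictly
    higher than the observed accuracy; ``add_one`` reports
    ``(#{>= observed} + 1) / (n_permutations + 1)``, which cannot be zero.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if mode not in ("strict", "add_one"):
        raise ValidationError(f"unknown p-value mode {mode!r}")
    clusters = np.asarray(cluster_labels, dtype=int)
    if isinstance(groups, SampleMetadata):
        if sample_ids is None:
            raise ValidationError("sample_ids required when groups is SampleMetadata")
        group_array = groups.labels_for(sample_ids)
    else:
        group_array = np.asarray(list(groups), dtype=object)
    observed, _, _ = greedy_accuracy(clusters, group_array)
    group_names = sorted(set(group_array.tolist()))
    codes = np.asarray([group_names.index(g) for g in group_array])
    k = int(clusters.max()) + 1
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    n = clusters.size
    for b in range(n_permutations):
        perm = rng.permutation(clusters)
        cont = _contingency(perm, codes, k, len(group_names))
        mis, _ = _greedy_from_contingency(cont)
        null[b] = 1.0 - mis / n
    if mode == "strict":
        p = float(np.sum(null > observed) / n_permutations)
    else:
        p = float((np.sum(null >= observed) + 1) / (n_permutations + 1))
    return p, null


def format_p(p: float, n_permutations: int, mode: str = "strict") -> str:
    """Render a permutation p-value; strict zeros become '< 1/B'."""
    if mode == "strict" and p == 0.0:
        return f"< {1.0 / n_permutations:g}"
    return f"{p:g}"


# --------------------------------------------------------------------------
# k-means on PC scores
# --------------------------------------------------------------------------

def kmeans_pc(
    result: OrdinationResult,
    k: int = 4,
    n_components: int = 3,
    seed: int = 0,
    n_restarts: int = 25,
) -> np.ndarray:
    """K-means cluster labels from the first ``n_components`` PC scores.

    Lloyd's algorithm with k-means++ seeding and ``n_restarts`` seeded
    initialisations, keeping the lowest within-cluster sum of squares;
    deterministic given ``seed``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    n_components = min(n_components, result.n_components)
    X = result.scores.iloc[:, :n_components].to_numpy()
    if X.shape[0] < k:
        raise ValidationError(f"{X.shape[0]} samples < k={k}")
    model = KMeans(
        n_clusters=k, n_init=n_restarts, init="k-means++",
        random_state=seed & 0x7FFFFFFF, algorithm="lloyd",
    )
    return model.fit_predict(X)


# --------------------------------------------------------------------------
# model / results surface
# --------------------------------------------------------------------------

@dataclass
class DiscriminationResults:
    """Fitted discrimination statistic for one dataset.

    Invariants: ``accuracy == 1 - n_misassigned / n_samples`` and
    ``cluster_to_group`` is injective on mapped clusters.
    """

    cluster_labels: pd.Series
    cluster_to_group: dict[int, str]
    n_misassigned: int
    accuracy: float
    p_value: float
    null_accuracies: np.ndarray
    n_permutations: int
    p_value_mode: str
    seed: int
    k: int
    n_components: int
    dataset_label: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.cluster_labels)

    @property
    def p_value_text(self) -> str:
        return format_p(self.p_value, self.n_permutations, self.p_value_mode)

    def summary(self) -> str:
        label = f" [{self.dataset_label}]" if self.dataset_label else ""
        lines = [
            f"Cluster-to-group discrimination{label}",
            "=" * 48,
            f"samples: {self.n_samples}    k: {self.k}    "
            f"components: {self.n_components}",
            f"accuracy: {100 * self.accuracy:.1f}%   "
            f"({self.n_misassigned} mis-assigned)",
            f"permutation p ({self.p_value_mode}, B={self.n_permutations}): "
            f"{self.p_value_text}",
            f"null accuracy mean: {100 * self.null_accuracies.mean():.1f}%",
            "cluster -> group map:",
        ]
        sizes = self.cluster_labels.value_counts()
        for c in sorted(self.cluster_to_group):
            lines.append(
                f"  cluster {c} (n={int(sizes.get(c, 0))}) -> "
                f"{self.cluster_to_group[c]}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One-row tidy summary for report tables."""
        return pd.DataFrame(
            [
                {
                    "dataset": self.dataset_label,
                    "n_samples": self.n_samples,
                    "k": self.k,
                    "n_components": self.n_components,
                    "accuracy": self.accuracy,
                    "n_misassigned": self.n_misassigned,
                    "p_value": self.p_value,
                    "p_value_mode": self.p_value_mode,
                    "n_permutations": self.n_permutations,
                    "null_mean_accuracy": float(self.null_accuracies.mean()),
                    "seed": self.seed,
                }
            ]
        )


class DiscriminationModel:
    """How well do unsupervised clusters recover the known sample groups?

    Built from per-sample PC scores (an :class:`OrdinationResult` or a
    samples x components DataFrame) and group metadata; ``fit()`` runs
    k-means, the greedy matching and the permutation test.

    Examples
    --------
    >>> model = DiscriminationModel(ordination, metadata, k=4, n_components=3)
    >>> res = model.fit(seed=17, n_permutations=1000)
    >>> print(res.summary())
    """

    def __init__(
        self,
        scores: OrdinationResult | pd.DataFrame,
        metadata: SampleMetadata,
        k: int | None = None,
        n_components: int = 3,
    ) -> None:
        if isinstance(scores, OrdinationResult):
            self.dataset_label = scores.dataset_label
            scores = scores.scores
        else:
            self.dataset_label = ""
        missing = [s for s in scores.index if s not in metadata]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")
        self.scores = scores
        self.metadata = metadata
        self.groups = metadata.labels_for(list(scores.index))
        self.k = k if k is not None else len(set(self.groups.tolist()))
        self.n_components = min(n_components, scores.shape[1])

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 25,
        n_permutations: int = 1000,
        p_value_mode: str = "strict",
    ) -> DiscriminationResults:
        X = self.scores.iloc[:, : self.n_components]
        if X.shape[0] < self.k:
            raise ValidationError(f"{X.shape[0]} samples < k={self.k}")
        model = KMeans(
            n_clusters=self.k, n_init=n_restarts, init="k-means++",
            random_state=seed & 0x7FFFFFFF, algorithm="lloyd",
        )
        labels = model.fit_predict(X.to_numpy())
        accuracy, mapping, mis = greedy_accuracy(labels, self.groups)
        p, null = permutation_pvalue(
            labels, self.groups, n_permutations=n_permutations,
            seed=seed, mode=p_value_mode,
        )
        return DiscriminationResults(
            cluster_labels=pd.Series(labels, index=X.index, name="cluster"),
            cluster_to_group=mapping,
            n_misassigned=mis,
            accuracy=accuracy,
            p_value=p,
            null_accuracies=null,
            n_permutations=n_permutations,
            p_value_mode=p_value_mode,
            seed=seed,
            k=self.k,
            n_components=self.n_components,
            dataset_label=self.dataset_label,
        )


def assess_dataset(
    result: OrdinationResult,
    metadata: SampleMetadata,
    k: int = 4,
    n_components: int = 3,
    seed: int = 0,
    n_permutations: int = 1000,
    n_restarts: int = 25,
    p_value_mode: str = "strict",
) -> DiscriminationResults:
    """k-means -> greedy matching -> permutation test, bundled."""
    model = DiscriminationModel(result, metadata, k=k, n_components=n_components)
    return model.fit(
        seed=seed, n_restarts=n_restarts,
        n_permutations=n_permutations, p_value_mode=p_value_mode,
    )
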