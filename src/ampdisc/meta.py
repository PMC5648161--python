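"""Cross-marker analyses: merged-OTU PCA and PCA of per-dataset PC scores.

Two complementary views of multi-marker concordance:

* ``combine_otu_tables`` stacks the (already filtered and rarefied) tables
  of every marker over their shared samples, namespacing OTU ids by
  dataset, and the combined table goes through the standard
  scale -> PCA -> discrimination pipeline.  Loading attribution then says
  which marker's OTUs drive each combined component.
* ``pca_of_pcs`` treats each dataset's leading PC score vectors as
  variables (e.g. ``algae.PC1``) observed on the shared samples, scales
  them, and runs a second-level PCA; co-loading dataset-PCs reveal axes of
  community variation shared across taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import OtuTable, SampleMetadata, ValidationError
from .discrimination import DiscriminationResults, assess_dataset
from .io import align_samples
from .ordination import OrdinationResult, pca, remove_outliers_and_recompute

logger = logging.getLogger(__name__)

NAMESPACE_SEP = ":"


def combine_otu_tables(
    tables: Sequence[OtuTable], metadata: SampleMetadata
) -> OtuTable:
    """Row-concatenate tables over their shared samples.

    OTU ids are namespaced as ``<dataset_label>:<otu_id>`` so identical ids
    across markers never collide and each row's provenance is recoverable.
    """
    if len(tables) < 2:
        if len(tables) == 1:
            return tables[0]
        raise ValidationError("combine_otu_tables requires at least one table")
    aligned = align_samples(tables, metadata)
    frames = []
    for table in aligned:
        frame = table.counts.copy()
        frame.index = [
            f"{table.dataset_label}{NAMESPACE_SEP}{otu}" for otu in frame.index
        ]
        frames.append(frame)
    combined = pd.concat(frames, axis=0)
    logger.info(
        "combine_otu_tables: %d OTUs over %d shared samples from %d datasets",
        combined.shape[0], combined.shape[1], len(tables),
    )
    return OtuTable(combined, "combined")


def dataset_of_otu(namespaced_id: str) -> str:
    """Recover the dataset label from a namespaced combined-table OTU id."""
    return namespaced_id.split(NAMESPACE_SEP, 1)[0]


def loading_attribution(
    result: OrdinationResult, n_components: int = 3
) -> pd.DataFrame:
    """Share of each component's loading weight carried by each dataset.

    Weights are squared loadings (so shares per component sum to 1); rows
    are datasets, columns components.  Only meaningful on ordinations of a
    combined table with namespaced OTU ids.
    """
    n_components = min(n_components, result.n_components)
    datasets = [dataset_of_otu(o) for o in result.otu_ids]
    weights = result.loadings.iloc[:, :n_components] ** 2
    weights = weights.groupby(np.asarray(datasets)).sum()
    return weights / weights.sum(axis=0)


@dataclass
class CombinedReport:
    """Merged-OTU analysis bundle: ordination + discrimination + attribution."""

    ordination: OrdinationResult
    discrimination: DiscriminationResults
    attribution: pd.DataFrame

    def summary(self) -> str:
        parts = [self.ordination.summary(), "", self.discrimination.summary(), ""]
        parts.append("loading attribution (share of squared loadings per PC):")
        parts.append(self.attribution.round(3).to_string())
        return "\n".join(parts)


def combined_pca_report(
    combined: OtuTable,
    metadata: SampleMetadata,
    k: int = 4,
    n_components: int = 3,
    seed: int = 0,
    n_permutations: int = 1000,
    outlier_sd: float = 6.0,
) -> CombinedReport:
    """Standard pipeline on a combined table, plus loading attribution."""
    ordination = remove_outliers_and_recompute(combined, sd_multiplier=outlier_sd)
    discrimination = assess_dataset(
        ordination, metadata, k=k, n_components=n_components,
        seed=seed, n_permutations=n_permutations,
    )
    attribution = loading_attribution(ordination, n_components)
    return CombinedReport(ordination, discrimination, attribution)


def pca_of_pcs(
    results: Mapping[str, OrdinationResult], n_components: int = 3
) -> OrdinationResult:
    """Second-level PCA over per-dataset PC score vectors.

    Builds the samples x (datasets x n_components) matrix of scores
    (columns named ``<dataset>.PC<i>``) over the samples shared by all
    ordinations, scales each column to zero mean and unit variance, and
    decomposes it.  The returned ``loadings`` give each dataset-PC
    variable's weight on each meta-component.
    """
    if not results:
        raise ValidationError("no ordination results supplied")
    labels = list(results)
    shared = [
        s for s in results[labels[0]].sample_ids
        if all(s in set(results[l].sample_ids) for l in labels[1:])
    ]
    if len(shared) < 2:
        raise ValidationError("fewer than 2 samples shared by all ordinations")
    columns = {}
    for label in labels:
        res = results[label]
        take = min(n_components, res.n_components)
        scores = res.scores.loc[shared]
        for i in range(take):
            columns[f"{label}.PC{i + 1}"] = scores.iloc[:, i]
    matrix = pd.DataFrame(columns, index=shared)
    sd = matrix.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("pca_of_pcs: dropping constant variables: %s", constant)
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(index=constant)
    scaled = (matrix - matrix.mean(axis=0)) / sd
    meta = pca(scaled, dataset_label="meta")
    return meta
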