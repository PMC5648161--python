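"""OTU and read reduction: on-target filtering, rarefaction, abundance filter.

Three stages, applied per marker dataset in this order:

1. drop off-target OTUs (wrong lineage, or best-hit identity below the 80%
   floor; unannotated OTUs count as off-target);
2. rarefy every sample to a fixed read depth by drawing reads without
   replacement (samples below the depth are dropped);
3. drop OTUs that never reach the relative-abundance threshold (1% by
   default) in any sample.

Filters only remove rows or columns; retained counts are never altered.
"""

from __future__ import annotations

import enum
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import OtuTable, TargetSpec, TaxonomyAnnotation, ValidationError

logger = logging.getLogger(__name__)

#: Rarefaction depths used for the native-depth analysis of each marker,
#: and the common depth used when comparing markers head to head.
NATIVE_DEPTHS: dict[str, int] = {
    "bacteria": 20_000,
    "archaea": 2_000,
    "algae": 600,
    "diatom": 1_400,
    "fungus": 350,
}
COMMON_DEPTH: int = 350


class AbundanceScope(str, enum.Enum):
    """How the relative-abundance threshold is evaluated.

    ``per_sample_max`` (default): keep an OTU iff it reaches the threshold
    fraction of reads in at least one sample.  ``dataset_total``: keep an
    OTU iff its grand total reaches the threshold fraction of the table's
    grand total.
    """

    per_sample_max = "per_sample_max"
    dataset_total = "dataset_total"


def filter_on_target(
    table: OtuTable,
    annotations: Sequence[TaxonomyAnnotation],
    spec: TargetSpec,
) -> OtuTable:
    """Keep only OTUs whose annotation matches the target spec.

    An OTU is kept iff its lineage intersects the target keywords and its
    percent identity is >= ``spec.min_identity`` or absent.  OTUs with no
    annotation at all are treated as off-target (unknown sequences).
    """
    by_id = {a.otu_id: a for a in annotations}
    keep, n_unannotated, n_lineage, n_identity = [], 0, 0, 0
    for otu_id in table.otu_ids:
        ann = by_id.get(otu_id)
        if ann is None:
            n_unannotated += 1
            continue
        on_lineage = any(
            rank.lower() in spec.target_lineage_keywords for rank in ann.lineage
        )
        if not on_lineage:
            n_lineage += 1
            continue
        pid = ann.percent_identity
        if pid is not None and pid < spec.min_identity:
            n_identity += 1
            continue
        keep.append(otu_id)
    logger.info(
        "filter_on_target[%s]: kept %d/%d OTUs (dropped: %d unannotated, "
        "%d off-target lineage, %d identity < %g)",
        table.dataset_label, len(keep), table.n_otus,
        n_unannotated, n_lineage, n_identity, spec.min_identity,
    )
    if not keep:
        logger.warning("filter_on_target[%s]: no OTUs retained", table.dataset_label)
    return table.select_otus(keep)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Classic rarefaction: each sample's reads form a multiset and ``depth``
    of them are drawn without replacement (a multivariate hypergeometric
    draw over OTUs).  Samples with fewer than ``depth`` total reads are
    dropped with a warning.  Output column sums all equal ``depth``.
    """
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept_cols, dropped = [], []
    matrix = table.counts.to_numpy()
    out_cols = {}
    for j, sample_id in enumerate(table.sample_ids):
        total = int(totals.iloc[j])
        if total < depth:
            dropped.append(sample_id)
            continue
        column = matrix[:, j]
        if total == depth:
            out_cols[sample_id] = column.copy()
        else:
            out_cols[sample_id] = rng.multivariate_hypergeometric(column, depth)
        kept_cols.append(sample_id)
    if dropped:
        logger.warning(
            "rarefy[%s]: dropped %d sample(s) below depth %d: %s",
            table.dataset_label, len(dropped), depth, dropped[:10],
        )
    if not kept_cols:
        raise ValidationError(
            f"rarefy: every sample of {table.dataset_label or '<table>'} "
            f"falls below depth {depth}"
        )
    frame = pd.DataFrame(out_cols, index=table.otu_ids)[kept_cols]
    return OtuTable(frame, table.dataset_label)


def filter_low_abundance(
    table: OtuTable,
    threshold: float = 0.01,
    scope: AbundanceScope | str = AbundanceScope.per_sample_max,
) -> OtuTable:
    """Drop OTUs that never reach ``threshold`` relative abundance.

    See :class:`AbundanceScope` for the two readings of "less than 1% of the
    reads".  Zero-total samples contribute no fractions.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    scope = AbundanceScope(scope)
    matrix = table.counts.to_numpy(dtype=float)
    if scope is AbundanceScope.per_sample_max:
        totals = matrix.sum(axis=0)
        nonzero = totals > 0
        fractions = np.zeros_like(matrix)
        fractions[:, nonzero] = matrix[:, nonzero] / totals[nonzero]
        keep_mask = (fractions >= threshold).any(axis=1)
    else:
        grand = matrix.sum()
        keep_mask = (
            (matrix.sum(axis=1) / grand) >= threshold
            if grand > 0
            else np.zeros(table.n_otus, dtype=bool)
        )
    keep = [otu for otu, k in zip(table.otu_ids, keep_mask) if k]
    reads_before, reads_after = table.total_reads(), int(matrix[keep_mask].sum())
    logger.info(
        "filter_low_abundance[%s]: kept %d/%d OTUs (%.1f%% of reads) at "
        "threshold %g, scope %s",
        table.dataset_label, len(keep), table.n_otus,
        100.0 * reads_after / reads_before if reads_before else 0.0,
        threshold, scope.value,
    )
    return table.select_otus(keep)
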