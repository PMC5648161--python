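"""Per-OTU differential abundance between sample groups.

Every OTU is tested between every unordered pair of groups with an
equal-variance (Student's) two-sample t-test on per-sample counts from the
rarefied table (equal depth makes raw counts comparable; a
relative-abundance option is exposed).  The Bonferroni family spans all
OTUs x all group pairs — the most conservative reading — and an OTU is
"differential" when any of its pairs is significant after adjustment.

Also provides the "top OTUs by total read count" summary used to report a
dataset's dominant taxa alongside their annotations.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OtuTable, SampleMetadata, TaxonomyAnnotation, ValidationError

logger = logging.getLogger(__name__)


def otu_pairwise_tests(
    table: OtuTable,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    equal_var: bool = True,
    relative: bool = False,
) -> pd.DataFrame:
    """All OTU x group-pair t-tests with Bonferroni correction.

    Returns a tidy frame with columns ``otu_id, group1, group2, t_statistic,
    p_raw, p_adjusted, significant``; the family size is
    ``n_OTUs * n_pairs``.  Zero-variance-in-both-groups comparisons with
    equal means get p = 1; group pairs with fewer than 2 samples per group
    are NA.
    """
    labels = metadata.labels_for(table.sample_ids)
    groups = [g for g in metadata.allowed_groups if g in set(labels)]
    pairs = list(itertools.combinations(groups, 2))
    if not pairs:
        raise ValidationError("need at least 2 groups")
    matrix = table.counts.to_numpy(dtype=float)
    if relative:
        totals = matrix.sum(axis=0)
        totals[totals == 0] = 1.0
        matrix = matrix / totals
    family = table.n_otus * len(pairs)
    masks = {g: labels == g for g in groups}
    rows = []
    for i, otu_id in enumerate(table.otu_ids):
        values = matrix[i]
        for g1, g2 in pairs:
            x, y = values[masks[g1]], values[masks[g2]]
            if len(x) < 2 or len(y) < 2:
                t_stat, p_raw = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    # constant inputs are handled explicitly below
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t_stat, p_raw = stats.ttest_ind(x, y, equal_var=equal_var)
                if np.isnan(p_raw):
                    # both groups constant; equal means are a perfect null
                    t_stat, p_raw = (0.0, 1.0) if np.isclose(x.mean(), y.mean()) else (np.inf, 0.0)
            rows.append((otu_id, g1, g2, t_stat, p_raw))
    frame = pd.DataFrame(
        rows, columns=["otu_id", "group1", "group2", "t_statistic", "p_raw"]
    )
    frame["p_adjusted"] = np.minimum(1.0, frame["p_raw"] * family)
    frame["significant"] = frame["p_adjusted"] < alpha
    n_hits = frame[frame["significant"]]["otu_id"].nunique()
    logger.info(
        "otu_pairwise_tests[%s]: %d/%d OTUs differ between at least two "
        "groups (alpha=%g, family=%d)",
        table.dataset_label, n_hits, table.n_otus, alpha, family,
    )
    return frame


def differential_otus(results: pd.DataFrame) -> list[str]:
    """OTUs significant in at least one group pair, in table order."""
    hits = results.loc[results["significant"], "otu_id"]
    return list(dict.fromkeys(hits))


def top_otus_by_reads(
    table: OtuTable,
    annotations: Sequence[TaxonomyAnnotation] = (),
    n: int = 10,
) -> pd.DataFrame:
    """The ``n`` most abundant OTUs by total reads, with their annotations.

    Ties are broken by OTU id so the ranking is deterministic; ``n`` larger
    than the OTU count returns all OTUs.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    totals = table.otu_totals()
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    by_id = {a.otu_id: a for a in annotations}
    rows = []
    for otu_id, total in ranked:
        ann = by_id.get(otu_id)
        rows.append(
            {
                "otu_id": otu_id,
                "total_reads": int(total),
                "lineage": ";".join(ann.lineage) if ann else "",
                "percent_identity": (
                    "ND" if ann is None or ann.percent_identity is None
                    else ann.percent_identity
                ),
            }
        )
    return pd.DataFrame(rows)
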