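"""Core data containers shared across the pipeline.

The unit of analysis is the :class:`OtuTable`: an integer count matrix of
OTUs (rows) by water samples (columns), tagged with the marker dataset it
came from (e.g. ``"bacteria"`` for 16S, ``"algae"`` for 23S).  Taxonomy
annotations carry each OTU's best-hit lineage and percent identity, which
drive on-target filtering; sample metadata assigns each sample to one of the
study groups (river section x rain epoch), the ground truth the
discrimination statistic is scored against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four sample groups of the default study design
#: (river section x before/after the major rain event).
DEFAULT_GROUPS: tuple[str, ...] = (
    "upper_before",
    "upper_after",
    "middle_before",
    "lower_after",
)


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class TaxonomyAnnotation:
    """Best-BLAST-hit annotation for one OTU.

    Parameters
    ----------
    otu_id : str
        OTU identifier matching a row of the count table.
    lineage : tuple of str
        Ordered rank labels (kingdom ... species); missing ranks allowed.
        Rank prefixes such as ``k__`` are stripped at parse time.
    percent_identity : float or None
        Best-hit percent identity in [0, 100]. ``None`` means the OTU was
        assigned from a curated reference database rather than a BLAST hit
        (rendered ``ND`` in tabular output).
    """

    otu_id: str
    lineage: tuple[str, ...]
    percent_identity: float | None = None

    def __post_init__(self) -> None:
        pid = self.percent_identity
        if pid is not None and not (0.0 <= pid <= 100.0):
            raise ValidationError(
                f"percent identity for {self.otu_id!r} out of [0, 100]: {pid}"
            )


class SampleMetadata:
    """Immutable mapping of sample id -> group label.

    Group labels are restricted to a declared finite label set so that typos
    in metadata files surface as errors rather than phantom groups.
    """

    def __init__(
        self,
        assignments: Mapping[str, str] | Iterable[tuple[str, str]],
        allowed_groups: Sequence[str] = DEFAULT_GROUPS,
    ) -> None:
        pairs = list(assignments.items()) if isinstance(assignments, Mapping) else list(assignments)
        seen: dict[str, str] = {}
        allowed = tuple(dict.fromkeys(allowed_groups))
        for sample_id, group in pairs:
            if sample_id in seen:
                raise ValidationError(f"duplicate sample id in metadata: {sample_id!r}")
            if group not in allowed:
                raise ValidationError(
                    f"sample {sample_id!r} has unknown group {group!r}; "
                    f"allowed: {sorted(allowed)}"
                )
            seen[sample_id] = group
        self._groups = pd.Series(seen, dtype=object, name="group")
        self._allowed = allowed

    @property
    def sample_ids(self) -> list[str]:
        return list(self._groups.index)

    @property
    def allowed_groups(self) -> tuple[str, ...]:
        return self._allowed

    @property
    def groups(self) -> pd.Series:
        """Sample id -> group label, in insertion order."""
        return self._groups.copy()

    def group_of(self, sample_id: str) -> str:
        return str(self._groups[sample_id])

    def group_sizes(self) -> pd.Series:
        return self._groups.value_counts()

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self._groups.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing[:5]}")
        return SampleMetadata(
            [(s, str(self._groups[s])) for s in sample_ids], self._allowed
        )

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Group labels aligned to ``sample_ids`` as an object array."""
        return np.asarray([self.group_of(s) for s in sample_ids], dtype=object)

    def __len__(self) -> int:
        return len(self._groups)

    def __contains__(self, sample_id: object) -> bool:
        return sample_id in self._groups.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self._allowed == other._allowed and self._groups.equals(other._groups)

    def __repr__(self) -> str:
        sizes = ", ".join(f"{g}={n}" for g, n in self.group_sizes().items())
        return f"<SampleMetadata n={len(self)} ({sizes})>"


class OtuTable:
    """Integer OTU count matrix (OTUs x samples) with a dataset label.

    Wraps a pandas DataFrame with OTU ids on the index and sample ids on the
    columns; counts are validated to be non-negative integers, and both id
    axes must be duplicate-free.
    """

    def __init__(self, counts: pd.DataFrame, dataset_label: str = "") -> None:
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at OTU {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}"
                )
            if not np.allclose(values, np.round(values), rtol=0, atol=0):
                r, c = np.argwhere(values != np.round(values))[0]
                raise ValidationError(
                    f"non-integer count at OTU {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}: {values[r, c]}"
                )
        self._counts = counts.astype(np.int64)
        self._counts.index = self._counts.index.astype(str)
        self._counts.columns = self._counts.columns.astype(str)
        self._counts.index.name = "#OTU ID"
        self.dataset_label = dataset_label

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        otu_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        dataset_label: str = "",
    ) -> "OtuTable":
        counts = np.asarray(counts)
        if counts.shape != (len(otu_ids), len(sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(otu_ids)} OTUs x {len(sample_ids)} samples"
            )
        frame = pd.DataFrame(counts, index=list(otu_ids), columns=list(sample_ids))
        return cls(frame, dataset_label)

    # -- accessors ------------------------------------------------------------

    @property
    def counts(self) -> pd.DataFrame:
        return self._counts

    @property
    def otu_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._counts.shape

    @property
    def n_otus(self) -> int:
        return self._counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self._counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self._counts.sum(axis=0)

    def otu_totals(self) -> pd.Series:
        return self._counts.sum(axis=1)

    def total_reads(self) -> int:
        return int(self._counts.to_numpy().sum())

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self._counts.loc[list(otu_ids)], self.dataset_label)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self._counts[list(sample_ids)], self.dataset_label)

    def relabel(self, dataset_label: str) -> "OtuTable":
        return OtuTable(self._counts, dataset_label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.dataset_label == other.dataset_label
            and self._counts.equals(other._counts)
        )

    def __repr__(self) -> str:
        label = f" [{self.dataset_label}]" if self.dataset_label else ""
        return f"<OtuTable{label} {self.n_otus} OTUs x {self.n_samples} samples>"


@dataclass(frozen=True)
class TargetSpec:
    """What counts as an on-target OTU for one marker dataset.

    An OTU is on-target when its lineage contains any of the target keywords
    (case-insensitive) and its percent identity is at least ``min_identity``
    or absent (reference-database assignments carry no identity).
    """

    target_lineage_keywords: frozenset[str]
    min_identity: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValidationError(f"min_identity out of [0, 100]: {self.min_identity}")
        object.__setattr__(
            self,
            "target_lineage_keywords",
            frozenset(k.lower() for k in self.target_lineage_keywords),
        )

    def matches(self, annotation: TaxonomyAnnotation) -> bool:
        on_lineage = any(
            rank.lower() in self.target_lineage_keywords for rank in annotation.lineage
        )
        pid = annotation.percent_identity
        return on_lineage and (pid is None or pid >= self.min_identity)
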