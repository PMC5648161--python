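"""Readers and writers for the three tab-delimited interchange formats.

* OTU table: the classic tab-delimited dialect (``#OTU ID`` header cell
  followed by sample-id columns; one OTU per row, plain integer counts).
* Taxonomy: three columns ``otu_id``, ``lineage`` (``;``-joined ranks,
  optional Greengenes-style ``k__`` prefixes tolerated), ``percent_identity``
  (``ND`` for reference-database assignments with no BLAST identity).
* Metadata: two columns ``sample_id``, ``group`` with a header row.

Parsing is strict by design: malformed cells raise instead of being coerced,
because downstream rarefaction draws reads without replacement and needs
exact integer counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_GROUPS,
    FormatError,
    OtuTable,
    SampleMetadata,
    TaxonomyAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

OTU_HEADER = "#OTU ID"
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "d__")


def read_otu_table(path: str | Path, dataset_label: str = "") -> OtuTable:
    """Read a classic tab-delimited OTU table.

    The first header cell must be ``#OTU ID``; remaining header cells are
    sample ids.  Comment lines before the header (e.g. ``# Constructed from
    biom file``) are skipped.  Every body cell must parse as a non-negative
    integer.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith(OTU_HEADER):
            header_idx = i
            break
        if not line.startswith("#"):
            break
    if header_idx is None:
        raise FormatError(f"{path}: no '{OTU_HEADER}' header line found")
    header = lines[header_idx].split("\t")
    if header[0] != OTU_HEADER:
        raise FormatError(f"{path}: first header cell is {header[0]!r}, not '{OTU_HEADER}'")
    sample_ids = header[1:]
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        otu_ids.append(cells[0])
        row = []
        for sample_id, cell in zip(sample_ids, cells[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric count for OTU {cells[0]!r}, "
                    f"sample {sample_id!r}: {cell!r}"
                ) from None
            if value < 0 or value != int(value):
                raise ValidationError(
                    f"{path}:{lineno}: count must be a non-negative integer for "
                    f"OTU {cells[0]!r}, sample {sample_id!r}: {cell!r}"
                )
            row.append(int(value))
        rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(otu_ids), len(sample_ids))
    return OtuTable.from_arrays(otu_ids, sample_ids, counts, dataset_label)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a table in the classic dialect; plain integers, no separators."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([OTU_HEADER, *table.sample_ids]) + "\n")
        matrix = table.counts.to_numpy()
        for otu_id, row in zip(table.otu_ids, matrix):
            fh.write(otu_id + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a ``;``-joined lineage, stripping rank prefixes and blanks."""
    ranks = []
    for part in text.split(";"):
        part = part.strip()
        for prefix in _RANK_PREFIXES:
            if part.startswith(prefix):
                part = part[len(prefix) :]
                break
        if part and part.upper() not in ("NA", "NONE"):
            ranks.append(part)
    return tuple(ranks)


def read_taxonomy(path: str | Path) -> list[TaxonomyAnnotation]:
    """Read the 3-column taxonomy TSV (otu_id, lineage, percent_identity|ND)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, header=0)
    expected = ["otu_id", "lineage", "percent_identity"]
    if list(frame.columns[:3]) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    annotations = []
    for _, row in frame.iterrows():
        raw = row["percent_identity"]
        if pd.isna(raw) or str(raw).strip().upper() == "ND":
            identity = None
        else:
            try:
                identity = float(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}: bad percent identity for {row['otu_id']!r}: {raw!r}"
                ) from None
        lineage = parse_lineage("" if pd.isna(row["lineage"]) else str(row["lineage"]))
        annotations.append(TaxonomyAnnotation(str(row["otu_id"]), lineage, identity))
    return annotations


def write_taxonomy(annotations: Sequence[TaxonomyAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("otu_id\tlineage\tpercent_identity\n")
        for ann in annotations:
            pid = "ND" if ann.percent_identity is None else f"{ann.percent_identity:g}"
            fh.write(f"{ann.otu_id}\t{';'.join(ann.lineage)}\t{pid}\n")


def read_metadata(
    path: str | Path, allowed_groups: Sequence[str] = DEFAULT_GROUPS
) -> SampleMetadata:
    """Read the 2-column metadata TSV (sample_id, group)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if list(frame.columns[:2]) != ["sample_id", "group"]:
        raise FormatError(
            f"{path}: expected columns ['sample_id', 'group'], got {list(frame.columns)}"
        )
    if frame.empty:
        logger.warning("%s: empty metadata file", path)
    pairs = [(str(r["sample_id"]), str(r["group"])) for _, r in frame.iterrows()]
    return SampleMetadata(pairs, allowed_groups)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample_id, group in metadata.groups.items():
            fh.write(f"{sample_id}\t{group}\n")


def align_samples(
    tables: Sequence[OtuTable], metadata: SampleMetadata
) -> list[OtuTable]:
    """Restrict tables to the samples present in all tables and in metadata.

    Sample order follows the first table's column order so repeated runs are
    byte-stable.  Dropped samples are logged per table.
    """
    if not tables:
        raise ValidationError("align_samples requires at least one table")
    shared = [s for s in tables[0].sample_ids if s in metadata]
    for table in tables[1:]:
        members = set(table.sample_ids)
        shared = [s for s in shared if s in members]
    if not shared:
        raise ValidationError("no samples shared by all tables and the metadata")
    aligned = []
    for table in tables:
        dropped = sorted(set(table.sample_ids) - set(shared))
        if dropped:
            logger.info(
                "align_samples: dropping %d sample(s) from %s: %s",
                len(dropped), table.dataset_label or "<table>", dropped[:10],
            )
        aligned.append(table.select_samples(shared))
    return aligned
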