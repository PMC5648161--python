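"""Study-level orchestration: per-dataset and cross-dataset workflows.

One config drives the whole analysis: for every marker dataset, taxonomic
filtering -> rarefaction (native or common depth) -> low-abundance filter
-> PCA with the outlier loop -> discrimination -> differential tests; then
the two cross-dataset analyses (merged-OTU PCA and PCA-of-PCs).  Every
stage's seed is derived from the master seed and the stage/dataset tokens,
so adding a dataset never perturbs another's draws, and a run manifest
records inputs, parameters and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from ._seeding import derive_seed
from .containers import (
    DEFAULT_GROUPS,
    OtuTable,
    SampleMetadata,
    TargetSpec,
    TaxonomyAnnotation,
    ValidationError,
)
from .differential import otu_pairwise_tests, top_otus_by_reads
from .discrimination import DiscriminationResults, assess_dataset
from .filtering import (
    COMMON_DEPTH,
    NATIVE_DEPTHS,
    filter_low_abundance,
    filter_on_target,
    rarefy,
)
from .io import read_metadata, read_otu_table, read_taxonomy, write_otu_table
from .meta import CombinedReport, combine_otu_tables, combined_pca_report, pca_of_pcs
from .ordination import OrdinationResult, pc_group_tests, remove_outliers_and_recompute

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetEntry:
    """Paths and target definition for one marker dataset."""

    label: str
    table_path: str
    taxonomy_path: str
    target_keywords: tuple[str, ...] = ()
    min_identity: float = 80.0
    depth: int | None = None  # native rarefaction depth; falls back to NATIVE_DEPTHS

    def target_spec(self) -> TargetSpec:
        keywords = self.target_keywords or (self.label.capitalize(),)
        return TargetSpec(frozenset(keywords), self.min_identity)

    def native_depth(self) -> int:
        if self.depth is not None:
            return self.depth
        if self.label in NATIVE_DEPTHS:
            return NATIVE_DEPTHS[self.label]
        raise ValidationError(f"no rarefaction depth known for {self.label!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the full study."""

    datasets: tuple[DatasetEntry, ...]
    metadata_path: str
    groups: tuple[str, ...] = DEFAULT_GROUPS
    common_depth: int = COMMON_DEPTH
    abundance_threshold: float = 0.01
    k: int = 4
    n_components: int = 3
    n_permutations: int = 1000
    seed: int = 0
    outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.common_depth < 1:
            raise ValidationError("common_depth must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        entries = tuple(
            DatasetEntry(
                label=d["label"],
                table_path=d["table"],
                taxonomy_path=d["taxonomy"],
                target_keywords=tuple(d.get("targets", ())),
                min_identity=float(d.get("min_identity", 80.0)),
                depth=d.get("depth"),
            )
            for d in raw["datasets"]
        )
        fields = {
            k: raw[k]
            for k in (
                "common_depth", "abundance_threshold", "k", "n_components",
                "n_permutations", "seed", "outlier_sd",
            )
            if k in raw
        }
        if "groups" in raw:
            fields["groups"] = tuple(raw["groups"])
        return cls(datasets=entries, metadata_path=raw["metadata"], **fields)


@dataclass
class DatasetResult:
    """Outputs of the per-dataset pipeline for one marker."""

    label: str
    table: OtuTable  # filtered + rarefied + abundance-filtered
    ordination: OrdinationResult
    discrimination: DiscriminationResults
    pc_tests: pd.DataFrame
    differential: pd.DataFrame
    top_otus: pd.DataFrame
    depth: int


def analyze_dataset(
    table: OtuTable,
    annotations: Sequence[TaxonomyAnnotation],
    metadata: SampleMetadata,
    target_spec: TargetSpec,
    depth: int,
    abundance_threshold: float = 0.01,
    k: int = 4,
    n_components: int = 3,
    n_permutations: int = 1000,
    seed: int = 0,
    outlier_sd: float = 6.0,
) -> DatasetResult:
    """The per-dataset pipeline on in-memory objects."""
    label = table.dataset_label
    on_target = filter_on_target(table, annotations, target_spec)
    rarefied = rarefy(on_target, depth, seed=derive_seed(seed, "rarefy", label))
    filtered = filter_low_abundance(rarefied, abundance_threshold)
    kept_meta = metadata.subset(filtered.sample_ids)
    ordination = remove_outliers_and_recompute(filtered, sd_multiplier=outlier_sd)
    meta_for_scores = metadata.subset(ordination.sample_ids)
    discrimination = assess_dataset(
        ordination, meta_for_scores, k=k, n_components=n_components,
        seed=derive_seed(seed, "discriminate", label),
        n_permutations=n_permutations,
    )
    tests = pc_group_tests(ordination, meta_for_scores, n_components=n_components)
    diff = otu_pairwise_tests(
        filtered.select_samples(ordination.sample_ids), meta_for_scores
    )
    top = top_otus_by_reads(filtered, annotations)
    return DatasetResult(
        label=label, table=filtered, ordination=ordination,
        discrimination=discrimination, pc_tests=tests,
        differential=diff, top_otus=top, depth=depth,
    )


def run_per_dataset(
    cfg: PipelineConfig, mode: str = "native_depth"
) -> dict[str, DatasetResult]:
    """Run the per-dataset pipeline for every configured marker.

    ``mode`` selects each dataset's own depth (``native_depth``) or the
    shared ``common_depth``.  A failing dataset is logged and skipped;
    the others proceed.
    """
    if mode not in ("native_depth", "common_depth"):
        raise ValidationError(f"unknown mode {mode!r}")
    metadata = read_metadata(cfg.metadata_path, cfg.groups)
    outputs: dict[str, DatasetResult] = {}
    for entry in cfg.datasets:
        depth = entry.native_depth() if mode == "native_depth" else cfg.common_depth
        try:
            table = read_otu_table(entry.table_path, entry.label)
            annotations = read_taxonomy(entry.taxonomy_path)
            outputs[entry.label] = analyze_dataset(
                table, annotations, metadata, entry.target_spec(), depth,
                abundance_threshold=cfg.abundance_threshold, k=cfg.k,
                n_components=cfg.n_components,
                n_permutations=cfg.n_permutations,
                seed=cfg.seed, outlier_sd=cfg.outlier_sd,
            )
        except Exception:
            logger.exception("dataset %s failed; continuing", entry.label)
    return outputs


@dataclass
class CrossDatasetResult:
    combined: CombinedReport
    meta_ordination: OrdinationResult
    meta_discrimination: DiscriminationResults


def run_cross_dataset(
    cfg: PipelineConfig, per_dataset: Mapping[str, DatasetResult]
) -> CrossDatasetResult | None:
    """Merged-OTU PCA and PCA-of-PCs over the successful datasets."""
    if len(per_dataset) < 2:
        logger.warning(
            "cross-dataset stage skipped: only %d successful dataset(s)",
            len(per_dataset),
        )
        return None
    metadata = read_metadata(cfg.metadata_path, cfg.groups)
    tables = [r.table for r in per_dataset.values()]
    combined = combine_otu_tables(tables, metadata)
    report = combined_pca_report(
        combined, metadata.subset(combined.sample_ids), k=cfg.k,
        n_components=cfg.n_components,
        seed=derive_seed(cfg.seed, "discriminate", "combined"),
        n_permutations=cfg.n_permutations, outlier_sd=cfg.outlier_sd,
    )
    meta_ord = pca_of_pcs(
        {label: r.ordination for label, r in per_dataset.items()},
        n_components=cfg.n_components,
    )
    meta_disc = assess_dataset(
        meta_ord, metadata.subset(meta_ord.sample_ids), k=cfg.k,
        n_components=cfg.n_components,
        seed=derive_seed(cfg.seed, "discriminate", "meta"),
        n_permutations=cfg.n_permutations,
    )
    return CrossDatasetResult(report, meta_ord, meta_disc)


def _write_dataset_outputs(result: DatasetResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.ordination.scores.to_csv(out / "scores.tsv", sep="\t")
    result.ordination.loadings.to_csv(out / "loadings.tsv", sep="\t")
    pd.Series(
        result.ordination.variance_explained,
        index=[f"PC{i+1}" for i in range(len(result.ordination.variance_explained))],
        name="variance_explained",
    ).to_csv(out / "variance.tsv", sep="\t")
    result.pc_tests.to_csv(out / "pc_tests.tsv", sep="\t", index=False)
    result.differential.to_csv(out / "differential.tsv", sep="\t", index=False)
    result.top_otus.to_csv(out / "top_otus.tsv", sep="\t", index=False)
    result.discrimination.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    write_otu_table(result.table, out / "filtered_table.tsv")


def run_all(
    cfg: PipelineConfig, out_dir: str | Path, mode: str = "native_depth",
    plots: bool = False,
) -> tuple[dict[str, DatasetResult], CrossDatasetResult | None]:
    """Full study run with TSV outputs and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_dataset = run_per_dataset(cfg, mode=mode)
    for label, result in per_dataset.items():
        _write_dataset_outputs(result, out / label)
        if plots:
            _plot_dataset(result, out / label)
    cross = run_cross_dataset(cfg, per_dataset)
    if cross is not None:
        combined_dir = out / "combined"
        combined_dir.mkdir(exist_ok=True)
        cross.combined.ordination.scores.to_csv(combined_dir / "scores.tsv", sep="\t")
        cross.combined.attribution.to_csv(combined_dir / "attribution.tsv", sep="\t")
        cross.combined.discrimination.to_frame().to_csv(
            combined_dir / "report.tsv", sep="\t", index=False
        )
        meta_dir = out / "meta"
        meta_dir.mkdir(exist_ok=True)
        cross.meta_ordination.scores.to_csv(meta_dir / "scores.tsv", sep="\t")
        cross.meta_ordination.loadings.to_csv(meta_dir / "loadings.tsv", sep="\t")
        cross.meta_discrimination.to_frame().to_csv(
            meta_dir / "report.tsv", sep="\t", index=False
        )
    manifest = {
        "ampdisc_version": __version__,
        "python": platform.python_version(),
        "mode": mode,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": {
            label: {
                "rarefy": derive_seed(cfg.seed, "rarefy", label),
                "discriminate": derive_seed(cfg.seed, "discriminate", label),
            }
            for label in [e.label for e in cfg.datasets]
        },
        "datasets_completed": sorted(per_dataset),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return per_dataset, cross


def _plot_dataset(result: DatasetResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    # metadata restricted to retained samples
    ord_res = result.ordination
    ord_res.plot(components=(1, 2), ax=axes[0])
    if ord_res.n_components >= 3:
        ord_res.plot(components=(2, 3), ax=axes[1])
    fig.suptitle(f"{result.label} (depth {result.depth})")
    fig.tight_layout()
    fig.savefig(out / "pca.png", dpi=100)
    plt.close(fig)
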