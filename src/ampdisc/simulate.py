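"""Synthetic multi-marker amplicon study generator.

Emulates the statistical structure the downstream analysis assumes, without
any real sequencing data: group-structured community compositions,
off-target amplification, a poor-identity stratum, and uneven per-sample
sequencing depth.

The composition model is deliberately simple and overdispersed:

* a log-normal baseline abundance per OTU (spread ``base_abundance_sigma``);
* a subset of "differential" OTUs whose abundance is multiplied by
  ``2**(s * effect_size)`` in each group, with the sign ``s in {-1, 0, +1}``
  drawn per OTU x group from the seeded stream, so group centroids are
  distinct and not collinear;
* per-sample depth drawn gamma-Poisson around ``mean_depth`` (so the
  rarefaction stage genuinely drops some samples);
* integer counts multinomial given the sample's group composition.

A study is a list of such datasets observed on one shared set of water
samples; per-dataset effect sizes let one marker be made "algae-like"
(strong group signal) and another "fungus-like" (weak).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seeding import rng_for
from .containers import (
    DEFAULT_GROUPS,
    OtuTable,
    SampleMetadata,
    TaxonomyAnnotation,
    ValidationError,
)

#: Group sizes of the default study design: 70 river-water samples over
#: four location x rain-epoch groups.
DEFAULT_GROUP_SIZES: tuple[tuple[str, int], ...] = (
    ("upper_before", 23),
    ("upper_after", 15),
    ("middle_before", 10),
    ("lower_after", 22),
)

_OFFTARGET_POOL = (
    ("Metazoa", "Insecta"),
    ("Metazoa", "Arachnida"),
    ("Metazoa", "Actinopterygii"),
    ("Viridiplantae", "Streptophyta"),
    ("Bacteria_offtarget", "Cyanobacteria_offtarget"),
)


@dataclass(frozen=True)
class DatasetConfig:
    """Per-marker generator settings.

    ``effect_size`` is the log2 fold-change applied to differential OTUs in
    affected groups; ``frac_offtarget`` and ``frac_low_identity`` strata are
    exact OTU counts (rounded) under the seeded assignment;
    ``identity_absent`` marks reference-database datasets whose on-target
    annotations carry no percent identity (``ND``).
    """

    label: str
    n_otus: int = 200
    frac_differential: float = 0.3
    effect_size: float = 2.0
    base_abundance_sigma: float = 1.0
    mean_depth: int = 1000
    depth_dispersion: float = 0.05
    frac_offtarget: float = 0.2
    frac_low_identity: float = 0.05
    identity_low: float = 70.0
    identity_absent: bool = False
    target_keyword: str | None = None

    def __post_init__(self) -> None:
        for name in ("frac_differential", "frac_offtarget", "frac_low_identity"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} out of [0, 1]: {value}")
        if self.mean_depth < 1:
            raise ValidationError(f"mean_depth must be >= 1: {self.mean_depth}")
        if self.effect_size < 0 or self.base_abundance_sigma <= 0:
            raise ValidationError("effect_size must be >= 0 and sigma > 0")
        if self.depth_dispersion < 0:
            raise ValidationError("depth_dispersion must be >= 0")
        if not (0.0 <= self.identity_low <= 100.0):
            raise ValidationError(f"identity_low out of [0, 100]: {self.identity_low}")

    @property
    def target(self) -> str:
        return self.target_keyword or self.label.capitalize()


@dataclass(frozen=True)
class SimulationConfig:
    """Full study configuration: shared samples, one entry per marker."""

    seed: int
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUP_SIZES
    datasets: tuple[DatasetConfig, ...] = ()

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("at least one group required")
        for label, n in self.groups:
            if n < 1:
                raise ValidationError(f"group {label!r} has size {n} < 1")

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)


def study_default(seed: int) -> SimulationConfig:
    """The default five-marker study.

    Signal strengths form a ladder (algae strongest ... fungus weakest) and
    mean depths sit at roughly twice each marker's rarefaction depth, so
    every preprocessing stage has real work to do.
    """
    return SimulationConfig(
        seed=seed,
        groups=DEFAULT_GROUP_SIZES,
        datasets=(
            DatasetConfig("bacteria", n_otus=400, effect_size=0.7, mean_depth=40_000,
                          identity_absent=True),
            DatasetConfig("archaea", n_otus=200, effect_size=0.12, mean_depth=4_000,
                          identity_absent=True),
            DatasetConfig("algae", n_otus=220, effect_size=4.0, mean_depth=1_200),
            DatasetConfig("diatom", n_otus=250, effect_size=0.45, mean_depth=2_800),
            DatasetConfig("fungus", n_otus=260, effect_size=0.08, mean_depth=700),
        ),
    )


def _metadata_for(groups: Sequence[tuple[str, int]]) -> SampleMetadata:
    labels = [label for label, _ in groups]
    pairs = []
    i = 0
    for label, n in groups:
        for _ in range(n):
            i += 1
            pairs.append((f"S{i:03d}", label))
    return SampleMetadata(pairs, allowed_groups=tuple(dict.fromkeys(labels)))


def simulate_dataset(
    cfg: SimulationConfig, dataset_index: int
) -> tuple[OtuTable, list[TaxonomyAnnotation], SampleMetadata]:
    """Generate one marker dataset; identical (cfg, index) -> identical output."""
    if not (0 <= dataset_index < cfg.n_datasets):
        raise ValidationError(f"dataset_index {dataset_index} out of range")
    ds = cfg.datasets[dataset_index]
    rng = rng_for(cfg.seed, "simulate", dataset_index, ds.label)
    metadata = _metadata_for(cfg.groups)
    group_labels = [label for label, _ in cfg.groups]

    n = ds.n_otus
    n_diff = round(ds.frac_differential * n)
    n_off = round(ds.frac_offtarget * n)
    n_low = round(ds.frac_low_identity * n)
    if n_diff + n_off + n_low > n:
        raise ValidationError(
            f"dataset {ds.label!r}: differential ({n_diff}) + off-target ({n_off}) "
            f"+ low-identity ({n_low}) strata exceed n_otus ({n})"
        )
    order = rng.permutation(n)
    diff_idx = order[:n_diff]
    off_idx = order[n_diff : n_diff + n_off]
    low_idx = order[n_diff + n_off : n_diff + n_off + n_low]

    baseline = rng.lognormal(mean=0.0, sigma=ds.base_abundance_sigma, size=n)
    # per-group composition: baseline x 2^(sign * effect) on differential OTUs
    signs = rng.integers(-1, 2, size=(n_diff, len(group_labels)))
    compositions = {}
    for g, label in enumerate(group_labels):
        abundance = baseline.copy()
        abundance[diff_idx] *= np.power(2.0, signs[:, g] * ds.effect_size)
        compositions[label] = abundance / abundance.sum()

    sample_ids = metadata.sample_ids
    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    for j, sample_id in enumerate(sample_ids):
        if ds.depth_dispersion == 0:
            depth = ds.mean_depth
        else:
            lam = rng.gamma(
                shape=1.0 / ds.depth_dispersion,
                scale=ds.mean_depth * ds.depth_dispersion,
            )
            depth = max(1, int(rng.poisson(lam)))
        counts[:, j] = rng.multinomial(depth, compositions[metadata.group_of(sample_id)])

    otu_ids = [f"OTU{i + 1:04d}" for i in range(n)]
    table = OtuTable.from_arrays(otu_ids, sample_ids, counts, ds.label)

    off_set, low_set = set(off_idx.tolist()), set(low_idx.tolist())
    annotations = []
    for i, otu_id in enumerate(otu_ids):
        if i in off_set:
            kingdom, phylum = _OFFTARGET_POOL[int(rng.integers(len(_OFFTARGET_POOL)))]
            lineage = (kingdom, phylum, f"offtarget_sp{i + 1}")
            identity = float(np.round(rng.uniform(85.0, 100.0), 1))
        else:
            lineage = (ds.target, f"{ds.target}_phylum{i % 7 + 1}", f"sp{i + 1}")
            if i in low_set:
                identity = ds.identity_low
            elif ds.identity_absent:
                identity = None
            else:
                identity = float(np.round(rng.uniform(85.0, 100.0), 1))
        annotations.append(TaxonomyAnnotation(otu_id, lineage, identity))
    return table, annotations, metadata


def simulate_study(
    cfg: SimulationConfig,
) -> list[tuple[OtuTable, list[TaxonomyAnnotation], SampleMetadata]]:
    """Generate all datasets over one shared sample collection."""
    return [simulate_dataset(cfg, i) for i in range(cfg.n_datasets)]
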