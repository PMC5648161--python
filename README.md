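# ampdisc

Multi-marker amplicon community discrimination: given OTU count tables from
several marker genes (16S rRNA for bacteria and archaea, 23S rRNA for algae,
18S rRNA for diatoms, ITS for fungi) sequenced from the same environmental
water samples, **how well does each taxon's community composition tell the
sample groups apart?**

The package is aimed at eDNA / microbiome researchers comparing the
discriminating power of different primer sets or taxa across grouped samples
(e.g. river sections before and after a rain event). It implements the full
analysis path from raw per-marker OTU tables to a cross-marker comparison:

1. **On-target filtering** — drop OTUs whose best-hit lineage falls outside
   the marker's target taxon, or whose best-hit identity is below 80%
   (unknown sequences). Unannotated OTUs count as off-target.
2. **Rarefaction** — subsample every sample to a fixed depth without
   replacement, either each marker's own depth or a common depth (350
   reads/sample by default) for head-to-head comparison.
3. **Low-abundance filter** — drop OTUs that never reach 1% relative
   abundance in any sample.
4. **Scaled PCA** — autoscaled principal components (the behaviour of R's
   `prcomp(scale. = TRUE)`), with an outlier-omission-and-recompute loop and
   pairwise group *t*-tests on PC1–3 (Bonferroni corrected).
5. **Discrimination statistic** — *k*-means on the PC1–3 scores with no
   group information, then a greedy largest-cluster-first matching of
   clusters to groups:

   accuracy = 1 − (mis-assigned samples) / (total samples),

   where each cluster, processed from largest to smallest, claims its most
   frequent not-yet-claimed group and every member from another group counts
   as mis-assigned. Significance comes from a permutation null: reshuffle
   the cluster labels over samples *B* times (default 1,000) and report the
   proportion of permutations recapitulating the groups more accurately.
6. **Differential abundance** — per-OTU pairwise group *t*-tests with a
   Bonferroni family spanning all OTUs × group pairs, plus a "top OTUs by
   read count" summary.
7. **Cross-marker analyses** — PCA of all markers' OTUs merged per sample
   (with per-marker loading attribution), and a second-level PCA of each
   marker's PC1–3 score vectors.

A seeded synthetic-study generator (`ampdisc.simulate`) produces multi-marker
OTU tables with group-structured compositions, off-target contamination and
uneven sequencing depth, so the entire pipeline is testable end to end
without any sequencing data.

## Worked example

```python
import ampdisc as ad

cfg = ad.study_default(seed=1)
table, annotations, metadata = ad.simulate_dataset(cfg, 2)   # the "algae" marker
spec = ad.TargetSpec(frozenset({"Algae"}), min_identity=80)
table = ad.filter_on_target(table, annotations, spec)
table = ad.rarefy(table, depth=600, seed=17)
table = ad.filter_low_abundance(table, threshold=0.01)
ordination = ad.remove_outliers_and_recompute(table)
meta = metadata.subset(ordination.sample_ids)
model = ad.DiscriminationModel(ordination, meta, k=4, n_components=3)
result = model.fit(seed=17, n_permutations=1000)
print(result.summary())
```

```
Cluster-to-group discrimination [algae]
================================================
samples: 68    k: 4    components: 3
accuracy: 100.0%   (0 mis-assigned)
permutation p (strict, B=1000): < 0.001
null accuracy mean: 32.8%
cluster -> group map:
  cluster 0 (n=23) -> upper_before
  cluster 1 (n=13) -> upper_after
  cluster 2 (n=22) -> lower_after
  cluster 3 (n=10) -> middle_before
```

Reading the output: two of the 70 simulated samples fell below the
rarefaction depth of 600 reads and were dropped. *k*-means on the first
three PCs found four clusters that match the four location × rain-epoch
groups exactly (accuracy 100%, zero mis-assigned), and none of 1,000 random
relabelings did as well, so the strict permutation p-value is reported as
`< 0.001`. A random clustering of these group sizes scores about 33% on
average — the permutation-null mean — which is the baseline the observed
accuracy should be judged against.

The same workflow is scriptable from the shell (`ampdisc simulate`,
`ampdisc rarefy`, `ampdisc pca`, `ampdisc discriminate`, `ampdisc run-all
--config study.yaml --out results/`, ...); see `ampdisc --help`.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its defaults, numerical conventions (tie-breaking, sign fixes,
p-value variants) and known limitations.
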