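# Methods

## The question and the statistic

Given grouped environmental samples assayed with several amplicon markers,
the package quantifies how well each marker's community composition
*discriminates* the groups. The statistic is deliberately interpretable:
samples are clustered by k-means on their leading principal-component
scores with no access to group labels, clusters are matched to groups by a
greedy rule, and the accuracy is the fraction of samples whose cluster was
claimed by their own group.

### Greedy matching, exactly

Clusters are processed in decreasing size. Each cluster is assigned the
most frequent group among its members that no larger cluster has already
claimed; if every group present in the cluster is taken, the assignment
falls to the first unclaimed group in lexicographic order, and if no group
remains unclaimed the cluster stays unmapped. Members not belonging to the
assigned group are mis-assigned, and

    accuracy = 1 − n_misassigned / n_samples.

Tie-breaks are fixed so results are reproducible: equal-size clusters are
processed in ascending cluster index, and equal group frequencies within a
cluster resolve to the lexicographically smaller group label. The greedy
accuracy is bounded above by the optimal injective cluster→group assignment
(Hungarian algorithm); the test suite verifies this bound exhaustively on
all configurations of up to 8 samples with up to 3 clusters and 3 groups,
and verifies equality (zero mis-assignments) whenever groups occupy
exclusive pure clusters.

### Permutation null

The null hypothesis is "cluster membership carries no information about
group". It is simulated by reshuffling the cluster-label vector over
samples (group labels fixed — equivalent in distribution to shuffling the
groups) and recomputing the greedy accuracy, default B = 1,000 times. Two
estimators are exposed:

* `strict` (default): p = #{permutation accuracy > observed} / B. A zero is
  rendered as `< 1/B`.
* `add_one`: p = (#{permutation accuracy ≥ observed} + 1) / (B + 1), the
  standard valid Monte-Carlo estimator, which can never be zero.

The greedy accuracy is a discrete statistic (multiples of 1/n over a narrow
range), so permutation ties are common. Because `strict` excludes ties from
the count it is mildly anti-conservative under the null, while `add_one`
is calibrated; the calibration acceptance test therefore applies the
Kolmogorov–Smirnov uniformity check to `add_one` p-values.

## Preprocessing

**On-target filter.** An OTU is kept iff its annotated lineage contains a
target keyword (case-insensitive; Greengenes-style `k__` prefixes are
stripped at parse time) *and* its best-hit percent identity is ≥ 80 (the
default `min_identity`) or absent. Absent identity denotes
reference-database assignment rather than a BLAST hit and passes the
identity test. Unannotated OTUs are treated as off-target: an unknown
sequence cannot be claimed for the target taxon.

**Rarefaction.** Classic subsampling without replacement, implemented as a
multivariate hypergeometric draw per sample, so every retained column sums
exactly to the requested depth and each OTU's rarefied count never exceeds
its original. Samples whose total falls below the depth are dropped with a
warning — the convention of the QIIME lineage of tools; nothing else is
defensible once a sample cannot supply the requested reads. Default depths:
bacteria 20,000; archaea 2,000; algae 600; diatoms 1,400; fungi 350; and a
common depth of 350 for head-to-head marker comparison. Rarefaction runs
*before* the abundance filter, matching the order in which subsampled
tables are normally taken into ordination.

**Low-abundance filter.** The default reading of "remove OTUs representing
less than 1% of the reads" is *per-sample-max*: keep an OTU iff it reaches
≥ 1% of reads in at least one sample. The alternative reading — ≥ 1% of the
dataset's grand total — is arithmetically incompatible with retaining ~100
OTUs jointly holding ~60–90% of reads (100 OTUs at ≥ 1% each would already
be 100%), so it cannot be what retention counts of that shape describe;
it is still exposed as `scope="dataset_total"`. Filters only drop rows:
retained counts are never rescaled or imputed.

## Ordination

Counts are autoscaled per OTU (mean 0, sample variance 1 with the n−1
denominator); zero-variance OTUs cannot be unit-scaled and are dropped with
a warning. The decomposition itself is an ordinary full-rank SVD PCA
(scikit-learn backend) with min(n−1, p) components, cross-checked in the
tests against an independent eigen-decomposition of the covariance matrix
at 1e-8. PCA signs are arbitrary, so each component is flipped to make its
largest-magnitude loading positive — a pure reproducibility convention.

"Obvious outlier" removal is operationalised as: flag samples whose PC1 or
PC2 score deviates from the score mean by more than 6 standard deviations
(one round by default), remove them, recompute. The multiplier and round
count are parameters; the loop refuses to go below 3 samples. A 6-sd rule
removes only gross artefacts (failed samples, contamination) and leaves
genuine group structure alone.

Pairwise group separation along each of PC1–3 is tested with equal-variance
two-sample t-tests (Welch available via `equal_var=False`), Bonferroni
corrected over the full family of components × group pairs — the most
conservative family choice.

## Differential abundance

Each OTU is tested between every unordered pair of groups on rarefied
counts (equal depth makes counts comparable across samples; a
relative-abundance option exists). The Bonferroni family is OTUs × pairs,
again the most conservative reading, and an OTU is called differential when
any pair survives adjustment. Degenerate inputs are defined rather than
propagated: both groups constant and equal gives p = 1, a group with fewer
than 2 samples gives NA.

## Cross-marker analyses

The merged analysis row-concatenates each marker's filtered, rarefied table
over the samples shared by all markers, namespacing OTU ids as
`<dataset>:<otu>`, then scales the concatenated matrix jointly and runs the
standard PCA → discrimination path. Loading attribution reports the share
of each component's squared loadings carried by each marker (shares sum to
1 per component), which substantiates statements like "this axis is driven
mostly by the algal OTUs".

The PCA-of-PCs analysis treats each marker's PC1–3 score vectors as
variables observed on the shared samples (columns `algae.PC1`, ...), scales
them, and decomposes again. Co-loading of several markers' PCs on one
meta-component is the signature of an environmental axis that multiple taxa
respond to. Plotting the variables in loading space is the natural display
of this decomposition.

## Synthetic studies

The generator emulates the *assumptions* the analysis exercises, not any
mechanistic ecology. Per marker: a log-normal baseline abundance per OTU
(σ = 1); a differential subset (30% of OTUs by default) whose abundance is
multiplied by 2^(s·effect_size) with s ∈ {−1, 0, +1} drawn per OTU × group,
giving distinct, non-collinear group centroids; per-sample depth drawn
gamma-Poisson around `mean_depth` (dispersion 0.05, enough for a realistic
minority of samples to fall below the rarefaction depth); and integer
counts multinomial given the sample's group composition. Fixed fractions of
OTUs receive off-target lineages (20%) or sub-80% identities (5%) so both
arms of the on-target filter do real work; markers flagged
`identity_absent` emulate reference-database annotation (identity `ND`).

The default study is 70 samples in four groups sized 23/15/10/22 observed
by five markers whose effect sizes form a deliberate ladder — algae 4.0,
bacteria 0.7, diatoms 0.45, archaea 0.12, fungi 0.08 (log2 units). The
ladder was designed once, from a pilot of the effect-size → accuracy
response at these sample sizes (the multivariate signal saturates above
log2FC ≈ 1), to span the full dynamic range of the statistic: one marker at
the ceiling, one near the permutation-null floor, the rest spread between.
With it, common-depth accuracies land around 100 / 85–95 / 40–75 / 25–40 /
30–35 percent respectively.

What the generator does *not* emulate — phylogenetic correlation between
OTUs, PCR and primer bias, chimeras, zero-inflation beyond multinomial
sampling, and any spatial/temporal autocorrelation between samples. Passing
recovery tests therefore demonstrate that the pipeline detects the kind of
compositional group structure it assumes, not that any particular real
marker will behave this way.

## Problem sizes and determinism

Every stochastic step takes an explicit seed; study-level runs derive one
seed per stage × dataset from the master seed via a CRC-based token scheme,
so adding or removing a marker never changes another marker's draws, and
identical configs produce byte-identical output trees. The acceptance tests
run the full 70-sample, five-marker study: the ranking-recovery check uses
20 replicate seeds and the null-calibration check 50 replicate seeds at 200
permutations — sizes chosen to put Monte-Carlo error well below the margins
being asserted while keeping the whole suite around ten seconds.

## Known limitations

* Counts are modelled as given; no compositional transforms (CLR) or
  abundance-aware tests (e.g. negative-binomial GLMs) are offered — the
  t-test-on-rarefied-counts convention is kept deliberately.
* Greedy matching is order-dependent by construction; with equal-size
  clusters whose preferences collide, its result can differ from the
  Hungarian optimum (the tests quantify this gap, the API does not hide it).
* Mid-range accuracies depend mildly on k-means initialisation; 25
  restarts make this negligible for well-separated data but not for
  borderline cases.
* The permutation p-value is one-sided by definition: only "better than
  observed" counts as evidence against chance.
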