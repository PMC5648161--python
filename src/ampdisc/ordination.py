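"""Scaled principal component analysis of OTU tables.

Counts are autoscaled per OTU (centered, unit sample variance, n-1
denominator) before the decomposition, so abundant and rare OTUs contribute
equally — the behaviour of R's ``prcomp(..., scale. = TRUE)``.  An
outlier-omission loop flags samples far out on PC1/PC2 and recomputes, and
pairwise group t-tests on the leading components quantify group separation
along each axis.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .containers import OtuTable, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """PC scores, loadings and variance bookkeeping for one table.

    ``scores`` is samples x components (columns ``PC1`` ...), ``loadings``
    is variables (OTUs) x components, and ``variance_explained`` holds each
    component's share of total variance (non-increasing, summing to <= 1).
    Component signs are fixed so each component's largest-magnitude loading
    is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    removed_outliers: list[str] = field(default_factory=list)
    dataset_label: str = ""

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def summary(self) -> str:
        lines = [
            f"Ordination of {self.loadings.shape[0]} variables over "
            f"{self.scores.shape[0]} samples"
            + (f" [{self.dataset_label}]" if self.dataset_label else ""),
        ]
        for i, ve in enumerate(self.variance_explained[:5]):
            lines.append(f"  PC{i + 1}: {100 * ve:.1f}% of variance")
        if self.removed_outliers:
            lines.append(f"  outliers removed: {', '.join(self.removed_outliers)}")
        return "\n".join(lines)

    def plot(self, metadata: SampleMetadata | None = None, components=(1, 2), ax=None):
        """Scatter of two PCs, coloured by group when metadata is given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a, b = components
        x = self.scores[f"PC{a}"]
        y = self.scores[f"PC{b}"]
        if metadata is None:
            ax.scatter(x, y, s=20)
        else:
            labels = metadata.labels_for(self.sample_ids)
            for group in dict.fromkeys(labels):
                mask = labels == group
                ax.scatter(x[mask], y[mask], s=20, label=str(group))
            ax.legend(fontsize="small")
        ax.set_xlabel(f"PC{a} ({100 * self.variance_explained[a - 1]:.1f}%)")
        ax.set_ylabel(f"PC{b} ({100 * self.variance_explained[b - 1]:.1f}%)")
        return ax


def scale_counts(table: OtuTable) -> pd.DataFrame:
    """Autoscale counts to a samples x OTUs matrix of z-scores.

    Each OTU column is centered to mean 0 and scaled to unit sample variance
    (n-1 denominator).  Zero-variance OTUs cannot be unit-scaled and are
    dropped with a warning.
    """
    if table.n_samples < 2:
        raise ValidationError("scaling requires at least 2 samples")
    frame = table.counts.T.astype(float)  # samples x OTUs
    sd = frame.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning(
            "scale_counts[%s]: dropping %d zero-variance OTU(s): %s",
            table.dataset_label, len(constant), constant[:10],
        )
        frame = frame.drop(columns=constant)
        sd = sd.drop(index=constant)
    if frame.shape[1] == 0:
        raise ValidationError("no variable OTUs left to scale")
    return (frame - frame.mean(axis=0)) / sd


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Flip components in place so the largest-|loading| entry is positive."""
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def pca(scaled: pd.DataFrame, dataset_label: str = "") -> OrdinationResult:
    """PCA of an already-scaled samples x variables matrix.

    Components are ordered by decreasing explained variance;
    ``variance_explained[i] = lambda_i / sum(lambda)``.
    """
    n_samples, n_vars = scaled.shape
    if n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    n_comp = min(n_samples - 1, n_vars)
    model = _SKPCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(scaled.to_numpy())
    loadings = model.components_.T.copy()
    _fix_signs(scores, loadings)
    names = [f"PC{i + 1}" for i in range(n_comp)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=scaled.index, columns=names),
        loadings=pd.DataFrame(loadings, index=scaled.columns, columns=names),
        variance_explained=model.explained_variance_ratio_.copy(),
        dataset_label=dataset_label,
    )


def pca_counts(table: OtuTable) -> OrdinationResult:
    """Convenience: ``pca(scale_counts(table))``."""
    return pca(scale_counts(table), table.dataset_label)


def remove_outliers_and_recompute(
    table: OtuTable,
    sd_multiplier: float = 6.0,
    max_rounds: int = 1,
) -> OrdinationResult:
    """PCA with an outlier-omission loop.

    After each decomposition, samples whose PC1 or PC2 score deviates from
    that component's score mean by more than ``sd_multiplier`` score
    standard deviations are removed and the PCA recomputed, up to
    ``max_rounds`` times.  If removal would leave fewer than 3 samples the
    loop stops early with a warning and returns the current result.
    """
    if sd_multiplier <= 0:
        raise ValidationError("sd_multiplier must be > 0")
    if max_rounds < 1:
        raise ValidationError("max_rounds must be >= 1")
    current = table
    removed: list[str] = []
    result = pca_counts(current)
    for _ in range(max_rounds):
        scores = result.scores.to_numpy()
        flagged_mask = np.zeros(scores.shape[0], dtype=bool)
        for j in range(min(2, scores.shape[1])):
            col = scores[:, j]
            sd = col.std(ddof=1)
            if sd > 0:
                flagged_mask |= np.abs(col - col.mean()) > sd_multiplier * sd
        flagged = [s for s, f in zip(result.sample_ids, flagged_mask) if f]
        if not flagged:
            break
        if current.n_samples - len(flagged) < 3:
            logger.warning(
                "outlier removal would leave < 3 samples (%d flagged of %d); "
                "keeping current result", len(flagged), current.n_samples,
            )
            break
        logger.info(
            "removing %d outlier sample(s): %s", len(flagged), flagged[:10]
        )
        removed.extend(flagged)
        keep = [s for s in current.sample_ids if s not in set(flagged)]
        current = current.select_samples(keep)
        result = pca_counts(current)
    result.removed_outliers = removed
    return result


def pc_group_tests(
    result: OrdinationResult,
    metadata: SampleMetadata,
    n_components: int = 3,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests on the leading PC scores.

    For each component up to ``n_components`` and each unordered group pair,
    an equal-variance (Student's) two-sample t-test; Bonferroni correction
    over the whole family (components x pairs), adjusted p capped at 1.
    Pairs with a group of fewer than 2 samples are reported as NA.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    n_components = min(n_components, result.n_components)
    labels = metadata.labels_for(result.sample_ids)
    groups = [g for g in metadata.allowed_groups if g in set(labels)]
    pairs = list(itertools.combinations(groups, 2))
    family = n_components * len(pairs)
    rows = []
    for c in range(1, n_components + 1):
        scores = result.scores[f"PC{c}"].to_numpy()
        for g1, g2 in pairs:
            x, y = scores[labels == g1], scores[labels == g2]
            if len(x) < 2 or len(y) < 2:
                logger.warning("group pair (%s, %s) has < 2 samples; NA", g1, g2)
                t_stat, p_raw = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t_stat, p_raw = stats.ttest_ind(x, y, equal_var=equal_var)
                if np.isnan(p_raw):  # both groups constant and equal
                    t_stat, p_raw = 0.0, 1.0
            rows.append(
                {
                    "component": f"PC{c}",
                    "group1": g1,
                    "group2": g2,
                    "t_statistic": t_stat,
                    "p_raw": p_raw,
                    "p_adjusted": min(1.0, p_raw * family) if np.isfinite(p_raw) else np.nan,
                }
            )
    frame = pd.DataFrame(rows)
    frame["significant"] = frame["p_adjusted"] < 0.05
    return frame
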