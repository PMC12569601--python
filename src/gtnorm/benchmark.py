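"""Subsampling evaluation of relative expression estimators.

Given a deep ("ground truth") expression profile, cells at shallower
depths are emulated by drawing m UMIs with replacement, weighted by the
deep counts (a multinomial subsample).  The Good-Turing and ML
estimators are then applied to each subsample and compared to the
ground truth — estimation error as the summed absolute per-gene error
(L1), and cell-cell distance as the Euclidean distance between
frequency vectors of two independent subsamples (of the same cell, or
of two different cells).  Depth levels are spaced equidistantly in
log10 between 100 and 100,000 UMIs/cell; summary tables report the
mean and the empirical 5%/95% quantiles over replicates per level.

Ground-truth frequencies are always the ML estimate on the deep
profile: at very high depth the unseen-gene mass is negligible, and
using ML for the truth is conservative toward the Good-Turing
estimator being evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ProjectionError
from .sgt import CountProfile, FrequencyVector, gt_frequencies, ml_frequencies

__all__ = [
    "SubsampleScheme",
    "umi_levels",
    "subsample_profile",
    "l1_error",
    "frequency_distance",
    "fixed_projection",
    "fit_reference_projection",
    "error_curves",
    "distance_curves",
]

_ESTIMATORS = {"gt": gt_frequencies, "ml": ml_frequencies}


@dataclass(frozen=True)
class SubsampleScheme:
    """Depth levels and replication of the subsampling benchmark."""

    min_umis: int = 100
    max_umis: int = 100_000
    k_levels: int = 20
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.min_umis < self.max_umis:
            raise ValueError("min_umis must be < max_umis")
        if self.k_levels < 2:
            raise ValueError("k_levels must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def umi_levels(scheme: SubsampleScheme) -> list[int]:
    """Depth levels equidistant in log10-space, floored to integers.

    With the defaults this yields 100, 143, 206, ..., 69,519, 100,000.
    """
    lo, hi = np.log10(scheme.min_umis), np.log10(scheme.max_umis)
    exponents = lo + np.arange(scheme.k_levels) * (hi - lo) / (scheme.k_levels - 1)
    levels = np.floor(10.0**exponents).astype(int)
    levels[0], levels[-1] = scheme.min_umis, scheme.max_umis
    return [int(v) for v in levels]


def subsample_profile(
    truth: CountProfile, m: int, rng: np.random.Generator | int
) -> CountProfile:
    """Draw m UMIs from a deep profile, weighted by count, with replacement.

    Equivalent to a multinomial draw of size m with probabilities
    c_g / N; the result has total exactly m.
    """
    if m < 1:
        raise ValueError("subsample size m must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    probs = truth.counts / truth.total
    counts = rng.multinomial(m, probs)
    return CountProfile(gene_ids=truth.gene_ids, counts=counts)


def _align(est: FrequencyVector, truth: FrequencyVector) -> tuple[np.ndarray, np.ndarray]:
    """Align two frequency vectors on the union of gene ids (absent = 0)."""
    if len(est.gene_ids) == len(truth.gene_ids) and np.array_equal(
        est.gene_ids, truth.gene_ids
    ):
        return est.freqs, truth.freqs
    union = np.unique(np.concatenate([est.gene_ids, truth.gene_ids]))
    a = np.zeros(len(union))
    b = np.zeros(len(union))
    a[np.searchsorted(union, est.gene_ids)] = est.freqs
    b[np.searchsorted(union, truth.gene_ids)] = truth.freqs
    return a, b


def l1_error(est: FrequencyVector, truth: FrequencyVector) -> float:
    """Sum of absolute per-gene relative expression errors."""
    a, b = _align(est, truth)
    return float(np.abs(a - b).sum())


def frequency_distance(p: FrequencyVector, q: FrequencyVector) -> float:
    """Euclidean distance between two relative expression profiles."""
    a, b = _align(p, q)
    return float(np.linalg.norm(a - b))


def fixed_projection(
    profiles: Sequence[FrequencyVector],
    gene_subset: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    loadings: np.ndarray,
) -> np.ndarray:
    """Project profiles into a reference PCA space.

    Genes are restricted to ``gene_subset`` (typically the reference
    population's variable genes), z-scored with the reference `means`
    and `sds`, and rotated by the reference component `loadings`
    (genes x components).  The same affine map is applied to every
    profile, so profiles at different depths land in a common space.
    """
    gene_subset = np.asarray(gene_subset)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if not (len(gene_subset) == len(means) == len(sds) == loadings.shape[0]):
        raise ValueError("gene_subset, means, sds and loadings rows must align")
    zero_sd = np.flatnonzero(sds == 0)
    if len(zero_sd):
        raise ProjectionError(
            "zero standard deviation for genes: "
            + ", ".join(str(gene_subset[i]) for i in zero_sd[:10])
        )
    coords = np.empty((len(profiles), loadings.shape[1]))
    for i, prof in enumerate(profiles):
        f = pd.Series(prof.freqs, index=prof.gene_ids)
        sub = f.reindex(gene_subset, fill_value=0.0).to_numpy()
        z = (sub - means) / sds
        coords[i] = z @ loadings
    return coords


def fit_reference_projection(
    freq_matrix: np.ndarray,
    gene_ids: np.ndarray,
    n_components: int = 50,
    n_variable_genes: int | None = 2000,
):
    """Build a fixed projection from a reference population.

    ``freq_matrix`` is cells x genes relative expression.  Selects the
    `n_variable_genes` highest-variance genes (all genes if None),
    excludes zero-variance genes, z-scores genewise and fits PCA.
    Returns (gene_subset, means, sds, loadings) for
    :func:`fixed_projection`.
    """
    from sklearn.decomposition import PCA

    gene_ids = np.asarray(gene_ids)
    variances = freq_matrix.var(axis=0)
    keep = np.flatnonzero(variances > 0)
    if n_variable_genes is not None and len(keep) > n_variable_genes:
        keep = keep[np.argsort(variances[keep])[::-1][:n_variable_genes]]
        keep = np.sort(keep)
    sub = freq_matrix[:, keep]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=0)
    z = (sub - means) / sds
    n_components = min(n_components, min(z.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(z)
    return gene_ids[keep], means, sds, pca.components_.T


def _summary_rows(
    values: dict[tuple[int, str], np.ndarray], metric: str
) -> pd.DataFrame:
    rows = []
    for (level, estimator), vals in sorted(values.items()):
        rows.append(
            {
                "level": level,
                "estimator": estimator,
                "metric": metric,
                "mean": float(np.mean(vals)),
                "q05": float(np.quantile(vals, 0.05)),
                "q95": float(np.quantile(vals, 0.95)),
            }
        )
    return pd.DataFrame(rows, columns=["level", "estimator", "metric", "mean", "q05", "q95"])


def error_curves(
    truth: CountProfile,
    scheme: SubsampleScheme,
    estimators: Iterable[str] = ("gt", "ml"),
) -> pd.DataFrame:
    """L1 estimation error vs subsampling depth.

    At each depth level, `scheme.replicates` profiles are subsampled
    from `truth`; each estimator's frequencies are compared to the ML
    frequencies of the deep truth.  Returns rows of
    (level, estimator, metric, mean, q05, q95).
    """
    estimators = list(estimators)
    rng = np.random.default_rng(scheme.seed)
    truth_freqs = ml_frequencies(truth)
    values: dict[tuple[int, str], np.ndarray] = {}
    for level in umi_levels(scheme):
        per_est: dict[str, list[float]] = {e: [] for e in estimators}
        for _ in range(scheme.replicates):
            sub = subsample_profile(truth, level, rng)
            for est in estimators:
                per_est[est].append(l1_error(_ESTIMATORS[est](sub), truth_freqs))
        for est in estimators:
            values[(level, est)] = np.array(per_est[est])
    return _summary_rows(values, "l1_error")


def distance_curves(
    truth_a: CountProfile,
    truth_b: CountProfile | None,
    scheme: SubsampleScheme,
    estimators: Iterable[str] = ("gt", "ml"),
) -> pd.DataFrame:
    """Cell-cell Euclidean distance in frequency space vs depth.

    Two profiles are subsampled independently at each level — both from
    `truth_a` when `truth_b` is None (same-cell mode, where the true
    distance is 0), else one from each — estimated, and their distance
    recorded.  Returns rows of (level, estimator, metric, mean, q05, q95).
    """
    estimators = list(estimators)
    rng = np.random.default_rng(scheme.seed)
    same_cell = truth_b is None
    values: dict[tuple[int, str], np.ndarray] = {}
    for level in umi_levels(scheme):
        per_est: dict[str, list[float]] = {e: [] for e in estimators}
        for _ in range(scheme.replicates):
            sub_a = subsample_profile(truth_a, level, rng)
            sub_b = subsample_profile(truth_a if same_cell else truth_b, level, rng)
            for est in estimators:
                fn = _ESTIMATORS[est]
                per_est[est].append(frequency_distance(fn(sub_a), fn(sub_b)))
        for est in estimators:
            values[(level, est)] = np.array(per_est[est])
    metric = "same_cell_distance" if same_cell else "cross_cell_distance"
    return _summary_rows(values, metric)
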