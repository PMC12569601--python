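"""Per-cell relative gene expression estimation.

Global-scaling normalization of single-cell RNA-seq data divides each
gene's UMI count by the cell total, i.e. it uses the maximum-likelihood
(ML) estimate ``f_g = c_g / N`` of the cell's relative expression
frequencies.  At typical depths (~5,000 UMIs/cell) many expressed genes
are never observed; ML gives them frequency zero and therefore
systematically overestimates every observed gene.

The Simple Good-Turing (SGT) estimator corrects this by reserving the
*missing mass* ``P0 = N_1 / N`` (the Turing estimate of the total
probability of all unseen genes, where ``N_1`` is the number of
singleton genes) and re-estimating the frequency of a gene seen ``r``
times from the smoothed frequencies-of-frequencies ``N_r``:

    f_r = (r + 1) / N * S(N_{r+1}) / S(N_r)

with ``S`` the Gale-Sampson log-log linear smoother.  Low counts are
shrunk, the output sums to ``1 - P0`` over observed genes, and
unobserved genes keep an exact zero.

This module is pure computation on one cell at a time; matrix-level
normalization lives in :mod:`gtnorm.normalize`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import EmptyProfileError, NeedsFallback

__all__ = [
    "CountProfile",
    "FreqOfFreq",
    "SgtFit",
    "FrequencyVector",
    "freq_of_freq",
    "ml_frequencies",
    "z_transform",
    "fit_loglog",
    "sgt_fit",
    "gt_frequencies",
    "missing_mass",
    "UnreliableSlopeWarning",
]

#: 95% two-sided normal quantile used by the Turing/LGT switch rule.
SWITCH_Z = 1.96


class UnreliableSlopeWarning(UserWarning):
    """Smoother slope b > -1: the Good-Turing estimates may be unreliable."""


@dataclass(frozen=True)
class CountProfile:
    """One cell's gene counts: ``gene_ids[i]`` was observed ``counts[i]`` times."""

    gene_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        gene_ids = np.asarray(self.gene_ids)
        counts = np.asarray(self.counts)
        if gene_ids.shape != counts.shape or counts.ndim != 1:
            raise ValueError("gene_ids and counts must be 1-D and of equal length")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(np.unique(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        """N, the number of UMIs in the cell."""
        return int(self.counts.sum())

    @property
    def n_genes_detected(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class FreqOfFreq:
    """Frequencies of frequencies: ``n_r[i]`` genes were seen ``r[i]`` times.

    ``r`` is strictly increasing, every ``n_r >= 1`` and
    ``sum(r * n_r)`` equals the cell total ``total``.
    """

    r: np.ndarray
    n_r: np.ndarray
    total: int

    def count_of(self, value: int) -> int:
        """N_r for a given count value (0 if unrepresented)."""
        idx = np.searchsorted(self.r, value)
        if idx < len(self.r) and self.r[idx] == value:
            return int(self.n_r[idx])
        return 0


@dataclass(frozen=True)
class SgtFit:
    """Result of a Simple Good-Turing fit on one cell.

    ``per_count_prob[r]`` is the probability assigned to ONE gene
    observed ``r`` times; ``missing_mass`` is P0, the total probability
    of all unobserved genes.  The rescaling step guarantees
    ``sum_r N_r * p_r + P0 == 1``.
    """

    per_count_prob: dict[int, float]
    missing_mass: float
    intercept: float
    slope: float
    switch_count: int | None
    fallback_ml: bool = False
    total: int = 0


@dataclass(frozen=True)
class FrequencyVector:
    """Relative expression estimates aligned with a profile's gene_ids."""

    gene_ids: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        if len(self.gene_ids) != len(self.freqs):
            raise ValueError("gene_ids and freqs must have equal length")

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.freqs))


def _require_nonempty(profile: CountProfile) -> None:
    if profile.total == 0:
        raise EmptyProfileError("profile has zero total count")


def freq_of_freq(profile: CountProfile) -> FreqOfFreq:
    """Tally the frequencies of frequencies of one cell.

    Returns the (r, N_r) table over the distinct positive count values.
    """
    _require_nonempty(profile)
    positive = profile.counts[profile.counts > 0]
    r, n_r = np.unique(positive, return_counts=True)
    return FreqOfFreq(r=r.astype(np.int64), n_r=n_r.astype(np.int64),
                      total=profile.total)


def ml_frequencies(profile: CountProfile) -> FrequencyVector:
    """Maximum-likelihood relative expression: f_g = c_g / N."""
    _require_nonempty(profile)
    return FrequencyVector(
        gene_ids=profile.gene_ids,
        freqs=profile.counts / profile.total,
    )


def z_transform(fof: FreqOfFreq) -> list[tuple[int, float]]:
    """Neighbor-averaged frequencies of frequencies Z_r.

    N_r tables are sparse for large r, so each N_r is spread over the
    gap to its represented neighbors: ``Z_r = 2 N_r / (t - q)`` where q
    is the previous represented count (0 for the first) and t the next
    (``2r - q`` for the last).  When both neighbors are adjacent,
    Z_r == N_r.
    """
    r = fof.r
    if len(r) == 0:
        raise ValueError("empty frequencies-of-frequencies table")
    out: list[tuple[int, float]] = []
    for i, (ri, ni) in enumerate(zip(r, fof.n_r)):
        q = int(r[i - 1]) if i > 0 else 0
        t = int(r[i + 1]) if i + 1 < len(r) else 2 * int(ri) - q
        out.append((int(ri), 2.0 * float(ni) / (t - q)))
    return out


def fit_loglog(z_pairs: Sequence[tuple[int, float]]) -> tuple[float, float]:
    """Ordinary least squares of log Z_r on log r (natural logs).

    Defines the smoother ``S(r) = exp(a) * r^b``.  Raises
    :class:`NeedsFallback` with fewer than two distinct counts; warns if
    the slope b > -1 (estimates then flagged unreliable, per the
    Gale-Sampson diagnostics) but proceeds.
    """
    if len(z_pairs) < 2:
        raise NeedsFallback("log-log regression needs >= 2 distinct count values")
    x = np.log([p[0] for p in z_pairs])
    y = np.log([p[1] for p in z_pairs])
    b, a = np.polyfit(x, y, 1)
    if b > -1.0:
        warnings.warn(
            f"smoother slope b = {b:.3f} > -1; Good-Turing estimates may be "
            "unreliable for this cell",
            UnreliableSlopeWarning,
            stacklevel=2,
        )
    return float(a), float(b)


def _smoothed_adjusted_count(r: int, b: float) -> float:
    # r*_LGT = (r+1) S(r+1)/S(r) = (r+1) ((r+1)/r)^b
    return (r + 1) * ((r + 1) / r) ** b


def sgt_fit(
    fof: FreqOfFreq,
    smoothing: Literal["sgt", "lgt"] = "sgt",
) -> SgtFit:
    """Fit the Simple Good-Turing estimator to one cell's (r, N_r) table.

    For every represented count r an adjusted count r* is chosen:
    the empirical Turing estimate ``(r+1) N_{r+1} / N_r`` for small r,
    and the smoothed (LGT) estimate ``(r+1) S(r+1)/S(r)`` once the two
    stop differing significantly or r+1 is unrepresented — after which
    the fit never returns to the Turing estimates (``smoothing="lgt"``
    uses the smoothed estimates throughout).  Per-count probabilities
    are rescaled so that the observed mass plus the missing mass
    ``P0 = N_1 / N`` is exactly 1.

    Cells with a single distinct count value cannot support the
    regression and fall back to ML (``fallback_ml=True``, P0 = 0).
    """
    n = fof.total
    try:
        a, b = fit_loglog(z_transform(fof))
    except NeedsFallback:
        return SgtFit(
            per_count_prob={int(r): int(r) / n for r in fof.r},
            missing_mass=0.0,
            intercept=math.nan,
            slope=math.nan,
            switch_count=None,
            fallback_ml=True,
            total=n,
        )

    p0 = fof.count_of(1) / n
    r_star: dict[int, float] = {}
    switch_count: int | None = None
    use_smoothed = smoothing == "lgt"
    if use_smoothed:
        switch_count = int(fof.r[0])
    for i, r in enumerate(fof.r):
        r = int(r)
        lgt = _smoothed_adjusted_count(r, b)
        if not use_smoothed:
            n_r = int(fof.n_r[i])
            n_r1 = fof.count_of(r + 1)
            if n_r1 == 0:
                use_smoothed = True
            else:
                turing = (r + 1) * n_r1 / n_r
                width = SWITCH_Z * math.sqrt(
                    (r + 1) ** 2 * (n_r1 / n_r**2) * (1.0 + n_r1 / n_r)
                )
                if abs(turing - lgt) <= width:
                    use_smoothed = True
                else:
                    r_star[r] = turing
                    continue
            if switch_count is None:
                switch_count = r
        r_star[r] = lgt

    observed_star = sum(int(n_r) * r_star[int(r)] for r, n_r in zip(fof.r, fof.n_r))
    scale = (1.0 - p0) / observed_star
    per_count_prob = {r: star * scale for r, star in r_star.items()}
    return SgtFit(
        per_count_prob=per_count_prob,
        missing_mass=p0,
        intercept=a,
        slope=b,
        switch_count=switch_count,
        fallback_ml=False,
        total=n,
    )


def gt_frequencies(
    profile: CountProfile,
    smoothing: Literal["sgt", "lgt"] = "sgt",
) -> FrequencyVector:
    """Good-Turing relative expression estimates for one cell.

    Genes with zero count get exactly 0; observed genes get the
    per-count probability from :func:`sgt_fit`, so the estimates sum to
    ``1 - P0``.
    """
    _require_nonempty(profile)
    fit = sgt_fit(freq_of_freq(profile), smoothing=smoothing)
    lut = {0: 0.0, **fit.per_count_prob}
    freqs = np.array([lut[int(c)] for c in profile.counts])
    return FrequencyVector(gene_ids=profile.gene_ids, freqs=freqs)


def missing_mass(profile: CountProfile) -> float:
    """Turing estimate P0 = N_1 / N of the total frequency of unseen genes."""
    _require_nonempty(profile)
    return int(np.count_nonzero(profile.counts == 1)) / profile.total
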