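"""Matrix-level normalization with Good-Turing or ML frequency estimates.

Drop-in global-scaling normalization: each cell's relative expression
frequencies are estimated (GT by default, ML optionally), multiplied by
a scale factor (default 10,000) and log-transformed as
``log(1 + f * scale_factor)``.  With ``method="ml"`` this reproduces
the conventional library-size log-normalization exactly; with
``method="gt"`` the zeros of the input are preserved and low counts are
shrunk by the Good-Turing correction.

Cells are independent: normalizing any subset of columns yields the
same values for those columns as normalizing the whole matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import EmptyProfileError
from .io import CountMatrix, NormalizedMatrix
from .sgt import CountProfile, freq_of_freq, sgt_fit

__all__ = ["NormalizationConfig", "normalize_matrix", "column_independence_check"]


@dataclass(frozen=True)
class NormalizationConfig:
    """Settings of the global-scaling normalization.

    method: "gt" (Good-Turing, default) or "ml" (library-size).
    scale_factor: multiplier applied to frequencies before the log
        (default 10,000, the Seurat NormalizeData default).
    log_transform: natural log of (1 + scaled value) when True.
    smoothing: "sgt" full Simple Good-Turing with the Turing/LGT switch
        (default) or "lgt" pure smoothed ratios.
    drop_empty: silently drop zero-total cells instead of raising.
    """

    method: Literal["gt", "ml"] = "gt"
    scale_factor: float = 1e4
    log_transform: bool = True
    smoothing: Literal["sgt", "lgt"] = "sgt"
    drop_empty: bool = False

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.method not in ("gt", "ml"):
            raise ValueError(f"unknown method {self.method!r}")


def _column_frequencies(counts: np.ndarray, cfg: NormalizationConfig) -> np.ndarray:
    """Per-gene relative expression for the nonzero counts of one cell."""
    n = counts.sum()
    if cfg.method == "ml":
        return counts / n
    fit = sgt_fit(
        freq_of_freq(CountProfile(np.arange(len(counts)), counts)),
        smoothing=cfg.smoothing,
    )
    lut = fit.per_count_prob
    return np.array([lut[int(c)] for c in counts])


def normalize_matrix(
    mat: CountMatrix, cfg: NormalizationConfig | None = None
) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """Normalize a count matrix column-wise; return matrix + per-cell QC.

    The returned matrix has the same genes, barcodes and sparsity
    pattern as the input (real-valued entries).  The QC table has one
    row per retained cell: barcode, n_umi, n_genes, missing_mass,
    fallback.

    Raises :class:`EmptyProfileError` listing the offending barcodes if
    any cell has zero total counts, unless ``cfg.drop_empty``.
    """
    cfg = cfg or NormalizationConfig()
    csc = mat.matrix.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel()
    empty = np.flatnonzero(totals == 0)
    if len(empty) and not cfg.drop_empty:
        bad = ", ".join(str(mat.barcodes[i]) for i in empty[:10])
        raise EmptyProfileError(
            f"{len(empty)} cell(s) with zero counts (e.g. {bad}); "
            "set drop_empty to exclude them"
        )
    keep = np.flatnonzero(totals > 0)

    out = sp.lil_matrix((mat.n_genes, len(keep)), dtype=np.float64)
    qc_rows = []
    for j_out, j in enumerate(keep):
        lo, hi = csc.indptr[j], csc.indptr[j + 1]
        rows = csc.indices[lo:hi]
        counts = csc.data[lo:hi]
        n = int(counts.sum())
        p0, fallback = 0.0, False
        if cfg.method == "gt":
            fit = sgt_fit(
                freq_of_freq(CountProfile(np.arange(len(counts)), counts)),
                smoothing=cfg.smoothing,
            )
            freqs = np.array([fit.per_count_prob[int(c)] for c in counts])
            p0, fallback = fit.missing_mass, fit.fallback_ml
        else:
            freqs = counts / n
            p0 = float(np.count_nonzero(counts == 1)) / n
        vals = freqs * cfg.scale_factor
        if cfg.log_transform:
            vals = np.log1p(vals)
        out[rows, j_out] = vals
        qc_rows.append(
            {
                "barcode": mat.barcodes[j],
                "n_umi": n,
                "n_genes": len(counts),
                "missing_mass": p0,
                "fallback": fallback,
            }
        )

    normalized = NormalizedMatrix(
        gene_ids=mat.gene_ids.copy(),
        barcodes=mat.barcodes[keep].copy(),
        matrix=out.tocsc(),
        gene_names=mat.gene_names.copy(),
        feature_types=mat.feature_types.copy(),
    )
    return normalized, pd.DataFrame(
        qc_rows, columns=["barcode", "n_umi", "n_genes", "missing_mass", "fallback"]
    )


def column_independence_check(mat: CountMatrix, cfg: NormalizationConfig) -> bool:
    """Verify cells are normalized independently of their neighbors.

    Normalizes each column alone and compares with the joint result;
    returns True when they agree exactly.
    """
    joint, _ = normalize_matrix(mat, cfg)
    for j in range(mat.n_cells):
        single = CountMatrix(
            gene_ids=mat.gene_ids,
            barcodes=mat.barcodes[j : j + 1],
            matrix=mat.matrix[:, j : j + 1],
        )
        alone, _ = normalize_matrix(single, cfg)
        if (alone.matrix != joint.matrix[:, j : j + 1]).nnz != 0:
            return False
    return True
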