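"""Estimate one cell's relative gene expression with GT and ML.

Builds a small single-cell count profile, fits the Simple Good-Turing
estimator, and contrasts its frequencies with the maximum-likelihood
ones.  The printed missing mass is the estimated total frequency of
all genes the cell expressed but sequencing never observed; GT reserves
exactly that probability and shrinks low-count genes to pay for it.
"""

import numpy as np

from gtnorm import (
    CountProfile,
    freq_of_freq,
    gt_frequencies,
    missing_mass,
    ml_frequencies,
    sgt_fit,
)

counts = np.array([12, 7, 4, 3, 2, 2, 1, 1, 1, 1, 0, 0])
genes = np.array([f"gene{i:02d}" for i in range(len(counts))], dtype=object)
cell = CountProfile(gene_ids=genes, counts=counts)

fit = sgt_fit(freq_of_freq(cell))
ml = ml_frequencies(cell)
gt = gt_frequencies(cell)

print(f"total UMIs N = {cell.total}, genes detected = {cell.n_genes_detected}")
print(f"missing mass P0 = N1/N = {missing_mass(cell):.4f}")
print(f"smoother: S(r) = exp({fit.intercept:.4f}) * r^{fit.slope:.4f}, "
      f"switch to smoothed estimates at r = {fit.switch_count}")
print(f"{'gene':>7} {'count':>5} {'ML':>8} {'GT':>8}")
for g, c, m, t in zip(genes, counts, ml.freqs, gt.freqs):
    print(f"{g:>7} {c:5d} {m:8.4f} {t:8.4f}")
print(f"sums: ML = {ml.total_mass:.4f}, GT = {gt.total_mass:.4f} "
      f"(= 1 - P0; the rest is reserved for unseen genes)")
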