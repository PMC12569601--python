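# Methods

## The estimation problem

A sequenced cell is modeled as N independent draws (UMIs) from its true
relative expression vector f over G genes. The observed counts c_g are
then multinomial, and the task is to estimate f from one cell's counts.
The ML estimator c_g/N is unbiased per gene but assigns zero to every
unobserved gene; conditional on the observed support it overestimates,
and the size of that bias depends on N. The Good–Turing family corrects
exactly this: the probability that the *next* UMI would come from an
unseen gene is estimated by the singleton fraction P0 = N_1/N, and the
frequency of a gene seen r times by (r+1)/N · S(N_{r+1})/S(N_r), where
N_r is the number of genes seen r times and S a smoother of r → N_r.

## Simple Good–Turing fit (per cell)

1. **Frequencies of frequencies.** Tally N_r over the distinct positive
   counts r of the cell.
2. **Neighbor averaging.** Because N_r is sparse at large r, each N_r is
   spread over the gap between its represented neighbors:
   Z_r = 2·N_r/(t − q), q the previous represented count (0 for the
   first), t the next (2r − q for the last). When counts are contiguous
   Z_r = N_r.
3. **Log-log smoother.** Ordinary least squares of ln Z_r on ln r gives
   S(r) = exp(a)·r^b. Natural logarithms are used; any base gives
   identical S ratios, fixing a convention only makes (a, b)
   reproducible. A slope b > −1 makes the smoothed estimator formally
   unreliable; the fit warns (`UnreliableSlopeWarning`) and proceeds,
   since aborting would break whole-matrix normalization on occasional
   odd cells.
4. **Adjusted counts and switch rule.** For each represented r, the
   smoothed adjusted count is r*_LGT = (r+1)((r+1)/r)^b and, when r+1 is
   represented, the empirical Turing estimate is r*_T = (r+1)N_{r+1}/N_r.
   Scanning represented r in increasing order, the Turing estimate is
   used until the first r at which either r+1 is unrepresented or
   |r*_T − r*_LGT| ≤ 1.96·sqrt((r+1)²(N_{r+1}/N_r²)(1 + N_{r+1}/N_r));
   from that r on (recorded as `switch_count`) the smoothed estimate is
   used and the fit never switches back. A `smoothing="lgt"` variant
   uses the smoothed ratios throughout — with it the estimator reduces
   to the pure ratio form S(N_{r+1})/S(N_r); with the default full-SGT
   rule the two coincide whenever the switch happens at the smallest
   count. Both are exposed because either reading of the ratio form is
   defensible; full SGT is the default as it is the classical recipe
   and the one used by the widely deployed count-data implementations.
5. **Rescaling.** P0 = N_1/N, and per-count probabilities
   p_r = (1 − P0)·r*_r / Σ_r N_r·r*_r, so Σ_r N_r p_r + P0 = 1 exactly
   (to ~1e-16 in double precision; all conservation tests use 1e-10,
   ML mass tests 1e-12). The renormalization distributes the correction
   proportionally across counts, the classical choice.
6. **Fallback.** Cells with fewer than two distinct positive count
   values cannot support the regression; they fall back to ML with
   P0 = 0 and are flagged (`fallback_ml`) per cell. This also closes the
   P0 = 1 corner: an all-singleton cell has one distinct count, so the
   GT path can never emit total mass 0.

Monotonicity: the smoothed adjusted count (r+1)^{b+1}/r^b is strictly
increasing in r for any b < 1, so pure-LGT probabilities are monotone;
Turing segments before the switch could in principle invert an
adjacent pair, but no violation occurs in the seeded random-profile
tests whenever b < −1.

## Normalization

`normalize_matrix` applies the chosen estimator column-wise and returns
log(1 + f·scale_factor) (natural log; scale factor default 10,000,
log transform on by default) — with `method="ml"` this is exactly the
standard library-size log-normalization, making GT a drop-in
replacement that differs only in the estimator. Columns are processed
independently, so normalizing any subset of cells reproduces those
columns bit-for-bit. Empty cells are rejected with their barcodes
listed (silent zeros would corrupt QC) unless `drop_empty` is set.
Per-cell totals, genes detected, missing mass and the fallback flag are
returned as a QC table, never baked into the matrix. No information is
pooled across cells — the denominators are single-cell totals by
construction.

## UMI correction

Within each (cell barcode, gene) group, directional clustering draws an
edge a → b when Hamming(a, b) = 1 and reads_a ≥ 2·reads_b − 1, seeds
clusters at unclaimed UMIs in descending read order (ties broken
lexicographically — the published network definition leaves ordering
open, so these are conventions of this implementation, recorded here,
not claims about any other tool), and grows each cluster breadth-first,
claiming each UMI once. The corrected molecule count is the number of
clusters.

The one-pass scheme reproduces a documented failure mode for regression
testing: every UMI is *simultaneously* reassigned to its best
higher-read Hamming-1 neighbor satisfying the same 2n−1 threshold, so
an error chain A(10) ← B(2) ← C(1) leaves two distinct corrected UMIs
(C lands on B while B moves to A) where directional clustering
correctly finds one molecule. Keeping the threshold in the one-pass
rule makes the method ordering directional ≤ one-pass ≤ raw provable:
any UMI with a qualifying higher-read neighbor would have been claimed
before it could seed a directional cluster, so every directional seed
is a one-pass fixed point.

Input is a read-level TSV (cell_barcode, gene_id, umi, reads) — the
same fields one extracts from an aligner BAM; BAM parsing itself is out
of scope.

## Subsampling benchmark

Depth levels are equidistant in log10 space from 100 to 100,000
UMIs/cell, floored to integers (floor, not round, reproduces the
canonical 100, 143, 206, … ladder); 20 levels and 1,000 replicates per
level are the defaults, overridable for desk-scale runs. Subsampling a
deep profile to m UMIs is one multinomial draw of size m with
probabilities c_g/N — equivalent to drawing genes weighted by count
with replacement — so each subsample totals exactly m. Ground-truth
frequencies are always the ML estimate of the deep profile: its missing
mass is negligible and the choice is conservative toward GT.

Estimation error is the L1 distance Σ_g |est_g − truth_g|; cell–cell
distance is the Euclidean distance between frequency vectors. Both
align gene universes by union with absent genes at 0, the only
convention that keeps L1 bounded by 2. Summary tables report the mean
and empirical 5%/95% quantiles (linear interpolation) per level and
estimator, from a single seeded `numpy.random.Generator`, so runs are
bit-reproducible.

`fixed_projection` reproduces the reference-population PCA pipeline:
genes restricted to a reference subset (typically the most variable
genes), z-scored with reference means and standard deviations
(zero-variance genes are a hard error), and rotated by reference
loadings — the same affine map for every profile regardless of depth.
`fit_reference_projection` builds such a reference with scikit-learn's
PCA.

## Synthetic data

`simulate_truth` produces a heavy-tailed truth: Zipf (frequency of the
k-th gene ∝ k^(−shape), default shape 1.0, assignment to gene ids
permuted by seed) or i.i.d. log-normal abundances. Zipf(1.0) over
10,000 genes yields cells whose missing mass is roughly 0.1–0.5 at
depths 500–5,000 — the regime where GT and ML genuinely differ, and the
reason it is the default. `simulate_cell` draws one multinomial cell;
`simulate_matrix` draws per-cell depths from a log-normal law with
median 5,000 truncated to [500, 20,000] (log-sd 0.6, which puts the
central mass across that range), the shape of a typical high-quality
droplet run.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, PCR amplification bias, or gene–gene correlation — cells are
exchangeable multinomial draws. Passing benchmarks therefore
demonstrate estimator behavior under multinomial sampling noise, the
noise component the estimators address, and say nothing about those
artifacts.

## Benchmark conditions used in tests and the acceptance script

Desk-scale runs use a 10,000-gene Zipf(1.0) truth sequenced to 200,000
UMIs (comfortably above the deepest 10,000-UMI level used), 200
replicates at levels {100, 1,000, 10,000}. For distance benchmarks the
second cell is the same truth with a 100-gene marker block upweighted
by 2.4 and renormalized, giving a true cell–cell distance of ~0.015 —
two similar but distinct cell types, the regime in which distance
estimation is hard. The separation between different-cell and same-cell
distances is compared at the 1,000-UMI level: since
E[cross²] = E[same²] + d_true², the expected separation at 100 UMIs
(~1e-3) is below the Monte-Carlo error of two independent 200-replicate
means, so a comparison there would measure noise; at 1,000 UMIs the
comparison is well powered. Same-cell overestimation by ML is asserted
at both 100 and 1,000 UMIs.

## Known limitations

- GT estimates within one cell are exchangeable given the count: two
  genes with the same count always get the same frequency.
- The smoother is the linear log-log fit only; no spline or local
  smoothers, no empirical-Bayes shrinkage, no cross-cell pooling.
- The b > −1 warning path produces estimates of uncertain quality on
  cells with nearly flat frequencies-of-frequencies; they are flagged,
  not fixed.
- UMI correction is sequence-only: no base qualities, no per-position
  error model, no cell-barcode whitelist correction.
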