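# Methods

This note records the models, conventions and design choices behind
`wavecluster`, in the order the pipeline applies them, together with what
the synthetic data do and do not establish.

## Wavelet transform

The transform is the standard FFT implementation of the continuous
wavelet transform with the Morlet mother wavelet.  Conventions:

* **ω₀ = 6.** The usual compromise between time and frequency
  resolution at which the Morlet admissibility correction is negligible;
  values below 5 are rejected.
* **Scale grid** `s_j = s0·2^(j·dj)` with `s0 = 2Δt` and `dj = 1/12`
  (twelve sub-octaves per doubling).  The number of scales defaults to
  capping the largest Fourier period at **span/3**: a period needs to
  complete roughly three cycles before its power estimate means
  anything, and shorter records simply cannot testify about slower
  rhythms.  Series shorter than 25 points are rejected outright for the
  same reason.
* **Standardization.** Each series is reduced to zero mean, unit
  variance before transforming, so power is amplitude-free; no
  polynomial detrending is applied (Box–Cox plus standardization precede
  the transform in the pipeline).
* **Padding.** Zero padding to the next power of two; the cone of
  influence (COI) marks the region contaminated by the pad: a point at
  distance d from the nearer series end is trustworthy up to period
  `ff·d/√2`, with ff the Fourier factor `4π/(ω₀+√(2+ω₀²))`.
* **Power** is the plain squared modulus `|W|²`.  The *significance
  test* compares observed power against surrogate power processed
  identically, so any scale bias cancels there.  The *clustering
  distance*, in contrast, compares power across scales within one
  spectrum pair, so there the spectra are bias-rectified by dividing
  power by scale (see below).
* `dominant_period` averages COI-interior power over a time window and
  takes the argmax over periods, with parabolic interpolation on the
  log-period axis to undo most of the dyadic grid's quantization; ties
  break toward the shorter period.

## Markov surrogates

The null hypothesis for spectral significance is a stochastic process
with the data's mean, variance, value distribution and short-term
autocorrelation.  Construction:

1. Discretize the values into `min(15, n/10)` equal-frequency bins
   (collapsed automatically when ties make bins empty, with a logged
   warning).  The count balances resolution of the transition structure
   against sparse transition rows.
2. Rearrange the state sequence by a randomized Eulerian path through
   the first-order transition multigraph (Hierholzer's algorithm with
   shuffled adjacency).  Every transition count is preserved *exactly*,
   hence so is each state's occupancy.
3. Fill each state's slots with a random permutation of the original
   values belonging to that bin.

Every surrogate is therefore an exact permutation of the source values
(mean, variance, distribution preserved by construction) with the binned
lag-1 structure preserved exactly — a strictly stronger guarantee than
simulating a fresh chain from the estimated transition matrix, which
preserves those properties only in expectation and can distort the value
multiset when bins are drawn unevenly.

The test is pointwise: cell (period, time) is flagged when observed
power exceeds the confidence quantile of the surrogate power at that
cell.  Displayed masks use 95% confidence; masks feeding the clustering
distance use 90%.  Area-wise corrections are out of scope.  On AR(1)
noise the empirical flagged fraction of COI-interior cells at the 95%
level sits near the nominal 5% (the acceptance suite checks 2–10%
averaged over 50 replicates).  Ensembles default to 1000 surrogates for
final runs; tests and the demonstration use 100, which bounds the
Monte-Carlo error of a 95% quantile well enough for cluster-level
conclusions.

## Spectrum distance (maximum covariance analysis)

For spectra A, B on identical axes: power is masked to zero outside each
spectrum's 90% significance mask, divided by scale (rectification), and
row-centered over time.  The cross-covariance matrix `C = X Yᵀ/(T−1)`
(scales as variables, time points as observations) is decomposed by SVD.
Axes are retained up to 95% cumulative squared covariance; for each
retained axis k with squared-covariance fraction f_k the discrepancy is

    (1 − |cos ∠(u_k, v_k)|)  +  ‖â_k − b̂_k‖/2

where u, v are the paired singular vectors (sign-aligned), and â, b̂ the
unit-normalized time projections ("leading patterns") `Xᵀu`, `Yᵀv`.  The
distance is the f_k-weighted sum, symmetrized by averaging the two
orientations.  Self-distance is exactly 0; pairs with no significant
power in either spectrum have undefined distance and receive the panel
maximum, with a logged warning.

Two choices deserve emphasis:

* **Rectification.** Unrectified Morlet power grows roughly linearly
  with scale, so the squared-covariance weights would be dominated by
  the slowest bands: two series genuinely sharing a fast rhythm but
  differing slowly would be called distant.  Dividing power by scale
  puts all bands on a comparable footing; with it, the demonstration
  panel's switching pair (13→4 and 20→4 days) is reliably closer to
  each other than either is to a stationary slow filler.
* **Time orientation.** Covariance is taken over time because the
  method's point is to align *time-localized* spectral features — the
  very information that time-averaged (global) spectra and plain
  correlations discard.

The exact functional is one plausible member of a family (angle-only,
pattern-only, and unweighted variants are easy swaps behind the same
interface); conclusions in this package rest on orderings and contrasts,
not on absolute distance values.

Correlation dissimilarities `d = 1 − ρ` (Spearman or Pearson, all time
points) provide the comparison route.  Both matrices are clustered with
Ward's minimum-variance criterion via the Lance–Williams recurrence on
the given dissimilarities (the Ward.D2 convention; SciPy's
implementation, deterministic tie handling).

## Tree comparison

`Bₖ = Tₖ/√(PₖQₖ)` from the cluster-overlap counts of the two flat
k-partitions, for k = 2 … n−1.  The null of unrelated trees is random
relabeling with the marginal cluster sizes fixed; the closed-form mean
and variance of Bₖ under that null give the one-sided rejection line
`mean + z₀.₉₅·sd`.  A permutation null (999 relabelings) is provided as
an independent check; at n = 19 the two rejection lines agree within
0.05 everywhere, and the closed-form moments match Monte-Carlo moments
to ~0.01.  The statistic is validated exhaustively against a brute-force
pair-counting oracle over *all* partition pairs of up to 7 elements.
With few leaves the normal approximation is slightly liberal (empirical
exceedance ~7% at nominal 5% for n = 12 random trees); conclusions that
hinge on a single marginal point should prefer the permutation line.

Total branch length sums each merge's two child segments with leaves at
height 0 — equivalently, the sum of all vertical connecting segments of
the dendrogram.  Trees serialize to ultrametric Newick; reading recovers
the merge structure (multifurcations resolve into equal-height binary
merges).

## Preprocessing

Fixed order: depth filter → relative abundance → core selection → CLR →
interpolation → Box–Cox.

* **Depth filter**: samples with fewer than 500 reads are dropped
  (strictly fewer — a sample at exactly 500 is kept).
* **Core taxa**: relative abundance > 0.005 in ≥ 25% of samples.  With
  bootstrapping (default 100 resamples of samples with replacement) a
  taxon is kept when it passes in a majority of resamples; `n_boot = 0`
  gives the plain criterion.  When several subjects are analyzed, each
  subject's core is selected separately and the union is analyzed in
  every subject.
* **CLR**: per sample, log fractions centered by their mean log; zeros
  are replaced by half the sample's smallest nonzero fraction and the
  sample renormalized (a global-pseudocount policy is available).
  Output columns sum to zero to machine precision.
* **Interpolation**: monotone cubic Hermite (PCHIP) onto the grid
  `t0 + i·1.6` days, no extrapolation; monotone slopes avoid the
  overshoot a free cubic spline produces on spiky series.  A span T
  yields `floor(T/1.6) + 1` points.
* **Box–Cox**: per series, after shifting the minimum to 1 *only when
  the minimum is ≤ 0* (CLR output is signed; already-positive data are
  left unshifted so that, e.g., a log-normal series correctly recovers
  λ ≈ 0).  λ is chosen on the grid [−2, 2] step 0.01 by maximizing the
  probability-plot correlation coefficient with plotting positions
  `(i − 3/8)/(n + 1/4)`; the transformed series is standardized.  The
  transform's purpose is to suppress the sharp peaks of spiky taxa that
  would otherwise dominate their spectra.

## Synthetic data: what it emulates, what it does not

`make_fig1_panel` builds the eight-signal demonstration: an antiphase
8-day pair (s1, s2), stationary 20- and 26-day fillers (s3, s4), a noisy
8-day signal (s6), and three period switchers (s5: 13→4, s7: 4→20,
s8: 20→4 at day 50), each 100 days at daily sampling, with phase
continuity at the switch (a phase reset would inject spurious broadband
power exactly at the discontinuity).  Deliberate constructions:

* **Filler phases are in quadrature** (s3 at π/2 relative to the
  switchers' 20-day plateaus, s6 at π/2 relative to s1/s2).  The
  demonstration's point is shared periodicity *without* value
  correlation; in-phase fillers would be genuinely correlated with half
  of a switching signal, and a correlation tree that agrees with the
  wavelet tree for a real reason is not a control.
* **s4 sits at 26 days**, away from both switcher plateaus, so no
  stationary filler duplicates half of a switcher's spectrum.
* The panel is fully deterministic (s6's noise has a fixed internal
  seed), so downstream results are reproducible bit for bit.

`make_synthetic_community` emulates dense 16S genus tables: irregular
timestamps (mean 1.6 days, ±20% multiplicative jitter over 450 days),
group taxa whose latent log-abundances follow a shared sinusoid
(amplitude 2 on the log scale, taxon noise sd 0.5, baseline +3 over the
fillers) with **evenly spaced phases** within each group, spiky fillers
with Student-t (3 df) fluctuations near the detection threshold, and
multinomial sampling of 10 000 reads per sample from the softmax of the
latent field.  Even phase spacing makes the ground truth what the
experiment needs it to be — membership carried by shared period, not by
accidental phase alignment.  Defaults (19 taxa, groups of 5 at 30 and
64 days) give ~282 samples and leave the depth filter inert by design.

What passing tests show: the pipeline's algebra is correct, its
significance test is calibrated on the null it states, and
spectrum-based clustering separates period-structured groups that
correlation cannot see, at these noise levels and sampling densities.
What they do not show: robustness to compositional artifacts beyond
multinomial sampling (no overdispersion, no sequencing batch effects),
to missing-data gaps longer than the interpolation can bridge, or to
rhythms whose period drifts continuously rather than switching.

## Numerical details and degenerate inputs

* Constant series are rejected everywhere (no spectrum, no correlation,
  no PPCC).  All-zero samples fail CLR upstream at the relative-
  abundance step.  Non-equidistant input to the transform is an error,
  not a silent resample.
* Equal-frequency binning collapses duplicate quantile edges and logs
  the reduced bin count (periodic signals on commensurate grids have
  ties).
* Quantiles of surrogate power use NumPy's default linear interpolation;
  at 100 surrogates the 95% threshold interpolates between order
  statistics 95 and 96.
* Dendrogram cutting uses the merge order to resolve height ties (the
  linkage ordering is authoritative).
* Problem sizes in tests and the acceptance script — 100-point panel
  series, 100 surrogates, a 19×~282 community, 50 AR(1) replicates —
  were chosen as the smallest sizes at which every property being
  tested is stable across seeds.
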