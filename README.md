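# wavecluster

Wavelet clustering of microbial community time series.

Correlation-based network inference treats a microbiome time series as a
bag of exchangeable observations: two taxa are "related" when their
abundances co-vary.  That misses everything the *timing* of the dynamics
carries — two taxa oscillating at the same period but in antiphase have
correlation −1, and a taxon that slowly drifts from a 4-day to a 20-day
rhythm looks like noise.  `wavecluster` clusters time series by the
similarity of their **Morlet wavelet power spectra**, so that taxa sharing
time-localized periodicities group together regardless of phase, and
compares the resulting trees quantitatively with trees built from plain
correlation.

## Method

For each (preprocessed, equidistant) series `x(t)` the package computes
the continuous wavelet transform with the Morlet mother wavelet
(ω₀ = 6), on a dyadic scale grid `s_j = s0·2^(j·dj)` with `s0 = 2Δt`,
`dj = 1/12`; wavelet power is `|W(s,t)|²` and scales map to Fourier
periods through `4π/(ω₀+√(2+ω₀²))`.  The cone of influence marks cells
within `√2·s` of a series end, where edge effects contaminate power.

Significance of power is assessed against **Markov surrogates**: the
values are binned into equal-frequency states, and each surrogate is a
random rearrangement of the original values that preserves the exact
first-order state-transition counts (a randomized Eulerian path through
the transition multigraph).  Surrogates therefore keep the mean,
variance, full value distribution and short-term autocorrelation of the
data; a spectrum cell is significant when its power exceeds the chosen
quantile of the surrogate power at that cell.

Pairs of spectra are compared by **maximum covariance analysis**: power
is masked at 90% confidence, bias-rectified by scale, and the
cross-covariance matrix between the two fields (scales as variables,
time points as observations) is decomposed by SVD.  For the leading axes
holding ≥95% of squared covariance, the distance accumulates the angular
discrepancy between paired singular vectors and the normalized gap
between their time projections, weighted by squared-covariance fraction.
The distance matrix is clustered with the **Ward** criterion.

Trees are compared with the **Fowlkes–Mallows Bₖ statistic**.  With
`m_ij` the number of objects shared between cluster *i* of one
*k*-partition and cluster *j* of the other, and *n* objects in total:

    Tₖ = Σᵢⱼ m²ᵢⱼ − n,   Pₖ = Σᵢ(Σⱼ m_ij)² − n,   Qₖ = Σⱼ(Σᵢ m_ij)² − n,
    Bₖ = Tₖ / √(Pₖ·Qₖ)  ∈ [0, 1]

traced over k = 2 … n−1, with a one-sided rejection line
`E[Bₖ] + z₀.₉₅·sd[Bₖ]` from the closed-form null moments under random
relabeling (a permutation null is available as a cross-check).  Total
branch length — the sum of a dendrogram's connecting segments, leaves at
height 0 — summarizes how much structural diversity a tree resolves.

Count tables are preprocessed in the fixed order: read-depth filter
(≥500 reads) → relative abundance → bootstrap core-taxon selection
(abundance > 0.005 in ≥25% of samples) → centered log-ratio transform →
monotone cubic Hermite interpolation onto a 1.6-day grid → per-series
Box–Cox rescaling with the exponent chosen by maximizing the normal
probability-plot correlation coefficient.

## Worked example

The built-in demonstration generates eight synthetic signals — an
antiphase pair of 8-day sinusoids (s1, s2), stationary 20- and 26-day
fillers (s3, s4), two signals that switch from a slow to a 4-day rhythm
at day 50 (s5: 13→4, s8: 20→4), a noisy 8-day signal (s6) and the
reverse switcher (s7: 4→20) — and runs the whole pipeline:

```
$ wavecluster demo-fig1 --n-surrogates 100 --seed 0 demo_out
{
 "wavelet_coclusters_s1s2": true,
 "wavelet_coclusters_s5s8": true,
 "spearman_separates_s1s2": true,
 "spearman_separates_s5s8": true,
 "bk_all_below_rejection": true
}
total branch lengths: {'tree_wavelet': 10.09275279672494, 'tree_spearman': 8.763043121636962}
```

At k = 4 the wavelet tree puts the antiphase pair {s1, s2} in one cluster
and the switchers {s5, s8} in another, because their spectra agree; the
Spearman tree separates both pairs, because their values anticorrelate
(s1 vs s2) or decorrelate (s5 vs s8).  The emitted Bₖ curve
(`demo_out/bk_wavelet_vs_spearman.csv`) quantifies that the two trees are
unrelated at every resolution — every Bₖ sits below the 95% rejection
line:

```
 k    bk  rejection
 2 0.385      0.637
 3 0.286      0.514
 4 0.200      0.448
 5 0.289      0.397
 6 0.000      0.370
 7 0.000      0.341
```

The wavelet tree's total branch length (10.09) exceeds the Spearman
tree's (8.76): the spectrum distance resolves more structural diversity
than correlation does.

The same pipeline runs on real data — a taxa×samples count table (TSV
with a timestamp row, or BIOM 1.0 JSON) per subject:

```
$ wavecluster run-all --subject male=male.tsv --subject female=female.tsv \
      --seed 1 --outdir out
```

which emits preprocessed series, spectra and significance masks, wavelet
/ Spearman / Pearson Ward trees (Newick), Bₖ curves between methods
within each subject and between subjects within each method, and total
branch lengths.  `wavecluster simulate` writes a synthetic 19-taxon
community with known period groups for end-to-end testing.

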