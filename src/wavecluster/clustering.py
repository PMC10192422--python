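"""Distances between series and between wavelet spectra, and Ward trees.

Two routes to a dissimilarity matrix are provided:

* ``wavelet_mca`` — spectra are compared through maximum covariance
  analysis (MCA): significance-masked power matrices are cross-covaried
  (scales as variables, time points as observations) and decomposed by
  SVD; for the leading axes holding a set fraction of squared covariance,
  the distance accumulates (a) the angular discrepancy between the paired
  singular vectors and (b) the normalized gap between their time
  projections ("leading patterns"), weighted by squared-covariance
  fraction.  Two spectra that localize the same periodicities at the same
  times are close regardless of phase.
* ``spearman`` / ``pearson`` — the classical ``d = 1 - rho`` correlation
  dissimilarity on the raw series, for comparison.

Either matrix is clustered agglomeratively with the Ward minimum-variance
criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .cwt import WaveletSpectrum
from .series import RegularSeriesSet
from .significance import SignificanceMask

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "mca_distance",
    "wavelet_distance_matrix",
    "correlation_dissimilarity",
    "ward_cluster",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with labels")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(d < 0):
            raise ValueError("negative distances")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree.  ``Z`` is a SciPy linkage matrix: row i
    merges clusters ``Z[i,0]`` and ``Z[i,1]`` at height ``Z[i,2]`` into a
    cluster of size ``Z[i,3]``; leaves sit at height 0."""

    labels: tuple[str, ...]
    Z: np.ndarray
    linkage_method: str = "ward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        Z = np.asarray(self.Z, dtype=float)
        object.__setattr__(self, "Z", Z)
        n = len(self.labels)
        if Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


def _masked_centered(spec: WaveletSpectrum, mask: SignificanceMask) -> np.ndarray:
    """Significance-masked, bias-rectified, row-centered power field.

    Power is divided by scale before masking: raw Morlet power grows with
    scale, so without rectification the squared-covariance weights of the
    MCA would be dominated by the slowest bands and genuine agreement at
    short periods would carry almost no weight."""
    if mask.mask.shape != spec.power.shape:
        raise ValueError("mask shape does not match spectrum")
    x = np.where(mask.mask, spec.power / spec.scales[:, None], 0.0)
    return x - x.mean(axis=1, keepdims=True)


def mca_distance(
    spec_a: WaveletSpectrum,
    mask_a: SignificanceMask,
    spec_b: WaveletSpectrum,
    mask_b: SignificanceMask,
    cum_cov_threshold: float = 0.95,
) -> float:
    """MCA-based distance between two significance-masked wavelet spectra.

    Returns NaN when the cross-covariance between the masked spectra is
    numerically zero (e.g. both spectra entirely non-significant); the
    matrix assembler replaces NaN with the panel maximum.
    """
    if not spec_a.same_axes(spec_b):
        raise ValueError(
            f"spectra {spec_a.label!r} and {spec_b.label!r} have incompatible axes"
        )
    if spec_a.params != spec_b.params:
        raise ValueError("spectra were computed with different transform parameters")
    x = _masked_centered(spec_a, mask_a)
    y = _masked_centered(spec_b, mask_b)
    nt = x.shape[1]
    cov = x @ y.T / (nt - 1)
    u, s, vt = np.linalg.svd(cov, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 1e-30:
        return float("nan")
    frac = s**2 / total
    k_keep = int(np.searchsorted(np.cumsum(frac), cum_cov_threshold) + 1)
    k_keep = min(k_keep, s.size)
    dist = 0.0
    for k in range(k_keep):
        uk = u[:, k]
        vk = vt[k]
        if uk @ vk < 0:  # joint sign indeterminacy of the SVD pair
            vk = -vk
        angular = 1.0 - abs(float(uk @ vk))
        a = x.T @ uk  # leading patterns (time projections)
        b = y.T @ vk
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na <= 1e-30 or nb <= 1e-30:
            gap = 1.0
        else:
            gap = float(np.linalg.norm(a / na - b / nb)) / 2.0
        dist += frac[k] * (angular + gap)
    return float(dist)


def wavelet_distance_matrix(
    spectra: list[WaveletSpectrum],
    masks: list[SignificanceMask],
    cum_cov_threshold: float = 0.95,
) -> DistanceMatrix:
    """All pairwise MCA distances, symmetrized by averaging the two
    orientations.  Pairs with undefined distance (fully non-significant
    spectra) receive the maximum observed distance in the panel."""
    if len(spectra) < 3:
        raise ValueError("need at least 3 spectra")
    if len(masks) != len(spectra):
        raise ValueError("one mask per spectrum required")
    n = len(spectra)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = mca_distance(spectra[i], masks[i], spectra[j], masks[j],
                               cum_cov_threshold)
            dji = mca_distance(spectra[j], masks[j], spectra[i], masks[i],
                               cum_cov_threshold)
            d[i, j] = d[j, i] = np.nanmean([dij, dji])
    bad = np.isnan(d)
    if bad.any():
        finite_max = np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0
        logger.warning(
            "%d spectrum pairs had undefined MCA distance (no significant "
            "power); assigned the panel maximum %.4g", int(bad.sum() // 2),
            finite_max,
        )
        d[bad] = finite_max
        np.fill_diagonal(d, 0.0)
    labels = tuple(sp.label for sp in spectra)
    return DistanceMatrix(labels, d, "wavelet_mca")


def correlation_dissimilarity(
    series_set: RegularSeriesSet, method: str = "spearman"
) -> DistanceMatrix:
    """Correlation dissimilarity ``d = 1 - rho`` between all series pairs,
    using all data points; ``rho`` is Spearman's or Pearson's coefficient."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if len(series_set.labels) < 3:
        raise ValueError("need at least 3 series")
    x = series_set.values
    sd = x.std(axis=1)
    if np.any(sd == 0):
        const = [lab for lab, s in zip(series_set.labels, sd) if s == 0]
        raise ValueError(f"constant series have undefined correlation: {const}")
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
    rho = np.corrcoef(x)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(series_set.labels, d, method)


def ward_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering of a precomputed dissimilarity matrix with
    Ward's minimum-variance criterion (Lance-Williams recurrence on the
    given dissimilarities, the Ward.D2 convention)."""
    if not np.all(np.isfinite(dist.d)):
        raise ValueError("non-finite entries in the distance matrix")
    Z = linkage(dist.condensed(), method="ward")
    return Dendrogram(dist.labels, Z, "ward")
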