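"""Markov-surrogate significance testing of wavelet power.

The null hypothesis is that the observed periodicities could arise from a
stochastic first-order Markov process with the same mean, variance, value
distribution and short-term autocorrelation as the data.  Surrogates are
built by (1) discretizing the values into equal-frequency bins, (2)
randomly rearranging the resulting state sequence while preserving every
first-order transition count exactly (a randomized Eulerian path through
the transition multigraph), and (3) refilling each state's slots with a
random permutation of the source values belonging to that bin.  Every
surrogate is therefore an exact permutation of the source values — mean,
variance and distribution are preserved by construction — while the binned
lag-1 transition structure is preserved exactly as well.

Each surrogate is wavelet-transformed with the same parameters as the
data, and a spectrum cell is flagged significant when the observed power
exceeds the chosen quantile of the surrogate power at that cell
(a pointwise test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cwt import WaveletSpectrum, _batch_power
from .series import SampledSeries

__all__ = [
    "SurrogateEnsemble",
    "SignificanceMask",
    "markov_surrogates",
    "surrogate_power",
    "significance_mask",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurrogateEnsemble:
    source_label: str
    times: np.ndarray
    series: np.ndarray  # n_surrogates x n
    n_bins: int
    seed: int

    @property
    def n_surrogates(self) -> int:
        return self.series.shape[0]


@dataclass(frozen=True)
class SignificanceMask:
    """Boolean matrix (periods x times) of cells exceeding the surrogate
    null at the given confidence level."""

    mask: np.ndarray
    confidence: float
    n_surrogates: int

    def __post_init__(self) -> None:
        if not (0.5 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0.5, 1)")


def _equal_frequency_states(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Assign each value to an equal-frequency bin; ties can collapse bins,
    in which case the effective bin count is reduced (and logged)."""
    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    interior = np.unique(edges[1:-1])
    states = np.searchsorted(interior, x, side="right")
    # re-index to consecutive occupied states
    occupied, states = np.unique(states, return_inverse=True)
    eff = occupied.size
    if eff < n_bins:
        logger.warning(
            "equal-frequency binning collapsed %d requested bins to %d "
            "occupied bins (ties in the data)", n_bins, eff,
        )
    return states, eff


def _eulerian_shuffle(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random state sequence with exactly the same first-order transition
    multiset as ``states`` (randomized Hierholzer walk from the first state)."""
    n_states = int(states.max()) + 1
    adj: list[list[int]] = [[] for _ in range(n_states)]
    for a, b in zip(states[:-1], states[1:]):
        adj[a].append(b)
    for lst in adj:
        rng.shuffle(lst)
    stack = [int(states[0])]
    path: list[int] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(adj[v].pop())
        else:
            path.append(stack.pop())
    path.reverse()
    return np.asarray(path, dtype=np.intp)


def markov_surrogates(
    series: SampledSeries,
    n_surrogates: int = 1000,
    n_bins: int | None = None,
    seed: int = 0,
) -> SurrogateEnsemble:
    """Build a Markov-surrogate ensemble for an equidistant series.

    ``n_bins`` defaults to ``min(15, n // 10)`` equal-frequency bins —
    enough resolution to capture short-term autocorrelation without sparse
    transition rows.  At least 19 surrogates are required for a pointwise
    95% test.
    """
    if series.n < 25:
        raise ValueError("series too short for surrogate testing (need >= 25)")
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a 95% pointwise test")
    x = series.values
    n = x.size
    if n_bins is None:
        n_bins = max(2, min(15, n // 10))
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    states, eff_bins = _equal_frequency_states(x, n_bins)
    pools = [np.flatnonzero(states == b) for b in range(eff_bins)]
    rng = np.random.default_rng(seed)
    out = np.empty((n_surrogates, n))
    for m in range(n_surrogates):
        seq = _eulerian_shuffle(states, rng)
        for b, pool in enumerate(pools):
            slots = np.flatnonzero(seq == b)
            vals = x[pool]
            out[m, slots] = vals[rng.permutation(vals.size)]
    return SurrogateEnsemble(series.label, series.times.copy(), out, eff_bins, seed)


def surrogate_power(ensemble: SurrogateEnsemble, params: dict) -> np.ndarray:
    """Wavelet power of every surrogate under the given transform params;
    returns an ``n_surrogates x n_scales x n`` array."""
    dt = params["dt"]
    steps = np.diff(ensemble.times)
    if not np.allclose(steps, dt, rtol=1e-6):
        raise ValueError("ensemble time grid does not match transform dt")
    scales = params["s0"] * 2.0 ** (params["dj"] * np.arange(params["n_scales"]))
    return _batch_power(ensemble.series, dt, scales, params["omega0"])


def significance_mask(
    spectrum: WaveletSpectrum,
    ensemble: SurrogateEnsemble,
    confidence: float = 0.95,
    surrogate_pow: np.ndarray | None = None,
) -> SignificanceMask:
    """Pointwise significance mask of a spectrum against its surrogate null.

    A cell is flagged when observed power exceeds the ``confidence``
    quantile of the surrogate power at that cell.  Pass ``surrogate_pow``
    (from :func:`surrogate_power`) to reuse one ensemble transform across
    several confidence levels.
    """
    if ensemble.times.size != spectrum.times.size or not np.allclose(
        ensemble.times, spectrum.times
    ):
        raise ValueError("ensemble was not built from the spectrum's series")
    if surrogate_pow is None:
        surrogate_pow = surrogate_power(ensemble, spectrum.params)
    if surrogate_pow.shape[1:] != spectrum.power.shape:
        raise ValueError("surrogate power shape does not match the spectrum")
    threshold = np.quantile(surrogate_pow, confidence, axis=0)
    return SignificanceMask(spectrum.power > threshold, confidence,
                            surrogate_pow.shape[0])
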