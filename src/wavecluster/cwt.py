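"""Morlet continuous wavelet transform on an equidistant time grid.

The transform follows the standard FFT construction: the series is
standardized to zero mean and unit variance, zero-padded to the next power
of two, and convolved in the frequency domain with Morlet daughters on a
dyadic scale grid ``s_j = s0 * 2**(j*dj)``.  Power is the squared modulus.
Scales convert to Fourier periods through the Morlet Fourier factor
``4*pi / (omega0 + sqrt(2 + omega0**2))``.

The cone of influence (COI) marks, for each time point, the largest period
whose estimate is untouched by edge effects: the wavelet e-folding time is
``sqrt(2)*s``, so a point at distance ``d`` from the nearer endpoint is
trustworthy up to period ``fourier_factor * d / sqrt(2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import SampledSeries

__all__ = [
    "WaveletSpectrum",
    "GlobalSpectrum",
    "morlet_cwt",
    "fourier_factor",
    "cone_of_influence",
    "global_spectrum",
    "dominant_period",
]

#: minimum series length for a meaningful spectrum (shorter records cannot
#: resolve periodicities beyond a few grid steps)
MIN_SERIES_LENGTH = 25

#: default cap on the largest resolvable period as a fraction of the span;
#: longer periods complete fewer than three cycles and are untrustworthy
MAX_PERIOD_FRACTION = 1.0 / 3.0


def fourier_factor(omega0: float) -> float:
    """Scale-to-period conversion constant for the Morlet wavelet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class WaveletSpectrum:
    """Wavelet power over a period x time grid, with the cone of influence."""

    label: str
    times: np.ndarray
    periods: np.ndarray
    scales: np.ndarray
    power: np.ndarray
    coi: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if self.power.shape != (self.periods.size, self.times.size):
            raise ValueError("power matrix shape inconsistent with axes")
        if self.coi.size != self.times.size:
            raise ValueError("coi must have one entry per time point")
        if np.any(self.power < 0):
            raise ValueError("negative wavelet power")
        if not np.all(np.diff(self.periods) > 0):
            raise ValueError("periods must be strictly increasing")

    @property
    def coi_mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell lies inside the cone
        (period <= COI at that time)."""
        return self.periods[:, None] <= self.coi[None, :]

    def same_axes(self, other: "WaveletSpectrum") -> bool:
        return (
            self.periods.size == other.periods.size
            and self.times.size == other.times.size
            and np.allclose(self.periods, other.periods)
            and np.allclose(self.times, other.times)
        )


@dataclass(frozen=True)
class GlobalSpectrum:
    """Time-averaged wavelet power per period (the average wavelet spectrum,
    an estimator of the classical Fourier spectrum)."""

    periods: np.ndarray
    mean_power: np.ndarray
    coi_masked: bool


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def _scale_grid(dt: float, span: float, omega0: float, dj: float,
                s0: float | None, n_scales: int | None) -> np.ndarray:
    ff = fourier_factor(omega0)
    if s0 is None:
        s0 = 2.0 * dt
    if n_scales is None:
        s_max = span * MAX_PERIOD_FRACTION / ff
        if s_max <= s0:
            raise ValueError("series too short for any scale above s0")
        n_scales = int(np.floor(np.log2(s_max / s0) / dj)) + 1
    return s0 * 2.0 ** (dj * np.arange(n_scales))


def _batch_power(values: np.ndarray, dt: float, scales: np.ndarray,
                 omega0: float) -> np.ndarray:
    """Wavelet power for each row of ``values`` (m x n) -> (m, n_scales, n).

    Each row is standardized independently; power is the squared modulus of
    the transform without per-scale rectification (the significance test
    processes surrogates identically, so any scale bias cancels).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, n = values.shape
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant series has no wavelet spectrum")
    x = (values - values.mean(axis=1, keepdims=True)) / sd
    npad = _next_pow2(n)
    xpad = np.zeros((m, npad))
    xpad[:, :n] = x
    xf = np.fft.fft(xpad, axis=1)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    power = np.empty((m, scales.size, n))
    norm_const = np.pi**-0.25
    for j, s in enumerate(scales):
        daughter = np.where(
            omega > 0,
            norm_const * np.sqrt(2.0 * np.pi * s / dt)
            * np.exp(-0.5 * (s * omega - omega0) ** 2),
            0.0,
        )
        w = np.fft.ifft(xf * daughter, axis=1)[:, :n]
        power[:, j, :] = np.abs(w) ** 2
    return power


def morlet_cwt(
    series: SampledSeries,
    omega0: float = 6.0,
    dj: float = 1.0 / 12.0,
    s0: float | None = None,
    n_scales: int | None = None,
) -> WaveletSpectrum:
    """Morlet wavelet power spectrum of an equidistant series.

    Parameters
    ----------
    series : SampledSeries
        Equidistant input of at least 25 points (shorter series cannot
        resolve useful periodicities).
    omega0 : float
        Morlet central frequency; 6 is the standard admissibility
        compromise.  Values below 5 violate the analytic approximation.
    dj : float
        Spacing of the dyadic scale grid in octaves (1/12 = twelve
        sub-octaves per doubling).
    s0, n_scales : optional
        Smallest scale (default ``2*dt``) and number of scales (default:
        enough to reach a period of one third of the span).
    """
    if not series.is_equidistant:
        raise ValueError(f"series {series.label!r} is not equidistant; "
                         "interpolate before wavelet analysis")
    if series.n < MIN_SERIES_LENGTH:
        raise ValueError(
            f"series {series.label!r} has {series.n} points; at least "
            f"{MIN_SERIES_LENGTH} are required for wavelet analysis"
        )
    if omega0 < 5:
        raise ValueError("omega0 must be at least 5")
    dt = series.dt
    scales = _scale_grid(dt, series.span, omega0, dj, s0, n_scales)
    power = _batch_power(series.values[None, :], dt, scales, omega0)[0]
    ff = fourier_factor(omega0)
    periods = scales * ff
    dist = np.minimum(series.times - series.times[0],
                      series.times[-1] - series.times)
    coi = ff * dist / np.sqrt(2.0)
    params = {
        "omega0": omega0,
        "dj": dj,
        "s0": float(scales[0]),
        "n_scales": int(scales.size),
        "dt": dt,
    }
    return WaveletSpectrum(series.label, series.times.copy(), periods, scales,
                           power, coi, params)


def cone_of_influence(spectrum: WaveletSpectrum) -> np.ndarray:
    """Maximum trustworthy period per time point (days)."""
    return spectrum.coi.copy()


def global_spectrum(spectrum: WaveletSpectrum, coi_masked: bool = True) -> GlobalSpectrum:
    """Time-average of wavelet power per period.

    With ``coi_masked`` (the default) cells outside the cone of influence
    are excluded from the average; a period row entirely outside the cone
    has no defined mean and is reported as NaN.
    """
    if coi_masked:
        valid = spectrum.coi_mask
        sums = np.where(valid, spectrum.power, 0.0).sum(axis=1)
        counts = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        mean[counts == 0] = np.nan
    else:
        mean = spectrum.power.mean(axis=1)
    return GlobalSpectrum(spectrum.periods.copy(), mean, coi_masked)


def dominant_period(
    spectrum: WaveletSpectrum,
    window: tuple[float, float] | None = None,
    refine: bool = True,
) -> float:
    """Period of maximal time-averaged power within a time window.

    The average is restricted to cells inside the cone of influence.  Ties
    are broken toward the shorter period.  With ``refine`` the discrete
    argmax is sharpened by parabolic interpolation of the power profile on
    the log-period axis, which removes most of the quantization of the
    dyadic period grid.
    """
    t = spectrum.times
    if window is None:
        in_window = np.ones(t.size, dtype=bool)
    else:
        lo, hi = window
        if hi <= lo:
            raise ValueError("empty window")
        in_window = (t >= lo) & (t <= hi)
        if not np.any(in_window):
            raise ValueError(f"window {window} contains no time points of the "
                             f"series span ({t[0]}, {t[-1]})")
    valid = spectrum.coi_mask & in_window[None, :]
    sums = np.where(valid, spectrum.power, 0.0).sum(axis=1)
    counts = valid.sum(axis=1)
    profile = np.full(spectrum.periods.size, -np.inf)
    has = counts > 0
    profile[has] = sums[has] / counts[has]
    if not np.any(has):
        raise ValueError("no spectrum cell inside both window and cone of influence")
    i = int(np.argmax(profile))  # first maximum = shortest period on ties
    period = spectrum.periods[i]
    if refine and 0 < i < profile.size - 1 and np.isfinite(profile[i - 1]) \
            and np.isfinite(profile[i + 1]):
        denom = profile[i - 1] - 2.0 * profile[i] + profile[i + 1]
        if denom < 0:
            delta = 0.5 * (profile[i - 1] - profile[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            dj = spectrum.params["dj"]
            period = float(period * 2.0 ** (delta * dj))
    return float(period)
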