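"""Count-table preprocessing for wavelet analysis.

The fixed pipeline order is: read-depth filter -> relative abundance ->
core-taxon selection -> centered log-ratio (CLR) transform -> cubic
Hermite interpolation onto an equidistant grid -> Box-Cox rescaling with
PPCC-optimal exponent.  Each stage is exposed separately;
:func:`preprocess_table` chains them.

CLR operates per sample: fractions are log-transformed and centered by
their geometric mean, so each output column sums to zero.  Zeros are
handled by a configurable policy before the log (default: replace with
half the smallest nonzero fraction of that sample).

Box-Cox is applied per series; non-positive series are first shifted so
their minimum sits at 1 (CLR output can be negative; a unit floor keeps
the log branch finite).  The exponent lambda maximizes the normal
probability plot correlation coefficient (PPCC) on a grid over [-2, 2].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import ndtri
from skbio.stats.composition import clr as _skbio_clr

from .series import CountTable, RegularSeriesSet, SampledSeries

__all__ = [
    "RelativeTable",
    "PreprocessConfig",
    "filter_low_depth",
    "relative_abundance",
    "select_core_taxa",
    "union_across_subjects",
    "clr_transform",
    "interpolate_equidistant",
    "boxcox_rescale",
    "preprocess_table",
]

logger = logging.getLogger(__name__)

#: floor applied to each CLR series before Box-Cox (see module docstring)
BOXCOX_SHIFT_FLOOR = 1.0


@dataclass(frozen=True)
class RelativeTable:
    """Per-sample relative abundances (columns sum to 1)."""

    taxa: tuple[str, ...]
    sample_times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "sample_times",
                           np.asarray(self.sample_times, dtype=float))
        if fr.shape != (len(self.taxa), self.sample_times.size):
            raise ValueError("fractions shape inconsistent")
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(fr.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.sample_times.size


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    Defaults follow the analysis this package implements: samples under
    500 reads are dropped; core taxa must exceed a relative abundance of
    0.005 in at least 25% of samples (assessed over bootstrap resamples);
    the interpolation grid step is 1.6 days.
    """

    min_reads: int = 500
    prevalence: float = 0.25
    detection: float = 0.005
    n_boot: int = 100
    target_dt: float = 1.6
    boxcox_lambda_grid: tuple[float, float, float] = (-2.0, 2.0, 0.01)
    pseudocount_policy: str = "half-min"
    pseudocount: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError("prevalence must be in (0, 1]")
        if self.detection <= 0:
            raise ValueError("detection must be positive")
        if self.target_dt <= 0:
            raise ValueError("target_dt must be positive")


def filter_low_depth(table: CountTable, min_reads: int = 500) -> CountTable:
    """Drop samples with fewer than ``min_reads`` total reads (strictly
    less than: a sample at exactly the threshold is kept)."""
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    keep = table.reads_per_sample >= min_reads
    if not np.any(keep):
        raise ValueError(f"all samples have fewer than {min_reads} reads")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("depth filter removed %d of %d samples (< %d reads)",
                    dropped, table.n_samples, min_reads)
    return CountTable(table.taxa, table.sample_times[keep],
                      table.counts[:, keep])


def relative_abundance(table: CountTable) -> RelativeTable:
    totals = table.reads_per_sample
    if np.any(totals == 0):
        raise ValueError("cannot normalize a sample with zero reads")
    return RelativeTable(table.taxa, table.sample_times,
                         table.counts / totals[None, :])


def _core_criterion(fr: np.ndarray, detection: float, prevalence: float) -> np.ndarray:
    """Boolean per-taxon core criterion on a fractions matrix."""
    n_samples = fr.shape[1]
    hits = (fr > detection).sum(axis=1)
    return hits >= prevalence * n_samples


def select_core_taxa(
    rel: RelativeTable,
    detection: float = 0.005,
    prevalence: float = 0.25,
    n_boot: int = 100,
    seed: int = 0,
) -> list[str]:
    """Core-taxon selection: taxa whose relative abundance exceeds
    ``detection`` in at least a ``prevalence`` fraction of samples.

    With ``n_boot > 0`` the samples are resampled with replacement
    ``n_boot`` times and a taxon is retained when it passes the criterion
    in a majority of resamples, which stabilizes the selection near the
    thresholds.  An empty result is allowed (warned, not fatal).
    """
    if n_boot < 0:
        raise ValueError("n_boot must be non-negative")
    fr = rel.fractions
    if n_boot == 0:
        keep = _core_criterion(fr, detection, prevalence)
    else:
        rng = np.random.default_rng(seed)
        votes = np.zeros(len(rel.taxa), dtype=int)
        for _ in range(n_boot):
            idx = rng.integers(0, rel.n_samples, size=rel.n_samples)
            votes += _core_criterion(fr[:, idx], detection, prevalence)
        keep = votes > n_boot / 2
    selected = [t for t, k in zip(rel.taxa, keep) if k]
    if not selected:
        warnings.warn("core-taxon selection returned no taxa", stacklevel=2)
    return selected


def union_across_subjects(core_lists: list[list[str]]) -> list[str]:
    """Ordered union of per-subject core-taxon lists, stable by first
    appearance (taxa present in at least one subject are analyzed in all)."""
    if not core_lists:
        raise ValueError("need at least one core list")
    out: list[str] = []
    seen: set[str] = set()
    for lst in core_lists:
        for t in lst:
            if t not in seen:
                seen.add(t)
                out.append(t)
    return out


def _replace_zeros(col: np.ndarray, policy: str, pseudocount: float) -> np.ndarray:
    if not np.any(col == 0):
        return col
    if policy == "half-min":
        nz = col[col > 0]
        repl = nz.min() / 2.0
        col = np.where(col == 0, repl, col)
    elif policy == "pseudocount":
        col = col + pseudocount
    else:
        raise ValueError(f"unknown pseudocount policy {policy!r}")
    return col / col.sum()


def clr_transform(
    rel: RelativeTable,
    pseudocount_policy: str = "half-min",
    pseudocount: float = 1e-6,
) -> np.ndarray:
    """Centered log-ratio transform per sample; each output column sums to
    zero.  Zeros are replaced per the policy (default: half the smallest
    nonzero fraction of the sample) and the column renormalized first."""
    fr = rel.fractions.copy()
    zero_cols = np.flatnonzero(fr.sum(axis=0) == 0)
    if zero_cols.size:
        raise ValueError(f"samples with all-zero composition: {zero_cols.tolist()}")
    for j in range(fr.shape[1]):
        fr[:, j] = _replace_zeros(fr[:, j], pseudocount_policy, pseudocount)
    # skbio's clr expects compositions along the last axis (rows = samples)
    return _skbio_clr(fr.T).T


def interpolate_equidistant(series: SampledSeries, target_dt: float) -> SampledSeries:
    """Monotone (PCHIP) cubic Hermite interpolation onto the grid
    ``t0, t0+dt, ...`` up to the last observation — no extrapolation.

    The interpolant passes through every original observation exactly; the
    monotone slope choice avoids overshoot on spiky series.  The number of
    grid points over a span ``T`` is ``floor(T/dt) + 1``.
    """
    if series.n < 4:
        raise ValueError(f"series {series.label!r}: need at least 4 points "
                         "for cubic Hermite interpolation")
    if target_dt <= 0:
        raise ValueError("target_dt must be positive")
    t0, t1 = series.times[0], series.times[-1]
    n_grid = int(np.floor((t1 - t0) / target_dt + 1e-9)) + 1
    grid = t0 + target_dt * np.arange(n_grid)
    interp = PchipInterpolator(series.times, series.values)
    return SampledSeries(series.label, grid, interp(grid))


def _ppcc(sorted_y: np.ndarray, norm_quantiles: np.ndarray) -> float:
    y = sorted_y - sorted_y.mean()
    denom = np.linalg.norm(y) * np.linalg.norm(norm_quantiles)
    if denom == 0:
        return np.nan
    return float(y @ norm_quantiles / denom)


def _boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log(x)
    return (x**lam - 1.0) / lam


def boxcox_rescale(
    series: SampledSeries,
    lambda_grid: tuple[float, float, float] = (-2.0, 2.0, 0.01),
) -> tuple[SampledSeries, float, float]:
    """Box-Cox rescale a series to suppress sharp peaks and approximate
    normality.

    Box-Cox needs positive support, but CLR output can be negative: a
    series whose minimum is at or below zero is shifted so the minimum
    equals 1 (already-positive series are left unshifted, so the exponent
    of e.g. log-normal data is recovered undistorted).  lambda is chosen
    on the grid maximizing the PPCC — the correlation between the ordered
    transformed values and standard normal quantiles at plotting positions
    ``(i - 3/8) / (n + 1/4)``.  Returns the transformed series standardized
    to zero mean and unit variance, plus ``(lambda, shift)``.
    """
    if series.n < 10:
        raise ValueError("need at least 10 observations for Box-Cox/PPCC")
    x = series.values
    if np.ptp(x) == 0:
        raise ValueError(f"series {series.label!r} is constant; PPCC undefined")
    shift = BOXCOX_SHIFT_FLOOR - x.min() if x.min() <= 0 else 0.0
    xpos = x + shift
    lo, hi, step = lambda_grid
    lams = np.arange(lo, hi + step / 2, step)
    n = x.size
    pp = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    nq = ndtri(pp)
    order = np.argsort(xpos)
    xs = xpos[order]
    best_lam, best_r = lams[0], -np.inf
    for lam in lams:
        r = _ppcc(_boxcox(xs, float(lam)), nq)
        if np.isfinite(r) and r > best_r:
            best_r, best_lam = r, float(lam)
    y = _boxcox(xpos, best_lam)
    y = (y - y.mean()) / y.std()
    return series.with_values(y), best_lam, float(shift)


def preprocess_table(
    table: CountTable,
    config: PreprocessConfig | None = None,
    taxa: list[str] | None = None,
) -> tuple[RegularSeriesSet, dict]:
    """Run the full preprocessing pipeline on one subject's count table.

    ``taxa`` overrides core selection (used when analyzing the union of
    core taxa across subjects).  Returns the equidistant, CLR + Box-Cox
    transformed series set and a provenance record (parameters, retained
    taxa, per-series lambda and shift).
    """
    config = config or PreprocessConfig()
    filtered = filter_low_depth(table, config.min_reads)
    rel = relative_abundance(filtered)
    if taxa is None:
        taxa = select_core_taxa(rel, config.detection, config.prevalence,
                                config.n_boot, config.seed)
    missing = [t for t in taxa if t not in rel.taxa]
    if missing:
        raise ValueError(f"requested taxa absent from table: {missing}")
    if len(taxa) < 3:
        raise ValueError(f"only {len(taxa)} taxa retained; need at least 3")
    clr_all = clr_transform(rel, config.pseudocount_policy, config.pseudocount)
    rows = [rel.taxa.index(t) for t in taxa]
    provenance: dict = {
        "min_reads": config.min_reads,
        "detection": config.detection,
        "prevalence": config.prevalence,
        "n_boot": config.n_boot,
        "target_dt": config.target_dt,
        "pseudocount_policy": config.pseudocount_policy,
        "seed": config.seed,
        "taxa": list(taxa),
        "n_samples": int(filtered.n_samples),
        "boxcox": {},
    }
    out = []
    grid = None
    for t, i in zip(taxa, rows):
        s = SampledSeries(t, rel.sample_times, clr_all[i])
        si = interpolate_equidistant(s, config.target_dt)
        sb, lam, shift = boxcox_rescale(si, config.boxcox_lambda_grid)
        provenance["boxcox"][t] = {"lambda": lam, "shift": shift}
        grid = sb.times
        out.append(sb.values)
    provenance["n_grid"] = int(grid.size)
    return RegularSeriesSet(tuple(taxa), grid, np.vstack(out),
                            meta={"provenance": provenance}), provenance
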