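"""Core containers for labeled time series and count tables.

Timestamps are in days throughout.  A :class:`SampledSeries` may be
irregularly sampled; wavelet analysis requires an equidistant grid, which
:func:`wavecluster.preprocessing.interpolate_equidistant` produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampledSeries",
    "SyntheticPanel",
    "CountTable",
    "RegularSeriesSet",
]

#: relative tolerance used when deciding whether a grid is equidistant
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class SampledSeries:
    """One labeled time series: strictly increasing timestamps plus values."""

    label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValueError(
                f"series {self.label!r}: {times.size} timestamps "
                f"but {values.size} values"
            )
        if times.size < 2:
            raise ValueError(f"series {self.label!r}: need at least 2 observations")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"series {self.label!r}: timestamps not strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ValueError(f"series {self.label!r}: non-finite entries")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        """Total observed span in days."""
        return float(self.times[-1] - self.times[0])

    @property
    def is_equidistant(self) -> bool:
        steps = np.diff(self.times)
        return bool(np.all(np.abs(steps - steps[0]) <= _GRID_RTOL * abs(steps[0])))

    @property
    def dt(self) -> float:
        """Grid step; only meaningful for equidistant series."""
        if not self.is_equidistant:
            raise ValueError(f"series {self.label!r} is not equidistant")
        return float(self.times[1] - self.times[0])

    def with_values(self, values: np.ndarray, label: str | None = None) -> "SampledSeries":
        return SampledSeries(label if label is not None else self.label,
                             self.times, np.asarray(values, dtype=float))


@dataclass(frozen=True)
class SyntheticPanel:
    """A collection of synthetic series plus the partition of labels that a
    spectrum-based clustering is expected to recover (ground truth)."""

    series: tuple[SampledSeries, ...]
    ground_truth_groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.series]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate series labels")
        covered: set[str] = set()
        for group in self.ground_truth_groups:
            if covered & group:
                raise ValueError("a label appears in more than one ground-truth group")
            covered |= group
        if covered != set(labels):
            raise ValueError("ground-truth groups must partition the label set")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.series]

    def __getitem__(self, label: str) -> SampledSeries:
        for s in self.series:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class CountTable:
    """Taxa-by-sample table of non-negative integer counts with per-sample
    collection times (days)."""

    taxa: tuple[str, ...]
    sample_times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        times = np.asarray(self.sample_times, dtype=float)
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        object.__setattr__(self, "sample_times", times)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (taxa x samples)")
        if counts.shape != (len(self.taxa), times.size):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.taxa)} taxa and {times.size} samples"
            )
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if not np.all(np.diff(times) > 0):
            raise ValueError("sample times not strictly increasing")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return self.sample_times.size

    @property
    def reads_per_sample(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class RegularSeriesSet:
    """A set of series sharing one equidistant time grid (rows = labels)."""

    labels: tuple[str, ...]
    grid_times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        grid = np.asarray(self.grid_times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid_times", grid)
        object.__setattr__(self, "values", values)
        steps = np.diff(grid)
        if grid.size < 2 or not np.all(
            np.abs(steps - steps[0]) <= 1e-9 * max(abs(steps[0]), 1.0)
        ):
            raise ValueError("grid_times must be equidistant")
        if values.shape != (len(self.labels), grid.size):
            raise ValueError("values shape inconsistent with labels/grid")

    @property
    def dt(self) -> float:
        return float(self.grid_times[1] - self.grid_times[0])

    def series(self, label: str) -> SampledSeries:
        i = self.labels.index(label)
        return SampledSeries(label, self.grid_times, self.values[i])

    def iter_series(self):
        for i, label in enumerate(self.labels):
            yield SampledSeries(label, self.grid_times, self.values[i])
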