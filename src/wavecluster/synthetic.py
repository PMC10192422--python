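"""Synthetic test signals and microbiome-like compositional count tables.

Two kinds of synthetic data are produced here:

* a fixed panel of eight oscillatory signals (stationary sinusoids,
  antiphase pairs, and period-switching signals) that exercises the whole
  wavelet-clustering pipeline, with known groups of shared periodicity;
* compositional count tables emulating dense 16S time series — irregular
  timestamps, groups of taxa whose latent log-abundances oscillate at a
  shared period but with independent phases, and spiky low-abundance
  filler taxa — so that parameter-recovery experiments have a ground truth.
"""

from __future__ import annotations

import numpy as np

from .series import CountTable, SampledSeries, SyntheticPanel

__all__ = [
    "make_sinusoid",
    "make_switching_sinusoid",
    "make_fig1_panel",
    "make_synthetic_community",
    "make_community_latents",
    "community_ground_truth",
]


def _check_period(period: float, dt: float) -> None:
    if period <= 2.0 * dt:
        raise ValueError(
            f"period {period} days is at or below the Nyquist limit for a "
            f"{dt}-day grid (need period > {2 * dt})"
        )


def make_sinusoid(
    period: float,
    phase: float = 0.0,
    span: float = 100.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str | None = None,
) -> SampledSeries:
    """Sinusoid ``sin(2*pi*t/period + phase)`` on an equidistant grid,
    optionally with additive Gaussian noise.

    Parameters
    ----------
    period : float
        Oscillation period in days; must exceed twice the grid step.
    phase : float
        Phase offset in radians (``pi`` gives the antiphase twin).
    span, dt : float
        Length of the grid (days) and its step.
    noise_sd : float
        Standard deviation of additive white Gaussian noise.
    seed : int
        Seed for the noise generator; the result is deterministic given it.
    """
    _check_period(period, dt)
    if span < 2 * period:
        raise ValueError("span must cover at least two full periods")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, span, dt)
    x = np.sin(2.0 * np.pi * t / period + phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=t.size)
    if label is None:
        label = f"sin_p{period:g}"
    return SampledSeries(label, t, x)


def make_switching_sinusoid(
    period_a: float,
    period_b: float,
    switch_time: float,
    span: float = 100.0,
    dt: float = 1.0,
    seed: int = 0,
    label: str | None = None,
) -> SampledSeries:
    """Signal oscillating at ``period_a`` before ``switch_time`` and at
    ``period_b`` after, with continuous phase at the switch.

    Phase continuity (rather than a phase reset) avoids a discontinuity that
    would inject spurious broadband power exactly at the switch.
    """
    _check_period(period_a, dt)
    _check_period(period_b, dt)
    if not (0.0 < switch_time < span):
        raise ValueError("switch_time must lie strictly inside the span")
    t = np.arange(0.0, span, dt)
    phase_at_switch = 2.0 * np.pi * switch_time / period_a
    phase = np.where(
        t < switch_time,
        2.0 * np.pi * t / period_a,
        phase_at_switch + 2.0 * np.pi * (t - switch_time) / period_b,
    )
    if label is None:
        label = f"switch_p{period_a:g}to{period_b:g}"
    return SampledSeries(label, t, np.sin(phase))


def make_fig1_panel() -> SyntheticPanel:
    """The eight-signal demonstration panel (span 100 days, daily grid).

    * ``s1``: stationary sinusoid, period 8 days;
    * ``s2``: the same sinusoid in antiphase — identical spectrum, Spearman
      dissimilarity ~2;
    * ``s3``: stationary, period 20 days, in quadrature (phase pi/2) with
      the 20-day plateaus of the switching signals so that it shares their
      periodicity without being value-correlated with either;
    * ``s4``: stationary, period 26 days (a slow filler; its period is kept
      away from the switching signals' plateaus so that spectrum similarity
      reflects shared time-localized structure, not an accidental overlap
      with half of a switching signal);
    * ``s5``: switches from ~13-day to ~4-day oscillation at day 50;
    * ``s6``: noisy period-8 sinusoid (noise sd 0.3, fixed internal seed),
      in quadrature with s1 and s2 — spectrally a member of the period-8
      family but value-correlated with neither;
    * ``s7``: switches from 4-day to 20-day oscillation at day 50;
    * ``s8``: the mirror of ``s7`` — 20-day then 4-day.

    ``s7`` and ``s8`` share the same time-averaged spectrum while their
    time-resolved spectra are opposite; ``s5`` and ``s8`` both slow down
    early and speed up late, so a spectrum-based clustering should place
    them together.  The whole construction is deterministic so downstream
    results are reproducible bit for bit.
    """
    series = (
        make_sinusoid(8, 0.0, label="s1"),
        make_sinusoid(8, np.pi, label="s2"),
        make_sinusoid(20, np.pi / 2, label="s3"),
        make_sinusoid(26, 0.0, label="s4"),
        make_switching_sinusoid(13, 4, 50, label="s5"),
        make_sinusoid(8, np.pi / 2, noise_sd=0.3, seed=61, label="s6"),
        make_switching_sinusoid(4, 20, 50, label="s7"),
        make_switching_sinusoid(20, 4, 50, label="s8"),
    )
    groups = (
        frozenset({"s1", "s2", "s6"}),   # stationary period-8 family
        frozenset({"s5", "s8"}),         # slow-then-fast switchers
        frozenset({"s3"}),
        frozenset({"s4"}),
        frozenset({"s7"}),               # fast-then-slow: opposite of s5/s8
    )
    return SyntheticPanel(series, groups)


def make_community_latents(
    n_taxa: int,
    groups: list[tuple[float, int]],
    span: float = 450.0,
    mean_dt: float = 1.6,
    jitter: float = 0.2,
    seed: int = 0,
    group_amplitude: float = 2.0,
    taxon_noise_sd: float = 0.5,
    group_mean: float = 3.0,
    filler_mean: float = 0.0,
    filler_scale: float = 1.2,
):
    """Latent log-abundance panel underlying :func:`make_synthetic_community`.

    Returns ``(times, latents, labels, groups_map)`` where ``latents`` is an
    ``n_taxa x n_samples`` matrix of log-abundances.  Taxa in a period group
    follow a shared sinusoid of that period with taxon-specific phases —
    evenly spaced around the circle (plus a random per-group offset), so
    that group membership is carried by the shared period alone and not by
    value correlation — and additive Gaussian noise; the remaining taxa are
    "spiky" fillers with heavy-tailed (Student-t, 3 df) fluctuations around
    a low baseline.

    ``groups_map`` maps each label to its group name (``"p<period>"`` for
    oscillating groups, ``"filler"`` otherwise); labels also carry the group
    name as a prefix so the truth is recoverable from a bare count table.
    """
    n_members = sum(m for _, m in groups)
    if n_taxa < n_members:
        raise ValueError("n_taxa smaller than the sum of group member counts")
    if not (0.0 <= jitter < 0.5):
        raise ValueError("jitter must be in [0, 0.5)")
    for period, _ in groups:
        if period <= 2.0 * mean_dt:
            raise ValueError(
                f"group period {period} not resolvable at mean spacing {mean_dt}"
            )
    rng = np.random.default_rng(seed)
    # irregular timestamps: mean spacing mean_dt with multiplicative jitter
    n_samples = int(np.floor(span / mean_dt)) + 1
    steps = mean_dt * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=n_samples - 1))
    times = np.concatenate([[0.0], np.cumsum(steps)])
    times *= span / times[-1]  # pin the span exactly

    labels: list[str] = []
    groups_map: dict[str, str] = {}
    latents = np.empty((n_taxa, times.size))
    row = 0
    for period, member_count in groups:
        gname = f"p{period:g}"
        group_offset = rng.uniform(0.0, 2.0 * np.pi)
        for j in range(member_count):
            label = f"{gname}_t{j + 1:02d}"
            phase = group_offset + 2.0 * np.pi * j / member_count
            latents[row] = (
                group_mean
                + group_amplitude * np.sin(2.0 * np.pi * times / period + phase)
                + rng.normal(0.0, taxon_noise_sd, size=times.size)
            )
            labels.append(label)
            groups_map[label] = gname
            row += 1
    for j in range(n_taxa - n_members):
        label = f"filler_t{j + 1:02d}"
        latents[row] = filler_mean + filler_scale * rng.standard_t(3, size=times.size)
        labels.append(label)
        groups_map[label] = "filler"
        row += 1
    return times, latents, labels, groups_map


def make_synthetic_community(
    n_taxa: int = 19,
    groups: list[tuple[float, int]] | None = None,
    span: float = 450.0,
    mean_dt: float = 1.6,
    jitter: float = 0.2,
    depth: int = 10_000,
    seed: int = 0,
    **latent_kwargs,
) -> CountTable:
    """Microbiome-like compositional count table with known period groups.

    Counts are drawn per sample from a multinomial over the softmax of the
    latent log-abundances, so each column sums exactly to ``depth`` — the
    compositional constraint that CLR preprocessing assumes.  Taxon labels
    are prefixed with their ground-truth group (see
    :func:`community_ground_truth`).  Deterministic given ``seed``.
    """
    if groups is None:
        groups = [(30.0, 5), (64.0, 5)]
    if depth < 1000:
        raise ValueError("depth must be at least 1000 reads")
    times, latents, labels, _ = make_community_latents(
        n_taxa, groups, span=span, mean_dt=mean_dt, jitter=jitter, seed=seed,
        **latent_kwargs,
    )
    rng = np.random.default_rng(seed + 1)
    probs = np.exp(latents - latents.max(axis=0, keepdims=True))
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.empty(latents.shape, dtype=np.int64)
    for j in range(times.size):
        counts[:, j] = rng.multinomial(depth, probs[:, j])
    return CountTable(tuple(labels), times, counts)


def community_ground_truth(table_or_labels) -> dict[str, str]:
    """Recover the group name encoded in synthetic-community taxon labels."""
    labels = getattr(table_or_labels, "taxa", table_or_labels)
    return {lab: lab.rsplit("_t", 1)[0] for lab in labels}
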