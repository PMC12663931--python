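"""Spike-latency input patterns and their noisy variants.

Input patterns are collections of afferent spike trains within a fixed
processing window.  In a latency pattern every afferent fires the same
number of spikes at times drawn independently and uniformly over the
window, so that classification cannot rely on spike counts and must read
out spike timing.  This module generates such patterns, expands
multi-spike patterns into rank-ordered single-spike patterns (the
construction that maps ordinal synapses onto static ones), corrupts
patterns with temporal jitter, spike deletions or background firing, and
builds the paired-synchrony patterns used in the spatiotemporal
correlation tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SpikePattern",
    "PatternBatch",
    "NoiseSpec",
    "gen_latency_batch",
    "expand_to_ordered_single_spike",
    "corrupt_pattern",
    "gen_pairing_batch",
    "round_half_up",
]

DEFAULT_DURATION = 0.5  # seconds; standard processing window T


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 always rounding up (no banker's rounding)."""
    return int(np.floor(x + 0.5))


@dataclass
class SpikePattern:
    """Spike times of ``n_afferents`` input neurons within ``[0, duration]``.

    ``times[i]`` holds the sorted spike times (seconds) of afferent ``i``.
    For latency patterns every afferent carries exactly
    ``n_spikes_per_afferent`` spikes; ragged patterns (after deletions)
    leave that field ``None``.
    """

    duration: float
    times: list[np.ndarray]
    n_spikes_per_afferent: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        for i, t in enumerate(self.times):
            if t.size and (t.min() < 0 or t.max() > self.duration + 1e-12):
                raise ValueError(f"afferent {i}: spike times outside [0, T]")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError(f"afferent {i}: spike times not sorted")
        if self.n_spikes_per_afferent is not None:
            for i, t in enumerate(self.times):
                if t.size != self.n_spikes_per_afferent:
                    raise ValueError(
                        f"afferent {i}: expected {self.n_spikes_per_afferent} spikes, got {t.size}"
                    )

    @property
    def n_afferents(self) -> int:
        return len(self.times)

    @property
    def n_total_spikes(self) -> int:
        return sum(t.size for t in self.times)

    def merged(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Time-sorted view ``(times, afferent_index, within-afferent rank)``.

        Rank is zero-based spike order within each afferent; ties in time are
        broken by afferent index (stable sort), which never affects the
        voltage because coincident spikes commute in the sum.
        """
        n = self.n_total_spikes
        ts = np.empty(n)
        aff = np.empty(n, dtype=np.int64)
        rank = np.empty(n, dtype=np.int64)
        k = 0
        for i, t in enumerate(self.times):
            m = t.size
            ts[k : k + m] = t
            aff[k : k + m] = i
            rank[k : k + m] = np.arange(m)
            k += m
        order = np.argsort(ts, kind="stable")
        return ts[order], aff[order], rank[order]


@dataclass
class PatternBatch:
    """A fixed classification batch: patterns plus binary target/null labels."""

    patterns: list[SpikePattern]
    labels: np.ndarray
    load: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.patterns) != self.labels.size:
            raise ValueError("labels must match number of patterns")
        if self.labels.size and not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be binary (0=null, 1=target)")

    def __len__(self) -> int:
        return len(self.patterns)


@dataclass
class NoiseSpec:
    """Corruption model applied to template patterns.

    Exactly one of the three modes is active:

    - ``jitter``: add independent Gaussian noise (SD ``sigma``) to every spike
      time;
    - ``delete``: remove each spike independently with probability ``p_del``
      (synaptic failures);
    - ``delete_with_background``: deletions as above plus homogeneous Poisson
      background spikes at ``background_rate`` spikes per afferent per
      pattern, chosen as ``p_del * n_spikes`` so the expected spike count is
      preserved.
    """

    mode: Literal["jitter", "delete", "delete_with_background"]
    sigma: float = 0.0
    p_del: float = 0.0
    background_rate: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("jitter", "delete", "delete_with_background"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0.0 <= self.p_del <= 1.0:
            raise ValueError("p_del must lie in [0, 1]")

    def resolved_background_rate(self, n_spikes: int) -> float:
        if self.background_rate is not None:
            return self.background_rate
        return self.p_del * n_spikes


def _draw_latency_pattern(
    rng: np.random.Generator, n_afferents: int, n_spikes: int, duration: float
) -> SpikePattern:
    raw = rng.uniform(0.0, duration, size=(n_afferents, n_spikes))
    raw.sort(axis=1)
    return SpikePattern(duration, [row for row in raw], n_spikes)


def gen_latency_batch(
    n_afferents: int,
    n_spikes: int,
    duration: float = DEFAULT_DURATION,
    load: float = 1.0,
    overlap_jitter_sd: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> PatternBatch:
    """Generate a batch of ``p = round(load * n_afferents)`` latency patterns.

    In the default iid mode every spike time is drawn uniformly on
    ``[0, duration]`` independently across patterns, afferents and spikes;
    target/null labels are fair coin flips, so no generalization is possible
    and the batch probes pure storage.  In overlap mode
    (``overlap_jitter_sd`` set, typically 10 ms) all patterns are Gaussian
    jitters of a single template, producing strongly overlapping batches.
    """
    if n_afferents < 1 or n_spikes < 1:
        raise ValueError("n_afferents and n_spikes must be positive")
    if load <= 0:
        raise ValueError("load must be positive")
    if overlap_jitter_sd is not None and overlap_jitter_sd <= 0:
        raise ValueError("overlap_jitter_sd must be positive when given")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = round_half_up(load * n_afferents)
    patterns: list[SpikePattern] = []
    if overlap_jitter_sd is None:
        for _ in range(p):
            patterns.append(_draw_latency_pattern(rng, n_afferents, n_spikes, duration))
    else:
        template = rng.uniform(0.0, duration, size=(n_afferents, n_spikes))
        for _ in range(p):
            jittered = template + rng.normal(0.0, overlap_jitter_sd, size=template.shape)
            jittered = np.clip(jittered, 0.0, duration)
            jittered.sort(axis=1)
            patterns.append(SpikePattern(duration, [row for row in jittered], n_spikes))
    labels = rng.integers(0, 2, size=p).astype(np.int8)
    return PatternBatch(patterns, labels, load=load)


def expand_to_ordered_single_spike(pattern: SpikePattern) -> SpikePattern:
    """Expand an ``N x nspikes`` latency pattern to ``N * nspikes`` single-spike afferents.

    Afferent ``i`` of the original pattern becomes the group of afferents
    ``i*nspikes .. (i+1)*nspikes - 1``; the j-th smallest spike time of the
    group is always assigned to the j-th afferent of the group, fixing the
    within-group rank order across any batch.  Training static synapses on
    such expanded patterns is exactly equivalent to training ordinal
    synapses on the original multi-spike patterns.
    """
    if pattern.n_spikes_per_afferent is None:
        counts = {t.size for t in pattern.times}
        if len(counts) != 1:
            raise ValueError("expansion requires a uniform spike count per afferent")
        n_spikes = counts.pop()
    else:
        n_spikes = pattern.n_spikes_per_afferent
    new_times = [np.array([t[j]]) for t in pattern.times for j in range(n_spikes)]
    return SpikePattern(pattern.duration, new_times, 1)


def corrupt_pattern(
    pattern: SpikePattern,
    noise: NoiseSpec,
    seed: int | np.random.Generator | None = None,
) -> SpikePattern:
    """Apply one independent draw of the noise model to a template pattern.

    Jittered times falling outside the window are clipped to the boundary so
    spike counts are preserved; jitter can reorder spikes, so trains are
    re-sorted.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = pattern.duration
    new_times: list[np.ndarray] = []
    if noise.mode == "jitter":
        for t in pattern.times:
            jt = np.clip(t + rng.normal(0.0, noise.sigma, size=t.size), 0.0, T)
            jt.sort()
            new_times.append(jt)
        nspk = pattern.n_spikes_per_afferent
    else:
        nspk_template = pattern.n_spikes_per_afferent or max(
            (t.size for t in pattern.times), default=0
        )
        rate = (
            noise.resolved_background_rate(nspk_template)
            if noise.mode == "delete_with_background"
            else 0.0
        )
        for t in pattern.times:
            keep = rng.random(t.size) >= noise.p_del
            kept = t[keep]
            if rate > 0:
                n_bg = rng.poisson(rate)
                kept = np.concatenate([kept, rng.uniform(0.0, T, size=n_bg)])
            kept.sort()
            new_times.append(kept)
        nspk = None
    return SpikePattern(T, new_times, nspk)


def pairings(n_afferents: int, pairing_id: int) -> list[tuple[int, int]]:
    """The two fixed afferent pairings used by the correlation tasks.

    Pairing 1 couples adjacent afferents ``(0,1), (2,3), ...``; pairing 2
    couples afferents half the array apart ``(0, N/2), (1, N/2+1), ...``
    (for 6 afferents: 1&4, 2&5, 3&6 in one-based labels).
    """
    if n_afferents % 2:
        raise ValueError("n_afferents must be even")
    half = n_afferents // 2
    if pairing_id == 1:
        return [(2 * k, 2 * k + 1) for k in range(half)]
    if pairing_id == 2:
        return [(k, k + half) for k in range(half)]
    raise ValueError("pairing_id must be 1 or 2")


def gen_pairing_batch(
    n_afferents: int,
    pairing_id: int,
    delta: float,
    n_patterns: int,
    delta_noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    label: int = 0,
    first_spike_window: float = DEFAULT_DURATION,
) -> PatternBatch:
    """Patterns of ``N/2`` synchronously firing afferent pairs.

    Each pair fires together at a time drawn uniformly on
    ``[0, first_spike_window]`` and again after a delay ``delta`` shared by
    all pairs of the pattern (plus per-pattern Gaussian delay noise of SD
    ``delta_noise_sd``, 1 ms during training).  Every afferent fires exactly
    two spikes.  The simulation window is extended beyond the first-spike
    window so second spikes are never truncated.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if delta_noise_sd < 0:
        raise ValueError("delta_noise_sd must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = pairings(n_afferents, pairing_id)
    duration = first_spike_window + delta + 6.0 * delta_noise_sd + 1e-9
    patterns = []
    for _ in range(n_patterns):
        d = max(delta + rng.normal(0.0, delta_noise_sd), 0.0) if delta_noise_sd else delta
        first = rng.uniform(0.0, first_spike_window, size=len(pairs))
        times: list[np.ndarray | None] = [None] * n_afferents
        for (a, b), t0 in zip(pairs, first):
            st = np.array([t0, min(t0 + d, duration)])
            times[a] = st
            times[b] = st.copy()
        patterns.append(SpikePattern(duration, times, 2))  # type: ignore[arg-type]
    labels = np.full(n_patterns, label, dtype=np.int8)
    return PatternBatch(patterns, labels)
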