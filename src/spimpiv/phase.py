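"""Heartbeat-phase assignment and binning for periodic-flow averaging.

Correlation averaging assumes a stationary flow; a beating heart is only
periodically stationary.  Frame pairs are therefore assigned a heartbeat
phase in ``[0, 2 pi)`` by interpolating a phase-anchor series recorded on a
separate synchronisation channel, and grouped into phase bins (default 30
bins of width ``2 pi / 30 ~ 0.209`` rad) before the per-bin ensemble
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .units import TWO_PI

__all__ = [
    "PhaseAnchorSeries",
    "PhaseBinning",
    "interpolate_phase",
    "assign_pair_phase",
    "assign_phases",
    "bin_pairs",
    "split_half_flow_uncertainty",
]


@dataclass
class PhaseAnchorSeries:
    """Timestamped phases from the synchronisation channel.

    Timestamps (ms) must be strictly increasing; phases are wrapped on
    input and unwrapped internally, and the unwrapped phase must be
    non-decreasing (the heart does not beat backwards).
    """

    timestamps: np.ndarray
    phases: np.ndarray
    unwrapped: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float).ravel()
        self.phases = np.mod(np.asarray(self.phases, dtype=float).ravel(), TWO_PI)
        if self.timestamps.size < 2:
            raise ValueError("need at least two phase anchors")
        if self.timestamps.size != self.phases.size:
            raise ValueError("timestamps and phases differ in length")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("anchor timestamps must be strictly increasing")
        self.unwrapped = np.unwrap(self.phases)
        if np.any(np.diff(self.unwrapped) < 0):
            raise ValueError("unwrapped anchor phase must be non-decreasing")

    @property
    def t_min(self) -> float:
        return float(self.timestamps[0])

    @property
    def t_max(self) -> float:
        return float(self.timestamps[-1])


@dataclass
class PhaseBinning:
    """Half-open phase bins ``[k * width, (k+1) * width)`` tiling the cycle."""

    n_bins: int = 30

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def bin_width(self) -> float:
        return TWO_PI / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_index(self, phase: np.ndarray) -> np.ndarray:
        return (np.floor(np.asarray(phase) / self.bin_width).astype(int)
                % self.n_bins)


def interpolate_phase(anchors: PhaseAnchorSeries, t) -> float | np.ndarray:
    """Phase at time ``t`` (ms) by linear interpolation of unwrapped anchors.

    No extrapolation: times outside the anchored interval raise.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < anchors.t_min) or np.any(t_arr > anchors.t_max):
        raise ValueError(
            f"time outside anchored interval "
            f"[{anchors.t_min:g}, {anchors.t_max:g}] ms")
    phi = np.interp(t_arr, anchors.timestamps, anchors.unwrapped) % TWO_PI
    return float(phi) if np.isscalar(t) or t_arr.ndim == 0 else phi


def assign_pair_phase(pair, anchors: PhaseAnchorSeries) -> float:
    """Phase of one frame pair, evaluated at the midpoint of its exposures."""
    t_mid = pair.timestamp + pair.dt / 2.0
    return float(interpolate_phase(anchors, t_mid))


def assign_phases(pairs: Sequence, anchors: PhaseAnchorSeries,
                  ) -> tuple[list, int]:
    """Assign phases to all pairs; pairs outside the anchor range are dropped.

    Returns the phased pairs and the dropped count.
    """
    kept, dropped = [], 0
    for p in pairs:
        t_mid = p.timestamp + p.dt / 2.0
        if t_mid < anchors.t_min or t_mid > anchors.t_max:
            dropped += 1
            continue
        p.phase = float(interpolate_phase(anchors, t_mid))
        kept.append(p)
    return kept, dropped


def bin_pairs(pairs: Sequence, binning: PhaseBinning,
              min_pairs_per_bin: int = 1,
              ) -> tuple[dict[tuple[int, int], list], set[tuple[int, int]]]:
    """Group phased pairs by ``(z_index, bin_index)``.

    Every pair lands in exactly one bin (``floor(phase / width) mod n``).
    Groups smaller than ``min_pairs_per_bin`` are returned too but flagged
    in the low-coverage set.
    """
    groups: dict[tuple[int, int], list] = {}
    for p in pairs:
        if p.phase is None:
            raise ValueError("all pairs must carry a phase before binning")
        key = (p.z_index, int(binning.bin_index(p.phase)))
        groups.setdefault(key, []).append(p)
    low = {k for k, v in groups.items() if len(v) < min_pairs_per_bin}
    return groups, low


def split_half_flow_uncertainty(group: Sequence,
                                analysis: Callable[[Sequence], float]) -> float:
    """Split-half spread estimate of any scalar flow metric.

    The group is split into interleaved halves (even/odd acquisition order,
    so both halves span the whole acquisition), the metric is computed on
    each half, and the absolute difference is returned — an empirical error
    bar that effectively halves the seeding.
    """
    group = list(group)
    if len(group) < 2:
        raise ValueError("split-half uncertainty needs at least two pairs")
    ordered = sorted(group, key=lambda p: p.timestamp)
    return abs(float(analysis(ordered[0::2])) - float(analysis(ordered[1::2])))
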