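"""Flow-rate integration, per-beat volumes, and the OOPM error harness.

Cross-section flow rate: the measured in-plane velocity field, resolved
over z-planes, is integrated across a grid-aligned plane (one IW column at
fixed x, through all z-planes).  Each valid cell contributes its normal
velocity times the cell area (transverse IW step times z-step); invalid or
excluded cells contribute zero and are reported as missing coverage rather
than interpolated.

Per-beat volumes: integrating the phase-resolved flow-rate series over one
period splits into forward (pumped) and regurgitated (reverse) volume.

The OOPM harness recreates the out-of-plane-motion tolerance experiment:
one interrogation window covering the whole field of view, correlation
averaging over all pairs at a given ``delta_z``, and the absolute in-plane
displacement error against the known applied shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .engine import (PIVConfig, SimilarityMap, VectorField, _accumulate,
                     find_peak, subpixel_offset)
from .units import UM3_PER_MS_TO_NL_PER_S

__all__ = [
    "FlowRateSeries",
    "OOPMResult",
    "cross_section_flow",
    "pumped_volume",
    "run_oopm_experiment",
    "oopm_proxy_scan",
]


@dataclass
class FlowRateSeries:
    """Phase-resolved cross-section flow rate and per-beat volumes."""

    bin_phases: np.ndarray                  # rad, bin centres
    q: np.ndarray                           # nL/s per bin
    q_error: np.ndarray | None = None       # nL/s, split-half spread
    coverage: np.ndarray | None = None      # valid-cell fraction per bin
    period: float = float("nan")            # ms
    forward_volume: float | None = None     # nL per beat
    regurgitant_volume: float | None = None
    net_volume: float | None = None

    @property
    def n_bins(self) -> int:
        return int(np.asarray(self.q).size)


@dataclass
class OOPMResult:
    """Error of the correlation-averaged full-field vector at one delta-z."""

    delta_z: float          # um
    delta_u: float          # px, |recovered - applied shift|
    recovered_u_px: float
    n_pairs: int
    n_particles: int = 0


def cross_section_flow(field_stack: Sequence[VectorField], plane_x: float,
                       cell_area: float) -> tuple[float, float]:
    """Net flow rate (nL/s) through a grid-aligned plane at ``plane_x`` px.

    ``field_stack`` holds one vector field per z-plane, all at the same
    phase; ``cell_area`` (um^2) is the transverse IW step times the z-step.
    Returns ``(q, coverage)`` where coverage is the fraction of plane cells
    carrying a valid vector.  Invalid cells contribute zero flow.
    """
    if len(field_stack) == 0:
        raise ValueError("field stack is empty")
    total = 0.0
    n_cells = 0
    n_valid = 0
    for fld in field_stack:
        cols = np.unique(fld.grid_x)
        if plane_x < cols.min() - 0.5 or plane_x > cols.max() + 0.5:
            raise ValueError(f"plane x={plane_x} px lies outside the IW grid")
        x_sel = cols[np.argmin(np.abs(cols - plane_x))]
        on_plane = fld.grid_x == x_sel
        ok = on_plane & fld.valid & ~fld.excluded & np.isfinite(fld.u)
        total += float(fld.u[ok].sum()) * cell_area   # um/ms * um^2
        n_cells += int(on_plane.sum())
        n_valid += int(ok.sum())
    coverage = n_valid / n_cells if n_cells else 0.0
    return total * UM3_PER_MS_TO_NL_PER_S, coverage


def pumped_volume(series: FlowRateSeries) -> FlowRateSeries:
    """Fill per-beat forward, regurgitant and net volumes (nL) of a series.

    Each bin contributes ``q * period / n_bins``; forward volume sums the
    positive contributions, regurgitant volume the magnitude of the
    negative ones, and net is their difference.
    """
    q = np.asarray(series.q, dtype=float)
    if q.size == 0 or np.any(~np.isfinite(q)):
        raise ValueError("flow-rate series has missing bins")
    if not math.isfinite(series.period):
        raise ValueError("series period is unknown")
    dt_s = series.period / q.size / 1000.0      # s per bin
    vols = q * dt_s                             # nL
    series.forward_volume = float(vols[vols > 0].sum())
    series.regurgitant_volume = float(-vols[vols < 0].sum())
    series.net_volume = series.forward_volume - series.regurgitant_volume
    return series


def run_oopm_experiment(dataset: Mapping[float, Sequence], true_shift: float,
                        config: PIVConfig,
                        margin_x: int | None = None,
                        margin_y: int = 4) -> list[OOPMResult]:
    """Correlation-averaged single-IW analysis of an OOPM dataset.

    For each ``delta_z`` the similarity maps of all pairs are computed with
    one interrogation window covering the whole field of view (the small
    window is the frame cropped by ``margin_x`` / ``margin_y`` pixels on
    each side; the large window is the full second frame), averaged, and
    reduced to a single sub-pixel displacement whose absolute deviation
    from the applied shift is reported.
    """
    if margin_x is None:
        margin_x = int(abs(true_shift)) + 8
    results = []
    for dz in sorted(dataset):
        pairs = list(dataset[dz])
        rows, cols = pairs[0].frame_a.shape
        if 2 * margin_x >= cols or 2 * margin_y >= rows:
            raise ValueError("margins leave no interrogation window")
        sh, sw = rows - 2 * margin_y, cols - 2 * margin_x
        a_stack = np.empty((len(pairs), sh, sw))
        b_stack = np.empty((len(pairs), rows, cols))
        for p, pr in enumerate(pairs):
            a_stack[p] = pr.frame_a[margin_y:rows - margin_y,
                                    margin_x:cols - margin_x]
            b_stack[p] = pr.frame_b
        acc = _accumulate(a_stack, b_stack, config.metric)
        sign = 1.0 if config.metric == "xcorr" else -1.0
        smap = SimilarityMap(sign * acc / len(pairs), (-margin_x, -margin_y),
                             n_contributing_pairs=len(pairs))
        pk = find_peak(smap, config.mask_halfwidth, config.ratio_threshold)
        sub = subpixel_offset(smap, (pk.dx, pk.dy))
        u_px = pk.dx + sub.delta_x
        n_part = int(np.mean([pr.meta.get("n_visible", 0) for pr in pairs]))
        results.append(OOPMResult(float(dz), abs(u_px - true_shift),
                                  float(u_px), len(pairs), n_part))
    return results


def oopm_proxy_scan(field_stacks: Mapping, threshold: float, dt: float,
                    region: tuple[float, float] | None = None) -> dict:
    """Count cells whose transverse displacement exceeds ``threshold`` um.

    Under an assumption of cylindrical chamber symmetry, the largest
    in-plane transverse (v) displacement bounds the out-of-plane motion.
    ``field_stacks`` maps any key (z-plane, phase bin, ...) to a
    :class:`VectorField`; ``region`` optionally restricts the scan to grid-x
    within ``(x_lo, x_hi)`` px.  Returns per-key counts and their maximum.
    """
    counts = {}
    for key, fld in field_stacks.items():
        sel = fld.valid & ~fld.excluded & np.isfinite(fld.v)
        if region is not None:
            sel &= (fld.grid_x >= region[0]) & (fld.grid_x <= region[1])
        disp = np.abs(fld.v[sel]) * dt      # um
        counts[key] = int((disp > threshold).sum())
    return {"counts": counts,
            "max_count": max(counts.values()) if counts else 0}
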