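"""Core velocimetry: SAD block matching with correlation averaging.

The analysis follows the classical ensemble-PIV pattern, with the match
metric replaced by the sum of absolute differences (SAD):

1. the image is tiled with small interrogation windows (IWs), each paired
   with a larger concentric window in the second frame;
2. for every candidate displacement the SAD between the small window of
   frame A and the corresponding footprint inside the large window of
   frame B is computed, giving a similarity map per IW per frame pair;
3. maps from many frame pairs are averaged elementwise (correlation
   averaging), which rescues sparsely seeded data;
4. the averaged map's peak is located, validated against a peak-to-peak
   ratio threshold (next-best value outside a masked neighbourhood of the
   peak), refined to sub-pixel accuracy with a three-point Gaussian fit,
   and converted to physical velocity.

SAD values are stored negated so that "larger is better" holds for every
metric; the peak-to-peak ratio is computed after shifting the averaged map
to be non-negative, preserving OpenPIV-style peak1/peak2 semantics.

Displacements are frame-B-relative-to-frame-A, in pixels, with x along
columns (right positive) and y along rows (down positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "PIVConfig",
    "IWPlacement",
    "SimilarityMap",
    "PeakResult",
    "SubpixelResult",
    "VectorField",
    "make_iw_grid",
    "similarity_map",
    "average_maps",
    "find_peak",
    "subpixel_offset",
    "analyze_plane",
    "analyze_groups",
    "validate_field",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PIVConfig:
    """All analysis parameters.

    Window sizes are ``(width, height)`` in pixels; the large window must
    contain the small one so that the similarity map covers displacements
    ``+-(large - small) / 2`` around zero.
    """

    small_iw: tuple[int, int] = (32, 12)
    large_iw: tuple[int, int] = (128, 16)
    overlap_fraction: float = 0.5
    ratio_threshold: float = 1.10
    mask_halfwidth: int = 3
    dt: float = 0.3                 # ms
    pixel_size: float = 0.3225      # um/px
    binning: int = 1
    metric: str = "sad"             # "sad" | "xcorr"
    min_iw_intensity: float | None = None   # summed counts over the small IW
    min_pairs_per_bin: int = 1

    def __post_init__(self) -> None:
        if not (self.large_iw[0] >= self.small_iw[0]
                and self.large_iw[1] >= self.small_iw[1]):
            raise ValueError("large_iw must contain small_iw componentwise")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.ratio_threshold < 1.0:
            raise ValueError("ratio_threshold must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.metric not in ("sad", "xcorr"):
            raise ValueError("metric must be 'sad' or 'xcorr'")

    @property
    def px_to_velocity(self) -> float:
        """Factor converting a pixel displacement to um/ms."""
        return self.pixel_size * self.binning / self.dt


@dataclass(frozen=True)
class IWPlacement:
    """One interrogation-window placement (pixel indices, top-left corners)."""

    sx0: int
    sy0: int
    lx0: int
    ly0: int
    small: tuple[int, int]   # (w, h)
    large: tuple[int, int]

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) centre of the small window in pixel coordinates."""
        return (self.sx0 + (self.small[0] - 1) / 2.0,
                self.sy0 + (self.small[1] - 1) / 2.0)


@dataclass
class SimilarityMap:
    """Match scores over candidate displacements; larger is better."""

    values: np.ndarray                   # (n_dy, n_dx)
    displacement_origin: tuple[int, int]  # (dx, dy) of element [0, 0]
    n_contributing_pairs: int = 1
    iw_center: tuple[float, float] | None = None

    @property
    def dx_axis(self) -> np.ndarray:
        return self.displacement_origin[0] + np.arange(self.values.shape[1])

    @property
    def dy_axis(self) -> np.ndarray:
        return self.displacement_origin[1] + np.arange(self.values.shape[0])


@dataclass
class PeakResult:
    dx: int
    dy: int
    ratio: float
    valid: bool


@dataclass
class SubpixelResult:
    delta_x: float
    delta_y: float
    edge: bool = False
    gaussian_failed: bool = False


# ---------------------------------------------------------------------------
# similarity kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sad_accumulate(a_stack, b_stack, out):  # pragma: no cover - compiled
    n, h, w = a_stack.shape
    H, W = b_stack.shape[1], b_stack.shape[2]
    ndy, ndx = H - h + 1, W - w + 1
    for p in range(n):
        for i in range(ndy):
            for j in range(ndx):
                s = 0.0
                for r in range(h):
                    for c in range(w):
                        s += abs(a_stack[p, r, c] - b_stack[p, i + r, j + c])
                out[i, j] += s


@njit(cache=True)
def _xcorr_accumulate(a_stack, b_stack, out):  # pragma: no cover - compiled
    n, h, w = a_stack.shape
    H, W = b_stack.shape[1], b_stack.shape[2]
    ndy, ndx = H - h + 1, W - w + 1
    for p in range(n):
        for i in range(ndy):
            for j in range(ndx):
                s = 0.0
                for r in range(h):
                    for c in range(w):
                        s += a_stack[p, r, c] * b_stack[p, i + r, j + c]
                out[i, j] += s


def _sad_accumulate_py(a_stack, b_stack, out):
    from numpy.lib.stride_tricks import sliding_window_view

    n, h, w = a_stack.shape
    for p in range(n):
        win = sliding_window_view(b_stack[p], (h, w))
        out += np.abs(win - a_stack[p]).sum(axis=(2, 3))


def _xcorr_accumulate_py(a_stack, b_stack, out):
    from numpy.lib.stride_tricks import sliding_window_view

    n, h, w = a_stack.shape
    for p in range(n):
        win = sliding_window_view(b_stack[p], (h, w))
        out += (win * a_stack[p]).sum(axis=(2, 3))


def _accumulate(a_stack: np.ndarray, b_stack: np.ndarray, metric: str) -> np.ndarray:
    """Sum of raw metric maps over the pair axis (SAD positive, un-negated)."""
    n, h, w = a_stack.shape
    H, W = b_stack.shape[1], b_stack.shape[2]
    out = np.zeros((H - h + 1, W - w + 1))
    if _HAVE_NUMBA:
        kern = _sad_accumulate if metric == "sad" else _xcorr_accumulate
    else:
        kern = _sad_accumulate_py if metric == "sad" else _xcorr_accumulate_py
    kern(np.ascontiguousarray(a_stack, dtype=np.float64),
         np.ascontiguousarray(b_stack, dtype=np.float64), out)
    return out


def _origin_for(small: tuple[int, int], large: tuple[int, int]) -> tuple[int, int]:
    return (-((large[0] - small[0]) // 2), -((large[1] - small[1]) // 2))


def similarity_map(iw_a: np.ndarray, iw_b: np.ndarray,
                   metric: str = "sad") -> SimilarityMap:
    """Match-score map of a small patch against a larger concentric patch.

    For ``sad`` the raw score at each displacement is the sum of absolute
    differences over the small-window footprint, stored negated so that the
    best match is the maximum.  For ``xcorr`` the raw intensity product is
    stored directly (no background subtraction).
    """
    a = np.asarray(iw_a, dtype=np.float64)
    b = np.asarray(iw_b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("patches must be 2D")
    if b.shape[0] < a.shape[0] or b.shape[1] < a.shape[1]:
        raise ValueError("large patch must contain the small patch")
    acc = _accumulate(a[None], b[None], metric)
    values = -acc if metric == "sad" else acc
    small = (a.shape[1], a.shape[0])
    large = (b.shape[1], b.shape[0])
    return SimilarityMap(values, _origin_for(small, large))


def average_maps(maps: Sequence[SimilarityMap]) -> SimilarityMap:
    """Elementwise arithmetic mean of similarity maps (correlation averaging)."""
    if len(maps) == 0:
        raise ValueError("cannot average an empty sequence of maps")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("similarity maps have mismatched shapes")
        if m.displacement_origin != first.displacement_origin:
            raise ValueError("similarity maps have mismatched origins")
    stack = np.stack([m.values for m in maps])
    return SimilarityMap(stack.mean(axis=0), first.displacement_origin,
                         n_contributing_pairs=sum(m.n_contributing_pairs
                                                  for m in maps),
                         iw_center=first.iw_center)


# ---------------------------------------------------------------------------
# peak detection and sub-pixel refinement
# ---------------------------------------------------------------------------

def find_peak(smap: SimilarityMap, mask_halfwidth: int = 3,
              ratio_threshold: float = 1.10) -> PeakResult:
    """Locate the best-match displacement and its peak-to-peak ratio.

    The ratio is the peak value over the next-highest value outside a
    ``(2h+1) x (2h+1)`` masked neighbourhood of the peak, evaluated on the
    map shifted to be non-negative.  Ties at the maximum break towards the
    lexicographically smallest ``(dy, dx)`` displacement.
    """
    vals = smap.values
    if vals.size == 0:
        raise ValueError("similarity map is empty")
    vmax = vals.max()
    ties = np.argwhere(vals == vmax)
    dy0, dx0 = smap.displacement_origin[1], smap.displacement_origin[0]
    order = np.lexsort((ties[:, 1] + dx0, ties[:, 0] + dy0))
    pi, pj = ties[order[0]]
    # positivize: negated-SAD maps are <= 0 and must be shifted before a
    # peak1/peak2 ratio makes sense; already-positive maps are left alone
    shifted = vals - min(float(vals.min()), 0.0)
    peak_val = shifted[pi, pj]
    h = int(mask_halfwidth)
    masked = shifted.copy()
    masked[max(pi - h, 0):pi + h + 1, max(pj - h, 0):pj + h + 1] = -np.inf
    if not np.any(np.isfinite(masked)):
        return PeakResult(int(pj + dx0), int(pi + dy0), float("nan"), False)
    second = masked.max()
    if second <= 0.0:
        ratio = math.inf if peak_val > 0 else float("nan")
    else:
        ratio = float(peak_val / second)
    valid = bool(ratio >= ratio_threshold) if not math.isnan(ratio) else False
    return PeakResult(int(pj + dx0), int(pi + dy0), ratio, valid)


def _axis_offset(vm1: float, v0: float, vp1: float) -> tuple[float, bool]:
    """Three-point Gaussian peak interpolation with parabolic fallback."""
    if vm1 > 0 and v0 > 0 and vp1 > 0:
        lm, l0, lp = math.log(vm1), math.log(v0), math.log(vp1)
        denom = 2.0 * lm - 4.0 * l0 + 2.0 * lp
        if denom != 0.0:
            return (lm - lp) / denom, False
    denom = 2.0 * (vm1 - 2.0 * v0 + vp1)
    if denom == 0.0:
        return 0.0, True
    return (vm1 - vp1) / denom, True


def subpixel_offset(smap: SimilarityMap, peak: tuple[int, int]) -> SubpixelResult:
    """Fractional refinement of an integer peak displacement.

    Fits a three-point Gaussian through the peak and its two neighbours,
    independently per axis, on values shifted to be non-negative.  If a
    neighbour is non-positive the fit falls back to a three-point parabola;
    a peak on the map border returns the integer result with an edge flag.
    """
    vals = smap.values - min(float(smap.values.min()), 0.0)
    dx0, dy0 = smap.displacement_origin
    pj = peak[0] - dx0
    pi = peak[1] - dy0
    n_dy, n_dx = vals.shape
    edge_x = not (0 < pj < n_dx - 1)
    edge_y = not (0 < pi < n_dy - 1)
    delta_x = delta_y = 0.0
    failed = False
    if not edge_x:
        delta_x, f = _axis_offset(vals[pi, pj - 1], vals[pi, pj], vals[pi, pj + 1])
        failed |= f
    if not edge_y:
        delta_y, f = _axis_offset(vals[pi - 1, pj], vals[pi, pj], vals[pi + 1, pj])
        failed |= f
    return SubpixelResult(delta_x, delta_y, edge=edge_x or edge_y,
                          gaussian_failed=failed)


# ---------------------------------------------------------------------------
# gridding and plane analysis
# ---------------------------------------------------------------------------

def make_iw_grid(image_shape: tuple[int, int], config: PIVConfig,
                 ) -> list[IWPlacement]:
    """Tile the image with small IWs and concentric large IWs.

    The step between small windows is ``small_iw * (1 - overlap_fraction)``;
    placements whose large window would extend past the image are dropped.
    """
    rows, cols = image_shape
    sw, sh = config.small_iw
    lw, lh = config.large_iw
    if cols < lw or rows < lh:
        raise ValueError("image is smaller than one large interrogation window")
    step_x = max(int(round(sw * (1.0 - config.overlap_fraction))), 1)
    step_y = max(int(round(sh * (1.0 - config.overlap_fraction))), 1)
    mx = (lw - sw) // 2
    my = (lh - sh) // 2
    placements = []
    for sy0 in range(0, rows - sh + 1, step_y):
        ly0 = sy0 - my
        if ly0 < 0 or ly0 + lh > rows:
            continue
        for sx0 in range(0, cols - sw + 1, step_x):
            lx0 = sx0 - mx
            if lx0 < 0 or lx0 + lw > cols:
                continue
            placements.append(IWPlacement(sx0, sy0, lx0, ly0,
                                          (sw, sh), (lw, lh)))
    return placements


@dataclass
class VectorField:
    """Per-IW velocity vectors for one z-plane (and phase bin, if binned)."""

    grid_x: np.ndarray          # IW centre x, px
    grid_y: np.ndarray          # IW centre y, px
    u_px: np.ndarray            # displacement, px (x, rightwards)
    v_px: np.ndarray            # displacement, px (y, downwards)
    u: np.ndarray               # um/ms
    v: np.ndarray               # um/ms
    ratio: np.ndarray           # peak-to-peak ratio
    valid: np.ndarray           # bool
    excluded: np.ndarray        # bool, skipped for low intensity
    n_pairs: int = 0
    z_index: int = 0
    z_um: float = 0.0
    phase_bin: int | None = None
    maps: list[SimilarityMap] | None = None

    @property
    def n(self) -> int:
        return self.grid_x.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "x": self.grid_x, "y": self.grid_y,
            "z_index": self.z_index, "z_um": self.z_um,
            "phase_bin": -1 if self.phase_bin is None else self.phase_bin,
            "u": self.u, "v": self.v,
            "u_px": self.u_px, "v_px": self.v_px,
            "ratio": self.ratio, "valid": self.valid,
            "excluded": self.excluded,
        })


def analyze_plane(pairs: Sequence, config: PIVConfig,
                  phase_bin: int | None = None,
                  return_maps: bool = False) -> VectorField:
    """Correlation-averaged analysis of the frame pairs of one z-plane.

    For each IW placement the per-pair similarity maps are averaged before
    peak detection, validation and sub-pixel refinement.  IWs whose summed
    small-window intensity stays below ``min_iw_intensity`` in every pair
    are marked excluded and skipped.
    """
    pairs = list(pairs)
    if len(pairs) == 0:
        raise ValueError("analyze_plane needs at least one frame pair")
    shape = pairs[0].frame_a.shape
    placements = make_iw_grid(shape, config)
    n_iw = len(placements)
    frames_a = [np.ascontiguousarray(p.frame_a, dtype=np.float64) for p in pairs]
    frames_b = [np.ascontiguousarray(p.frame_b, dtype=np.float64) for p in pairs]
    n = len(pairs)
    sw, sh = config.small_iw
    lw, lh = config.large_iw
    origin = _origin_for(config.small_iw, config.large_iw)

    gx = np.empty(n_iw)
    gy = np.empty(n_iw)
    u_px = np.full(n_iw, np.nan)
    v_px = np.full(n_iw, np.nan)
    ratio = np.full(n_iw, np.nan)
    valid = np.zeros(n_iw, dtype=bool)
    excluded = np.zeros(n_iw, dtype=bool)
    maps: list[SimilarityMap] | None = [] if return_maps else None

    a_stack = np.empty((n, sh, sw))
    b_stack = np.empty((n, lh, lw))
    for k, pl in enumerate(placements):
        gx[k], gy[k] = pl.center
        for p in range(n):
            a_stack[p] = frames_a[p][pl.sy0:pl.sy0 + sh, pl.sx0:pl.sx0 + sw]
            b_stack[p] = frames_b[p][pl.ly0:pl.ly0 + lh, pl.lx0:pl.lx0 + lw]
        if config.min_iw_intensity is not None:
            if a_stack.sum(axis=(1, 2)).max() < config.min_iw_intensity:
                excluded[k] = True
                if maps is not None:
                    maps.append(None)
                continue
        acc = _accumulate(a_stack, b_stack, config.metric)
        avg = acc / n if config.metric == "xcorr" else -(acc / n)
        smap = SimilarityMap(avg, origin, n_contributing_pairs=n,
                             iw_center=pl.center)
        pk = find_peak(smap, config.mask_halfwidth, config.ratio_threshold)
        sub = subpixel_offset(smap, (pk.dx, pk.dy))
        u_px[k] = pk.dx + sub.delta_x
        v_px[k] = pk.dy + sub.delta_y
        ratio[k] = pk.ratio
        valid[k] = pk.valid
        if maps is not None:
            maps.append(smap)

    scale = config.px_to_velocity
    return VectorField(gx, gy, u_px, v_px, u_px * scale, v_px * scale,
                       ratio, valid, excluded, n_pairs=n,
                       z_index=getattr(pairs[0], "z_index", 0),
                       z_um=getattr(pairs[0], "z_um", 0.0),
                       phase_bin=phase_bin, maps=maps)


def analyze_groups(groups: dict, config: PIVConfig) -> dict:
    """Run :func:`analyze_plane` on every ``(z_index, bin_index)`` group."""
    out = {}
    for (z_idx, bin_idx), members in sorted(groups.items()):
        if len(members) < config.min_pairs_per_bin:
            continue
        out[(z_idx, bin_idx)] = analyze_plane(members, config,
                                              phase_bin=bin_idx)
    return out


def validate_field(field: VectorField,
                   forward_axis_sign: int | None = None,
                   center: tuple[float, float] | None = None,
                   radius: float | None = None,
                   pixel_pitch: float | None = None) -> VectorField:
    """Apply physical outlier rules, flagging offenders invalid.

    ``forward_axis_sign`` (+1 or -1) enforces the known flow direction along
    x: vectors with the opposite horizontal component are flagged invalid.
    ``center`` = (y_c px, z_c um) with ``radius`` (um) flags vectors lying
    outside the nominal tube radius in tube coordinates; ``pixel_pitch``
    (um per px, i.e. ``pixel_size * binning``) converts the grid-y offset.
    Vector values are retained for audit; with no rules the field is
    returned unchanged.
    """
    new_valid = field.valid.copy()
    if forward_axis_sign is not None:
        sign = 1 if forward_axis_sign >= 0 else -1
        new_valid &= (sign * np.nan_to_num(field.u_px, nan=-1.0)) >= 0
    if radius is not None:
        if center is None or pixel_pitch is None:
            raise ValueError(
                "radius rule requires center=(y_c_px, z_c_um) and pixel_pitch")
        y_c_px, z_c_um = center
        r = np.hypot((field.grid_y - y_c_px) * pixel_pitch,
                     field.z_um - z_c_um)
        new_valid &= r <= radius
    return replace(field, valid=new_valid)
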