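"""Synthetic tracer imagery with known ground truth.

This module generates the four study scenes used to exercise every stage of
the velocimetry pipeline without microscope data:

* a steady Poiseuille tube phantom (beads in a ~50 um tube), imaged either
  through a thin Gaussian light sheet or under full-volume illumination with
  defocus blur;
* the out-of-plane-motion (OOPM) tolerance experiment: a fixed 3D bead sample
  viewed from two focal planes separated by ``delta_z``, with a known integer
  in-plane shift applied to the second frame;
* a pulsatile "heart" phantom: Poiseuille tube flow modulated by a periodic
  waveform with a regurgitation (negative-flow) lobe, with timestamps and a
  phase-anchor series emulating a brightfield synchronisation channel;
* an intensity-gradient scene that exposes the brightness bias of
  product-based cross-correlation.

Coordinates: ``x`` is the image column axis (increasing right), ``y`` the row
axis (increasing down), ``z`` the optical axis. Positions are in micrometres;
a tracer at ``x = k * pixel_size`` is centred on pixel column ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .units import TWO_PI, UM3_PER_MS_TO_NL_PER_S, v_max_from_flow_rate

__all__ = [
    "SceneConfig",
    "TracerEnsemble",
    "GroundTruth",
    "FramePair",
    "sample_tracers",
    "poiseuille_velocity",
    "render_frame",
    "make_tube_dataset",
    "make_oopm_dataset",
    "make_heart_phantom",
    "make_gradient_scene",
    "default_heart_waveform",
]

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma.
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Sheet-weight below which a tracer is treated as invisible when counting.
VISIBILITY_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Parameters of the simulated optical scene.

    ``v_max`` (um/ms) and ``flow_rate`` (uL/min) are mutually exclusive ways
    of setting the tube centreline velocity; if ``flow_rate`` is given,
    ``v_max`` is derived from it and ``tube_radius``.

    ``seeding_density`` is expressed as tracers per reference interrogation
    window (``ref_iw``, in pixels) within one illuminated slab of depth
    ``6 * sheet_fwhm`` — the slab actually populated for sheet-mode scenes.
    """

    tube_radius: float = 25.0          # um
    v_max: float | None = None         # um/ms
    flow_rate: float | None = None     # uL/min
    tracer_diameter: float = 1.04      # um
    seeding_density: float = 0.2       # tracers per ref_iw area per slab
    sheet_fwhm: float = 2.0            # um
    illumination_mode: str = "sheet"   # "sheet" | "volume"
    psf_sigma0: float = 0.6            # um, in-focus PSF sigma
    defocus_rate: float = 0.5          # blur growth per um of defocus
    defocus_dimming: float = 0.5       # amplitude ~ 1/(1+rate*|dz|)^dimming
    pixel_size: float = 0.3225         # um/px
    image_shape: tuple[int, int] = (128, 320)  # (rows, cols)
    dt: float = 0.3                    # ms between the two frames of a pair
    noise_sd: float = 0.0              # additive Gaussian read noise, counts
    amplitude: float = 1000.0          # in-focus peak counts of a unit tracer
    brightness_sigma: float = 0.0      # lognormal sd of per-tracer brightness
    ref_iw: tuple[int, int] = (32, 12)  # (width, height) px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if self.seeding_density < 0:
            raise ValueError("seeding_density must be non-negative")
        if self.sheet_fwhm <= 0:
            raise ValueError("sheet_fwhm must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.illumination_mode not in ("sheet", "volume"):
            raise ValueError("illumination_mode must be 'sheet' or 'volume'")
        if self.v_max is not None and self.flow_rate is not None:
            raise ValueError("v_max and flow_rate are mutually exclusive")
        if self.v_max is None:
            q = 0.5 if self.flow_rate is None else self.flow_rate
            self.v_max = v_max_from_flow_rate(q, self.tube_radius)

    @property
    def slab_halfdepth(self) -> float:
        """Half-depth of the populated slab in sheet mode (3 x FWHM)."""
        return 3.0 * self.sheet_fwhm

    @property
    def reference_depth(self) -> float:
        """Slab depth over which ``seeding_density`` is defined."""
        return 6.0 * self.sheet_fwhm

    @property
    def spot_sigma(self) -> float:
        """In-focus image sigma of one tracer, um (PSF (+) finite tracer)."""
        return math.hypot(self.psf_sigma0, self.tracer_diameter * _FWHM_TO_SIGMA)

    @property
    def axial_fwhm(self) -> float:
        """Effective axial visibility FWHM of one tracer, um.

        A tracer of finite diameter integrates the sheet profile over its
        own extent, so its brightness-vs-depth profile is wider than the
        sheet itself: approximated as the sheet FWHM combined in quadrature
        with the FWHM of a sphere's chord-area profile (``d / sqrt(2)``).
        Negligible for ~1 um beads; decisive for RBC-sized tracers.
        """
        return math.hypot(self.sheet_fwhm, self.tracer_diameter / math.sqrt(2.0))

    @property
    def iw_area_um2(self) -> float:
        w, h = self.ref_iw
        return w * h * self.pixel_size ** 2


@dataclass
class TracerEnsemble:
    """A set of point tracers with positions (um) and relative brightness."""

    positions: np.ndarray            # (n, 3) um
    intensities: np.ndarray          # (n,)
    diameter: float                  # um

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def advected(self, displacement: np.ndarray) -> "TracerEnsemble":
        """A copy with positions moved by ``displacement`` ((n,3) or (3,))."""
        return TracerEnsemble(self.positions + displacement,
                              self.intensities.copy(), self.diameter)


@dataclass
class GroundTruth:
    """Analytic truth attached to a generated dataset."""

    velocity_function: Callable[[np.ndarray, float], np.ndarray]
    q_of_phase: Callable[[np.ndarray], np.ndarray] | None = None
    net_volume: float | None = None          # nL per beat
    forward_volume: float | None = None      # nL per beat
    regurgitant_volume: float | None = None  # nL per beat
    params: dict = field(default_factory=dict)


@dataclass
class FramePair:
    """One paired exposure: images A and B separated by ``dt`` ms."""

    frame_a: np.ndarray
    frame_b: np.ndarray
    dt: float                      # ms
    z_index: int = 0
    z_um: float = 0.0
    timestamp: float = 0.0         # ms, start of exposure A
    phase: float | None = None     # radians in [0, 2pi)
    pair_id: int = 0
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _poisson_uniform(rng: Generator, mean: float,
                     bounds: Sequence[tuple[float, float]]) -> np.ndarray:
    n = int(rng.poisson(mean)) if mean > 0 else 0
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) * rng.random((n, 3))


def sample_tracers(config: SceneConfig,
                   region: Sequence[tuple[float, float]],
                   seed: int | Generator) -> TracerEnsemble:
    """Draw a Poisson ensemble of tracers uniformly inside a box region.

    ``region`` is ``((x0, x1), (y0, y1), (z0, z1))`` in um.  The expected
    count is ``seeding_density * (xy area / reference IW area) * depth
    factor`` with the depth factor being the region depth over the reference
    slab depth ``6 * sheet_fwhm``.
    """
    (x0, x1), (y0, y1), (z0, z1) = region
    if x1 <= x0 or y1 <= y0 or z1 <= z0:
        raise ValueError("region must have positive extent along every axis")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    area = (x1 - x0) * (y1 - y0)
    depth_factor = (z1 - z0) / config.reference_depth
    mean = config.seeding_density * area / config.iw_area_um2 * depth_factor
    pos = _poisson_uniform(rng, mean, region)
    intens = _draw_intensities(config, rng, pos.shape[0])
    return TracerEnsemble(pos, intens, config.tracer_diameter)


def _draw_intensities(config: SceneConfig, rng: Generator, n: int) -> np.ndarray:
    if config.brightness_sigma > 0:
        return rng.lognormal(mean=0.0, sigma=config.brightness_sigma, size=n)
    return np.ones(n)


def poiseuille_velocity(position: np.ndarray, v_max: float, radius: float,
                        center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Velocity of steady Poiseuille tube flow along +x, um/ms.

    ``u = v_max * (1 - r^2 / R^2)`` inside the tube and zero outside, with
    ``r`` the distance of ``(y, z)`` from the tube axis at ``center``.
    Accepts a single position ``(x, y, z)`` or an ``(n, 3)`` array.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    p = np.atleast_2d(np.asarray(position, dtype=float))
    r2 = (p[:, 1] - center[0]) ** 2 + (p[:, 2] - center[1]) ** 2
    u = v_max * np.clip(1.0 - r2 / radius ** 2, 0.0, None)
    out = np.zeros_like(p)
    out[:, 0] = u
    return out[0] if np.asarray(position).ndim == 1 else out


def sheet_weight(z: np.ndarray, focal_z: float, fwhm: float) -> np.ndarray:
    """Gaussian light-sheet illumination weight; 1 in plane, 1/2 at +-FWHM/2."""
    return np.exp(-4.0 * math.log(2.0) * (np.asarray(z) - focal_z) ** 2 / fwhm ** 2)


def render_frame(ensemble: TracerEnsemble, config: SceneConfig,
                 focal_z: float, rng: Generator | None = None,
                 add_noise: bool = True) -> np.ndarray:
    """Rasterise an ensemble into one camera frame.

    Each tracer is a 2D Gaussian spot sampled at pixel centres. In ``sheet``
    mode the spot amplitude is weighted by the light-sheet profile and the
    width is the in-focus width; in ``volume`` mode every tracer is lit, the
    width grows linearly with defocus distance and the amplitude decays as
    ``(1 + defocus_rate * |dz|) ** -defocus_dimming``.
    """
    rows, cols = config.image_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("image_shape must be positive")
    img = np.zeros((rows, cols))
    sig0 = config.spot_sigma
    for i in range(ensemble.n):
        x, y, z = ensemble.positions[i]
        base = config.amplitude * ensemble.intensities[i]
        col, row = x / config.pixel_size, y / config.pixel_size
        if (config.illumination_mode == "sheet"
                and ensemble.diameter > 4.0 * config.psf_sigma0):
            # a large fluorescent sphere behind a thin sheet images as the
            # sheet-weighted chord integral through the sphere: a sharp-
            # edged disk in the sheet, a dimmer shrinking cap out of it
            if base * tracer_axial_weight(z - focal_z, config) \
                    < config.amplitude * 1e-4:
                continue
            _add_sphere_spot(img, col, row, base,
                             ensemble.diameter / 2.0 / config.pixel_size,
                             z - focal_z, config)
            continue
        if config.illumination_mode == "sheet":
            amp = base * float(sheet_weight(z, focal_z, config.axial_fwhm))
            sigma_um = sig0
        else:
            growth = 1.0 + config.defocus_rate * abs(z - focal_z)
            sigma_um = sig0 * growth
            amp = base / growth ** config.defocus_dimming
        if amp < config.amplitude * 1e-4:
            continue
        _add_spot(img, col, row, amp, sigma_um / config.pixel_size)
    if add_noise and config.noise_sd > 0:
        if rng is None:
            rng = default_rng(config.seed)
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)
    return img


def _add_spot(img: np.ndarray, col: float, row: float,
              amp: float, sigma_px: float) -> None:
    rows, cols = img.shape
    half = int(math.ceil(4.0 * sigma_px)) + 1
    c0 = max(int(math.floor(col)) - half, 0)
    c1 = min(int(math.floor(col)) + half + 1, cols)
    r0 = max(int(math.floor(row)) - half, 0)
    r1 = min(int(math.floor(row)) + half + 1, rows)
    if c0 >= c1 or r0 >= r1:
        return
    gx = np.exp(-0.5 * ((np.arange(c0, c1) - col) / sigma_px) ** 2)
    gy = np.exp(-0.5 * ((np.arange(r0, r1) - row) / sigma_px) ** 2)
    img[r0:r1, c0:c1] += amp * gy[:, None] * gx[None, :]


def _sphere_sheet_profile(rho_px: np.ndarray, r_px: float, dz_px: float,
                          sheet_sigma_px: float) -> np.ndarray:
    """Chord integral of a Gaussian sheet through a uniform sphere.

    Brightness at projected radius ``rho`` of a sphere of radius ``r``
    whose centre sits ``dz`` from the sheet centre:
    ``int_{-L}^{L} exp(-(z - dz)^2 / 2 s^2) dz`` with ``L = sqrt(r^2 -
    rho^2)``, normalised so an in-sheet sphere peaks at 1.  Closed form
    via erf; reproduces the sharp in-sheet disk, the dimming and the
    shrinking of the lit cap as the sphere leaves the sheet.
    """
    from scipy.special import erf

    L = np.sqrt(np.clip(r_px ** 2 - rho_px ** 2, 0.0, None))
    s = math.sqrt(2.0) * sheet_sigma_px
    raw = erf((L - dz_px) / s) + erf((L + dz_px) / s)
    return raw / (2.0 * erf(r_px / s))


def tracer_axial_weight(dz_um: float, config: SceneConfig) -> float:
    """Peak-brightness weight of a finite sphere at ``dz`` from the sheet."""
    r_um = config.tracer_diameter / 2.0
    if config.tracer_diameter <= 4.0 * config.psf_sigma0:
        return float(sheet_weight(dz_um, 0.0, config.axial_fwhm))
    return float(_sphere_sheet_profile(np.zeros(1), r_um, dz_um,
                                       config.sheet_fwhm * _FWHM_TO_SIGMA)[0])


def _add_sphere_spot(img: np.ndarray, col: float, row: float, amp: float,
                     r_px: float, dz_um: float, config: SceneConfig) -> None:
    """Sheet-illuminated sphere tracer image with a PSF-softened edge."""
    rows, cols = img.shape
    soft_px = config.psf_sigma0 / config.pixel_size
    half = int(math.ceil(r_px + 4.0 * soft_px)) + 1
    c0 = max(int(math.floor(col)) - half, 0)
    c1 = min(int(math.floor(col)) + half + 1, cols)
    r0 = max(int(math.floor(row)) - half, 0)
    r1 = min(int(math.floor(row)) + half + 1, rows)
    if c0 >= c1 or r0 >= r1:
        return
    dx = np.arange(c0, c1) - col
    dy = np.arange(r0, r1) - row
    rho = np.sqrt(dy[:, None] ** 2 + dx[None, :] ** 2)
    sheet_sigma_px = config.sheet_fwhm * _FWHM_TO_SIGMA / config.pixel_size
    patch = _sphere_sheet_profile(rho, r_px, dz_um / config.pixel_size,
                                  sheet_sigma_px)
    if soft_px > 0.05:
        from scipy.ndimage import gaussian_filter
        patch = gaussian_filter(patch, soft_px, mode="constant")
    img[r0:r1, c0:c1] += amp * patch


# ---------------------------------------------------------------------------
# dataset generators
# ---------------------------------------------------------------------------

def _tube_geometry(config: SceneConfig) -> tuple[float, float, float]:
    """(y-centre um, x-min um, x-max um) of the tube within the image."""
    rows, cols = config.image_shape
    y_c = (rows / 2.0) * config.pixel_size
    pad = 10.0 + abs(config.v_max) * config.dt
    return y_c, -pad, cols * config.pixel_size + pad


def _sample_tube_slab(config: SceneConfig, z_lo: float, z_hi: float,
                      rng: Generator) -> TracerEnsemble:
    """Tracers uniform inside the tube volume intersected with a z-slab."""
    y_c, x0, x1 = _tube_geometry(config)
    R = config.tube_radius
    region = ((x0, x1), (y_c - R, y_c + R), (z_lo, z_hi))
    ens = sample_tracers(config, region, rng)
    r2 = (ens.positions[:, 1] - y_c) ** 2 + ens.positions[:, 2] ** 2
    keep = r2 <= R ** 2
    return TracerEnsemble(ens.positions[keep], ens.intensities[keep],
                          ens.diameter)


def make_tube_dataset(config: SceneConfig, n_pairs_per_z: int,
                      z_planes: Sequence[float], seed: int,
                      ) -> tuple[list[FramePair], GroundTruth]:
    """Steady Poiseuille tube phantom: frame pairs at each focal plane.

    The tube axis runs along +x at the image mid-height, at ``z = 0``.  For
    each z-plane, ``n_pairs_per_z`` independent ensembles are advected by
    ``dt`` under the Poiseuille profile and rendered twice.  In sheet mode
    tracers are populated within +-3 FWHM of the sheet; in volume mode the
    full tube depth is populated.
    """
    if n_pairs_per_z < 1:
        raise ValueError("n_pairs_per_z must be >= 1")
    y_c, _, _ = _tube_geometry(config)
    R, v_max = config.tube_radius, config.v_max
    ss = SeedSequence(seed)
    pairs: list[FramePair] = []
    pid = 0
    for iz, z0 in enumerate(z_planes):
        for child in ss.spawn(len(z_planes))[iz].spawn(n_pairs_per_z):
            rng = default_rng(child)
            if config.illumination_mode == "sheet":
                z_lo, z_hi = z0 - config.slab_halfdepth, z0 + config.slab_halfdepth
            else:
                z_lo, z_hi = -R, R
            ens = _sample_tube_slab(config, z_lo, z_hi, rng)
            vel = poiseuille_velocity(ens.positions, v_max, R, center=(y_c, 0.0))
            ens_b = ens.advected(vel * config.dt)
            a = render_frame(ens, config, z0, rng)
            b = render_frame(ens_b, config, z0, rng)
            pairs.append(FramePair(a, b, config.dt, z_index=iz, z_um=z0,
                                   timestamp=pid * 10.0 * config.dt,
                                   pair_id=pid,
                                   meta={"n_tracers": ens.n}))
            pid += 1

    def velocity_function(pos: np.ndarray, phase: float = 0.0) -> np.ndarray:
        return poiseuille_velocity(pos, v_max, R, center=(y_c, 0.0))

    q = math.pi * R * R * v_max / 2.0 * UM3_PER_MS_TO_NL_PER_S  # nL/s
    truth = GroundTruth(velocity_function,
                        q_of_phase=lambda phi: np.full_like(np.asarray(phi, float), q),
                        params={"v_max": v_max, "radius": R,
                                "y_center_um": y_c, "z_center_um": 0.0,
                                "q_nl_s": q})
    return pairs, truth


def make_oopm_dataset(delta_z_values: Sequence[float], in_plane_shift: int,
                      n_pairs: int, config: SceneConfig, seed: int,
                      n_visible: int = 200) -> dict[float, list[FramePair]]:
    """Out-of-plane-motion experiment: refocused view of a fixed bead field.

    For each ``delta_z``, ``n_pairs`` independent 3D ensembles are rendered
    twice: frame A at a reference focal plane, frame B at a focal plane
    displaced by ``delta_z`` and then translated laterally by
    ``in_plane_shift`` whole pixels (``numpy.roll``, no resampling error).
    The ensemble is sized so that about ``n_visible`` tracer images are
    visible per field of view.
    """
    rows, cols = config.image_shape
    if abs(int(in_plane_shift)) >= cols:
        raise ValueError("in_plane_shift exceeds the image width")
    shift = int(in_plane_shift)
    # z-band over which a tracer is visible (axial weight >= threshold),
    # solved numerically on the finite-sphere visibility profile
    dz_grid = np.linspace(0.0, config.tracer_diameter + 4.0 * config.sheet_fwhm,
                          2048)
    w_grid = np.array([tracer_axial_weight(d, config) for d in dz_grid])
    band = 2.0 * float(dz_grid[w_grid >= VISIBILITY_THRESHOLD].max())
    focal_a = 1.5 * band
    depth = 3.0 * band + max(delta_z_values)
    n_total_mean = n_visible * depth / band
    pad = 8.0 * config.spot_sigma
    bounds = ((-pad, cols * config.pixel_size + pad),
              (-pad, rows * config.pixel_size + pad),
              (0.0, depth))
    ss = SeedSequence(seed)
    out: dict[float, list[FramePair]] = {}
    pid = 0
    for idz, dz in enumerate(delta_z_values):
        child = ss.spawn(len(delta_z_values))[idz]
        plist: list[FramePair] = []
        for pair_seed in child.spawn(n_pairs):
            rng = default_rng(pair_seed)
            pos = _poisson_uniform(rng, n_total_mean, bounds)
            ens = TracerEnsemble(pos, _draw_intensities(config, rng, pos.shape[0]),
                                 config.tracer_diameter)
            a = render_frame(ens, config, focal_a, add_noise=False)
            b = np.roll(render_frame(ens, config, focal_a + dz, add_noise=False),
                        shift, axis=1)
            if config.noise_sd > 0:
                a = np.clip(a + rng.normal(0, config.noise_sd, a.shape), 0, None)
                b = np.clip(b + rng.normal(0, config.noise_sd, b.shape), 0, None)
            w_a = np.array([tracer_axial_weight(zz - focal_a, config)
                            for zz in ens.positions[:, 2]])
            w_b = np.array([tracer_axial_weight(zz - focal_a - dz, config)
                            for zz in ens.positions[:, 2]])
            vis_a = w_a >= VISIBILITY_THRESHOLD
            plist.append(FramePair(a, b, config.dt, z_index=idz, z_um=dz,
                                   timestamp=pid * 10.0 * config.dt,
                                   pair_id=pid,
                                   meta={"n_visible": int(vis_a.sum()),
                                         "n_shared_visible": int(
                                             (vis_a & (w_b >= VISIBILITY_THRESHOLD)).sum()),
                                         "true_shift_px": shift}))
            pid += 1
        out[float(dz)] = plist
    return out


def default_heart_waveform(v_peak: float = 2.5,
                           regurg_amplitude: float = 0.6,
                           ) -> Callable[[np.ndarray], np.ndarray]:
    """Biphasic centreline-velocity waveform, um/ms as a function of phase.

    A forward ``sin^2`` lobe over ``[0, pi)`` followed by a shorter negative
    (regurgitation) lobe over ``[pi, 3 pi / 2)``.  With amplitude ratio
    ``regurg_amplitude`` the regurgitated volume is ``regurg_amplitude / 2``
    of the forward volume (0.3 at the default).
    """
    def waveform(phi: np.ndarray) -> np.ndarray:
        phi = np.mod(np.asarray(phi, dtype=float), TWO_PI)
        fwd = np.where(phi < math.pi, np.sin(phi) ** 2, 0.0)
        in_neg = (phi >= math.pi) & (phi < 1.5 * math.pi)
        neg = np.where(in_neg, np.sin(2.0 * (phi - math.pi)) ** 2, 0.0)
        return v_peak * (fwd - regurg_amplitude * neg)

    return waveform


def make_heart_phantom(waveform: Callable[[np.ndarray], np.ndarray],
                       n_beats: int, frames_per_beat: int,
                       config: SceneConfig, seed: int,
                       z_planes: Sequence[float] = (0.0,),
                       period_ms: float = 400.0,
                       anchors_per_beat: int = 128,
                       ) -> tuple[list[FramePair], tuple[np.ndarray, np.ndarray],
                                  GroundTruth]:
    """Pulsatile tube phantom emulating phase-gated heart acquisition.

    Each z-plane is acquired over its own ``n_beats`` consecutive beats with
    ``frames_per_beat`` frame pairs per beat, stratified in phase with a
    seeded jitter inside each phase slot.  Pairs carry timestamps only; a
    dense ``(timestamps, phases)`` anchor series emulating the brightfield
    synchronisation channel is returned alongside, and heart phases must be
    recovered from it by interpolation.
    """
    R = config.tube_radius
    y_c, _, _ = _tube_geometry(config)
    ss = SeedSequence(seed)
    pairs: list[FramePair] = []
    pid = 0
    n_z = len(z_planes)
    z_seeds = ss.spawn(n_z)
    for iz, z0 in enumerate(z_planes):
        rng = default_rng(z_seeds[iz])
        t_block = iz * n_beats * period_ms
        for beat in range(n_beats):
            slot_jitter = rng.random(frames_per_beat)
            for j in range(frames_per_beat):
                t = (t_block + beat * period_ms
                     + (j + 0.05 + 0.9 * slot_jitter[j])
                     * period_ms / frames_per_beat)
                phi_mid = TWO_PI * (((t + config.dt / 2.0) / period_ms) % 1.0)
                vmax_t = float(waveform(phi_mid))
                ens = _sample_tube_slab(config, z0 - config.slab_halfdepth,
                                        z0 + config.slab_halfdepth, rng)
                vel = poiseuille_velocity(ens.positions, vmax_t, R,
                                          center=(y_c, 0.0))
                ens_b = ens.advected(vel * config.dt)
                a = render_frame(ens, config, z0, rng)
                b = render_frame(ens_b, config, z0, rng)
                pairs.append(FramePair(a, b, config.dt, z_index=iz, z_um=z0,
                                       timestamp=t, pair_id=pid,
                                       meta={"n_tracers": ens.n,
                                             "true_phase": phi_mid}))
                pid += 1

    total_time = n_z * n_beats * period_ms
    step = period_ms / anchors_per_beat
    anchor_t = np.arange(0.0, total_time + 2.0 * step, step)
    anchor_phase = TWO_PI * ((anchor_t / period_ms) % 1.0)

    def velocity_function(pos: np.ndarray, phase: float) -> np.ndarray:
        return poiseuille_velocity(pos, float(waveform(phase)), R,
                                   center=(y_c, 0.0))

    def q_of_phase(phi: np.ndarray) -> np.ndarray:
        return (math.pi * R * R / 2.0 * UM3_PER_MS_TO_NL_PER_S
                * np.asarray(waveform(phi), dtype=float))

    phi_grid = np.linspace(0.0, TWO_PI, 8193)
    q_grid = q_of_phase(phi_grid)                       # nL/s
    t_of_phi = period_ms / 1000.0 / TWO_PI              # s per radian
    fwd = np.trapezoid(np.clip(q_grid, 0.0, None), phi_grid) * t_of_phi
    reg = -np.trapezoid(np.clip(q_grid, None, 0.0), phi_grid) * t_of_phi
    truth = GroundTruth(velocity_function, q_of_phase=q_of_phase,
                        net_volume=fwd - reg, forward_volume=fwd,
                        regurgitant_volume=reg,
                        params={"radius": R, "y_center_um": y_c,
                                "z_center_um": 0.0, "period_ms": period_ms})
    return pairs, (anchor_t, anchor_phase), truth


def make_gradient_scene(config: SceneConfig, intensity_slope: float,
                        seed: int, shift_px: tuple[float, float] = (6.0, 0.0),
                        ) -> FramePair:
    """Uniform-translation pair whose tracer brightness ramps across rows.

    Tracer geometry depends only on ``seed``; per-tracer amplitude is
    ``amplitude + intensity_slope * row``, floored at 1 count, so the same
    seed with two slopes yields identical geometry and different
    intensities.  The ground-truth vector field is the uniform ``shift_px``.
    """
    if not math.isfinite(intensity_slope):
        raise ValueError("intensity_slope must be finite")
    rows, cols = config.image_shape
    rng = default_rng(seed)
    pad = 8.0 * config.spot_sigma + max(abs(s) for s in shift_px) * config.pixel_size
    bounds = ((-pad, cols * config.pixel_size + pad),
              (-pad, rows * config.pixel_size + pad),
              (0.0, 1.0))
    mean = (config.seeding_density
            * (bounds[0][1] - bounds[0][0]) * (bounds[1][1] - bounds[1][0])
            / config.iw_area_um2)
    pos = _poisson_uniform(rng, mean, bounds)
    pos[:, 2] = 0.0
    row_px = pos[:, 1] / config.pixel_size
    intens = np.maximum(config.amplitude + intensity_slope * row_px, 1.0)
    intens = intens / config.amplitude
    ens = TracerEnsemble(pos, intens, config.tracer_diameter)
    disp = np.array([shift_px[0] * config.pixel_size,
                     shift_px[1] * config.pixel_size, 0.0])
    a = render_frame(ens, config, 0.0, rng)
    b = render_frame(ens.advected(disp), config, 0.0, rng)
    return FramePair(a, b, config.dt, meta={"true_shift_px": tuple(shift_px),
                                            "n_tracers": ens.n})
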