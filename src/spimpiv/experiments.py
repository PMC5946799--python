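"""Canned synthetic studies exercising the full pipeline.

Each function builds a scene with the generator, runs the analysis exactly
as the pipeline would on microscope data, and returns measured quantities
next to the generator's ground truth.  They are the package's reference
experiments: the test suite and the reproduction script both call them.

Problem sizes are desk scale: large enough for the statistical behaviour
of each study to be stable over seeds, small enough that the whole set
runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.random import SeedSequence

from . import metrics, phase
from .engine import PIVConfig, analyze_plane
from .profiles import fit_paraboloid
from .scenes import (SceneConfig, default_heart_waveform, make_gradient_scene,
                     make_heart_phantom, make_oopm_dataset, make_tube_dataset,
                     sample_tracers)
__all__ = [
    "oopm_tolerance_study",
    "effective_tracer_count_study",
    "tube_mode_study",
    "gradient_bias_study",
    "heart_phantom_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            SeedSequence(seed).generate_state(n, dtype=np.uint32) >> np.uint32(1)]


# ---------------------------------------------------------------------------
# out-of-plane motion tolerance
# ---------------------------------------------------------------------------

def oopm_tolerance_study(seed: int,
                         delta_z_values=(0., 1., 2., 3., 4., 5., 6.),
                         true_shift: int = 24,
                         n_pairs: int = 8,
                         n_seeds: int = 4,
                         image_shape: tuple[int, int] = (520, 696),
                         sheet_fwhm: float = 2.5,
                         tracer_diameter: float = 7.32,
                         noise_sd: float = 20.0) -> dict:
    """Recreate the out-of-plane-motion tolerance experiment.

    ~200 RBC-sized beads fixed in a volume, imaged at the full sensor
    frame through a thin sheet from focal planes separated by ``delta_z``
    with a known 24 px in-plane shift and mild read noise; one full-field
    interrogation window, correlation averaging over all pairs, repeated
    over ``n_seeds`` independent bead samples.

    Returns the per-seed error curves, the seed-averaged curve and the
    maximum seed-averaged error over ``delta_z <= 4`` um.
    """
    curves = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SceneConfig(image_shape=image_shape, sheet_fwhm=sheet_fwhm,
                          tracer_diameter=tracer_diameter, dt=1.0,
                          noise_sd=noise_sd)
        dataset = make_oopm_dataset(delta_z_values, true_shift, n_pairs, cfg, s)
        pc = PIVConfig(dt=cfg.dt, pixel_size=cfg.pixel_size)
        results = metrics.run_oopm_experiment(dataset, true_shift, pc)
        curves.append([r.delta_u for r in results])
    curves = np.asarray(curves)
    mean_curve = curves.mean(axis=0)
    dz = np.asarray(delta_z_values, dtype=float)
    return {
        "delta_z": dz,
        "curves": curves,
        "mean_curve": mean_curve,
        "max_error_le_4um": float(mean_curve[dz <= 4.0].max()),
        "mean_error_ge_6um": float(mean_curve[dz >= 6.0].mean())
        if np.any(dz >= 6.0) else float("nan"),
    }


# ---------------------------------------------------------------------------
# correlation-averaging arithmetic
# ---------------------------------------------------------------------------

def effective_tracer_count_study(seed: int, n_pairs: int = 250,
                                 density: float = 0.2,
                                 image_shape: tuple[int, int] = (120, 320),
                                 iw: tuple[int, int] = (32, 12)) -> dict:
    """Effective tracer count under correlation averaging.

    With ``density`` tracers per small IW per frame, averaging ``n_pairs``
    frame pairs makes ``n_pairs * density`` tracers contribute to each
    averaged map.  Measured empirically by counting, per IW footprint, the
    tracers that fall inside it summed over the ensemble draws.
    """
    cfg = SceneConfig(image_shape=image_shape, seeding_density=density,
                      ref_iw=iw)
    rows, cols = image_shape
    region = ((0.0, cols * cfg.pixel_size), (0.0, rows * cfg.pixel_size),
              (-cfg.slab_halfdepth, cfg.slab_halfdepth))
    nx, ny = cols // iw[0], rows // iw[1]
    acc = np.zeros((ny, nx))
    for s in _child_seeds(seed, n_pairs):
        ens = sample_tracers(cfg, region, s)
        ci = (ens.positions[:, 0] / cfg.pixel_size // iw[0]).astype(int)
        ri = (ens.positions[:, 1] / cfg.pixel_size // iw[1]).astype(int)
        ok = (ci >= 0) & (ci < nx) & (ri >= 0) & (ri < ny)
        np.add.at(acc, (ri[ok], ci[ok]), 1)
    return {"nominal": n_pairs * density,
            "empirical_mean": float(acc.mean()),
            "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# sheet vs volume illumination on the tube phantom
# ---------------------------------------------------------------------------

TUBE_Z_PLANES = tuple(np.arange(-20.0, 20.1, 5.0))


def _tube_points(fields, pixel_size: float) -> np.ndarray:
    pts = []
    for z0, f in fields:
        ok = np.isfinite(f.u) & ~f.excluded & (f.u_px >= 0)
        for x, y, u in zip(f.grid_x[ok], f.grid_y[ok], f.u[ok]):
            pts.append((x * pixel_size, y * pixel_size, z0, u))
    return np.asarray(pts)


def tube_mode_study(seed: int, flow_rates=(0.5, 1.0),
                    modes=("sheet", "volume"),
                    n_pairs: int = 40,
                    seeding_density: float = 1.0,
                    image_shape: tuple[int, int] = (176, 192),
                    z_planes=TUBE_Z_PLANES,
                    keep_maps: bool = True) -> dict:
    """Tube-phantom comparison of sheet vs volume illumination.

    For each flow rate and illumination mode, frame pairs are generated at
    a z-stack through a 50 um tube, analysed with correlation averaging,
    and the recovered vectors are fit with the two-pass elliptic paraboloid.
    Vectors are screened with the physical discard rules (non-negative
    horizontal component; the fit's own nominal-radius discard) so that the
    depth-of-correlation distortion of the raw volume-mode vectors is
    retained rather than thresholded away.

    Also collects, per z-plane, the averaged similarity map of the central
    interrogation window, from which the displacement-bias mechanism under
    volume illumination can be read off directly.
    """
    radius = 25.0
    out: dict = {"radius": radius, "z_planes": np.asarray(z_planes),
                 "cases": {}}
    seeds = _child_seeds(seed, len(flow_rates) * len(modes) * len(z_planes))
    k = 0
    for q in flow_rates:
        for mode in modes:
            dt = 0.3 if q <= 0.75 else 0.5
            cfg = SceneConfig(image_shape=image_shape, flow_rate=q,
                              illumination_mode=mode, dt=dt,
                              seeding_density=seeding_density)
            pc = PIVConfig(dt=cfg.dt, pixel_size=cfg.pixel_size)
            fields = []
            center_maps = []
            for z0 in z_planes:
                pairs, truth = make_tube_dataset(cfg, n_pairs, [z0], seeds[k])
                k += 1
                f = analyze_plane(pairs, pc, return_maps=keep_maps)
                fields.append((float(z0), f))
                if keep_maps:
                    center_maps.append((float(z0), _central_map(f)))
            pts = _tube_points(fields, cfg.pixel_size)
            fit = fit_paraboloid(pts, radius)
            out["cases"][(mode, q)] = {
                "fit": fit, "truth_v_max": truth.params["v_max"],
                "config": cfg, "fields": fields,
                "center_maps": center_maps if keep_maps else None,
            }
    out["bias_table"] = _map_bias_table(out) if keep_maps else None
    return out


def _central_map(f):
    """Averaged similarity map of the IW nearest the tube axis."""
    rows_mid = np.median(np.unique(f.grid_y))
    cols_mid = np.median(np.unique(f.grid_x))
    k = int(np.argmin(np.hypot(f.grid_x - cols_mid, f.grid_y - rows_mid)))
    return f.maps[k]


def _map_bias_table(out: dict) -> list[dict]:
    """Argmax displacement of the central-IW map vs the local truth, per z."""
    rows = []
    for (mode, q), case in out["cases"].items():
        cfg: SceneConfig = case["config"]
        v_max = case["truth_v_max"]
        R = out["radius"]
        to_px = cfg.dt / cfg.pixel_size
        for z0, smap in case["center_maps"]:
            if smap is None:
                continue
            i, j = np.unravel_index(np.argmax(smap.values), smap.values.shape)
            dx = float(smap.dx_axis[j])
            local = v_max * max(1.0 - z0 ** 2 / R ** 2, 0.0) * to_px
            center = v_max * to_px
            rows.append({"mode": mode, "flow_rate": q, "z_um": z0,
                         "argmax_dx": dx, "local_truth_px": local,
                         "center_truth_px": center})
    return rows


# ---------------------------------------------------------------------------
# SAD vs direct cross-correlation on the gradient scene
# ---------------------------------------------------------------------------

def gradient_bias_study(seed: int, n_pairs: int = 30,
                        intensity_slope: float = 8.0,
                        shift_px: tuple[float, float] = (6.0, 0.0),
                        image_shape: tuple[int, int] = (160, 192)) -> dict:
    """Transverse intensity bias of raw cross-correlation vs SAD.

    A dense tracer texture translates uniformly along +x while its
    brightness ramps along +y.  Product-based matching favours displacement
    candidates that sample the brighter side, dragging vectors toward it;
    a difference-based metric has no such preference.  Returns the mean
    signed transverse displacement component (positive = toward the bright
    side) per metric.
    """
    cfg = SceneConfig(image_shape=image_shape, seeding_density=1.5,
                      tracer_diameter=5.0, dt=1.0)
    pairs = [make_gradient_scene(cfg, intensity_slope, s, shift_px)
             for s in _child_seeds(seed, n_pairs)]
    out = {"true_shift_px": shift_px}
    for metric in ("sad", "xcorr"):
        pc = PIVConfig(small_iw=(24, 24), large_iw=(48, 48), metric=metric,
                       dt=cfg.dt, pixel_size=cfg.pixel_size)
        f = analyze_plane(pairs, pc)
        ok = np.isfinite(f.v_px)
        out[metric] = {
            "mean_transverse_bias_px": float(np.mean(f.v_px[ok] - shift_px[1])),
            "mean_u_px": float(np.mean(f.u_px[ok])),
            "mean_angular_dev_rad": float(np.mean(np.abs(np.arctan2(
                f.v_px[ok] - shift_px[1], np.maximum(f.u_px[ok], 1e-9))))),
        }
    return out


# ---------------------------------------------------------------------------
# pulsatile heart phantom end to end
# ---------------------------------------------------------------------------

def heart_phantom_study(seed: int, n_bins: int = 30,
                        n_beats: int = 14,
                        z_planes=tuple(np.arange(-25.0, 25.1, 5.0)),
                        image_shape: tuple[int, int] = (224, 96),
                        period_ms: float = 400.0,
                        v_peak: float = 2.5,
                        seeding_density: float = 0.5,
                        split_half: bool = True) -> dict:
    """Phase-binned correlation averaging and flow integration, end to end.

    A pulsatile Poiseuille phantom with a regurgitation lobe is imaged over
    ``n_beats`` beats per z-plane; phases are recovered by interpolating the
    emitted anchor series, pairs are grouped into ``n_bins`` phase bins and
    correlation-averaged per (z, bin); the flow rate through a cross-section
    plane at the image centre is integrated per bin and the per-beat
    forward, regurgitant and net volumes are compared with the analytic
    ground truth of the driving waveform.
    """
    waveform = default_heart_waveform(v_peak=v_peak)
    cfg = SceneConfig(image_shape=image_shape, tracer_diameter=6.0,
                      seeding_density=seeding_density, dt=1.5,
                      sheet_fwhm=2.0)
    pairs, (anchor_t, anchor_phi), truth = make_heart_phantom(
        waveform, n_beats, n_bins, cfg, seed, z_planes=z_planes,
        period_ms=period_ms)
    anchors = phase.PhaseAnchorSeries(anchor_t, anchor_phi)
    phased, dropped = phase.assign_phases(pairs, anchors)
    binning = phase.PhaseBinning(n_bins)
    groups, low = phase.bin_pairs(phased, binning)

    pc = PIVConfig(small_iw=(24, 24), large_iw=(56, 48), dt=cfg.dt,
                   pixel_size=cfg.pixel_size, ratio_threshold=1.07,
                   min_iw_intensity=1e5)
    step_y_px = pc.small_iw[1] * (1.0 - pc.overlap_fraction)
    z_arr = np.asarray(z_planes)
    dz_um = float(np.mean(np.diff(z_arr))) if z_arr.size > 1 else 2.0 * 25.0
    cell_area = step_y_px * cfg.pixel_size * dz_um
    plane_x = image_shape[1] / 2.0

    q_est = np.full(n_bins, np.nan)
    cov = np.full(n_bins, np.nan)
    fields_by_bin: dict[int, list] = {}
    for b in range(n_bins):
        stack = []
        for iz in range(len(z_planes)):
            members = groups.get((iz, b))
            if not members:
                continue
            stack.append(analyze_plane(members, pc, phase_bin=b))
        fields_by_bin[b] = stack
        if stack:
            q_est[b], cov[b] = metrics.cross_section_flow(stack, plane_x,
                                                          cell_area)
    series = metrics.FlowRateSeries(binning.centers, q_est, coverage=cov,
                                    period=period_ms)
    series = metrics.pumped_volume(series)

    result = {
        "series": series,
        "truth": {"net": truth.net_volume, "forward": truth.forward_volume,
                  "regurgitant": truth.regurgitant_volume,
                  "q_of_phase": truth.q_of_phase},
        "net_rel_error": abs(series.net_volume - truth.net_volume)
        / truth.net_volume,
        "regurg_fraction_est": series.regurgitant_volume
        / series.forward_volume,
        "regurg_fraction_true": truth.regurgitant_volume
        / truth.forward_volume,
        "dropped_pairs": dropped,
        "low_coverage_bins": len(low),
    }
    result["regurg_fraction_rel_error"] = (
        abs(result["regurg_fraction_est"] - result["regurg_fraction_true"])
        / result["regurg_fraction_true"])

    if split_half:
        result["split_half"] = _split_half_shrink(groups, z_planes, pc,
                                                  cell_area, plane_x)
    return result


def _split_half_shrink(groups, z_planes, pc, cell_area, plane_x,
                       small_group: int = 4) -> dict:
    """Split-half spread of the mid-plane flow metric at two group sizes.

    For every phase bin at the central z-plane the split-half spread is
    computed once on the full group (~14 pairs) and once on a truncated
    group of ``small_group`` pairs; shrinking spread with pair count shows
    up as a positive mean paired difference across bins.
    """
    iz_mid = len(z_planes) // 2

    def metric_fn(pair_subset):
        f = analyze_plane(pair_subset, pc)
        q, _ = metrics.cross_section_flow([f], plane_x, cell_area)
        return q

    full_d, small_d = [], []
    for (iz, b), members in sorted(groups.items()):
        if iz != iz_mid or len(members) < 2 * small_group:
            continue
        members = sorted(members, key=lambda p: p.timestamp)
        full_d.append(phase.split_half_flow_uncertainty(members, metric_fn))
        small_d.append(phase.split_half_flow_uncertainty(
            members[:small_group], metric_fn))
    full_d, small_d = np.asarray(full_d), np.asarray(small_d)
    return {"mean_spread_full_groups": float(full_d.mean()),
            "mean_spread_half_groups": float(small_d.mean()),
            "mean_paired_difference": float((small_d - full_d).mean()),
            "n_groups": int(full_d.size)}
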