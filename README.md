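# spimpiv — light-sheet micro-particle image velocimetry

`spimpiv` measures micro-scale flow fields from paired tracer images, the
way it is done for blood flow in small transparent animals such as the
larval zebrafish: fluorescent tracers (beads or labelled red blood cells)
are imaged twice in quick succession, and the displacement of the tracer
pattern between the two exposures gives the local fluid velocity.  It is
aimed at light-sheet (SPIM) microscopy, where a ~2 μm illumination sheet
provides true optical sectioning, so that a z-stack of 2D measurements
assembles into a depth-resolved (3D, two-component) flow field.

The package implements the full analysis chain plus a synthetic imaging
simulator with analytic ground truth, so every stage is testable without
a microscope:

* **Block matching by sum of absolute differences (SAD).**  Each small
  interrogation window (IW) of frame A is matched inside a larger
  concentric window of frame B; the score at displacement (Δx, Δy) is
  `Σ |A − B_shifted|`.  Unlike the product-based cross-correlation, SAD is
  not biased toward bright image regions — on scenes with an intensity
  gradient, raw cross-correlation vectors rotate toward the bright side
  while SAD vectors do not.
* **Correlation averaging.**  Per-pair similarity maps are averaged
  elementwise over many frame pairs before peak detection, so sparse
  seeding (e.g. 0.2 tracers per IW) still yields reliable vectors: 250
  averaged pairs behave like ~50 tracers per window.
* **Validation and sub-pixel refinement.**  The peak-to-peak ratio
  (best score over the next best outside a 7×7 mask around the peak) flags
  unreliable vectors; a three-point Gaussian fit refines the peak to
  sub-pixel accuracy.
* **Cardiac phase binning.**  For periodic flow, frame pairs are assigned a
  heartbeat phase in [0, 2π) by interpolating a phase-anchor series from a
  synchronisation channel, and grouped into bins of 2π/30 ≈ 0.209 rad so
  correlation averaging applies per phase.
* **Profile fitting and flow integration.**  A two-pass least-squares fit
  of the elliptic paraboloid
  `u(x,y,z) = V_max (1 − (y−y_c)²/a² − (z−z_c)²/b²)` (with tube tilt)
  recovers peak velocity and profile semi-axes; for a faithful
  reconstruction of a circular tube `a = b =` tube radius, so `b/a` is a
  direct diagnostic of depth-of-correlation distortion.  Cross-section
  integration of the phase-resolved field gives the flow rate
  `Q(φ)` and the pumped / regurgitated volume per beat
  (`Q = π a b V_max / 2` for the paraboloid).

## Worked example

Simulate a small bead-phantom z-stack (50 μm tube, Poiseuille flow at
0.5 μl/min), analyse it, and fit the flow profile:

```bash
spimpiv simulate --preset tube --seed 3 --out scratch/tube \
        --n-pairs 40 --n-z 9
spimpiv piv --in scratch/tube --out scratch/tube_piv --preset tube
spimpiv fit --fields scratch/tube_piv/vectors.csv \
        --out scratch/tube_fit.yaml --radius 25
```

The fit report (`scratch/tube_fit.yaml`) from this exact run contains:

```yaml
v_max_um_per_ms: 8.409629377404425
a_um: 25.274374809825616
b_um: 25.053060354091457
b_over_a: 0.991243524027818
flow_rate_ul_min: 0.5018676358138477
```

Read: the peak velocity is 8.41 μm/ms against a true centreline velocity
of 8.49 μm/ms for 0.5 μl/min in a 25 μm-radius tube; both semi-axes land
within 2 % of the true radius and `b/a ≈ 0.99`, i.e. the sheet-mode
reconstruction is circularly symmetric, and the integrated flow rate
returns the nominal 0.5 μl/min to ~0.4 %.  Running the same analysis on a
volume-illumination (brightfield-like) simulation instead yields
`b/a ≈ 1.5–2.1` — the depth-of-correlation artefact the light sheet
exists to remove.

The same studies are available directly in Python via
`spimpiv.experiments` (OOPM tolerance, tube mode comparison, gradient
bias, heart phantom end-to-end).

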