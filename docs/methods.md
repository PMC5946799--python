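# Methods

This note documents the models, parameter choices and numerical
conventions behind `spimpiv`, and what the synthetic studies do and do
not establish about real microscope data.

## 1. Velocimetry model

### Block matching

One velocity vector is estimated per interrogation window (IW).  A small
window (w×h px) of frame A is compared against every placement inside a
larger concentric window of frame B; window sizes are configured as
(width, height).  The match score is the sum of absolute differences
(SAD), computed by direct summation (a numba kernel with a pure-numpy
fallback), never by FFT: window sizes here make direct sums tractable and
exactly testable against a brute-force oracle.  SAD maps are stored
negated so that *maximum = best* holds for every metric; a raw
product cross-correlation metric (`metric="xcorr"`) exists solely to
demonstrate its intensity bias and applies no background subtraction.

Displacements are frame-B-relative-to-frame-A in pixels, x along columns
(right positive), y along rows (down positive, noted in output
metadata).  Physical velocity is `u = u_px · pixel_size · binning / dt`.

### Correlation averaging

Per-pair maps are averaged elementwise per IW before peak detection.
With seeding density ρ tracers per IW and N averaged pairs, ρN tracers
contribute to each averaged map (0.2 × 250 ≈ 50), which is what makes
sparse in-vivo seeding workable.  The peak-to-peak validation threshold
is applied to the averaged map only, matching the processing order in
which averaging precedes peak fitting.

### Peak detection, validation, sub-pixel

The averaged map is shifted to be non-negative if (and only if) it
contains negative values — negated SAD maps always do; already-positive
maps are left untouched so that ratios keep their plain peak1/peak2
meaning.  The peak is the argmax (ties break to the lexicographically
smallest (Δy, Δx), a deterministic and testable convention); a
(2h+1)×(2h+1) square around it (default 7×7) is masked and the ratio of
peak to next-highest unmasked value must reach the threshold (1.10 tube
preset, 1.07 heart preset) for the vector to be valid.  Sub-pixel
refinement is the PIV-standard three-point Gaussian fit per axis,

    δ = (ln v₋ − ln v₊) / (2 ln v₋ − 4 ln v₀ + 2 ln v₊),

falling back to a three-point parabola when a neighbour is non-positive,
and returning the integer peak with an edge flag when the peak touches
the map border.  Windows whose summed small-IW intensity stays below
`min_iw_intensity` in every contributing pair are marked *excluded*
(distinct from invalid); the heart preset uses 10⁵ summed counts, reading
the published per-IW intensity floor as a summed count since a per-pixel
mean of that size is not meaningful for a CCD.

Physical outlier rules (`validate_field`) optionally discard vectors with
the wrong horizontal sign for a known flow direction and vectors outside
a nominal tube radius; discarded values are retained for audit.

## 2. Synthetic scenes

The generator produces the four study scenes with analytic ground truth.
Design choices that the underlying experiments do not pin down:

* **Tracer images.**  Small tracers (diameter ≤ 4 σ_PSF) render as
  Gaussian spots with σ = hypot(σ_PSF, d/2.355), sampled at pixel centres
  (adequate for >1 px spots, cheap).  Large sheet-mode tracers (the
  7.32 μm OOPM beads, the RBC-like heart tracers) render with the exact
  uniform-sphere × Gaussian-sheet chord integral, which has a closed form
  in erf: in the sheet this is a sharp-edged projected disk (PSF-softened);
  leaving the sheet it dims *and shrinks to the illuminated cap*.  This
  matters: a Gaussian-blob approximation decorrelates far too fast with
  out-of-plane offset and cannot reproduce the measured tolerance of
  ~4 μm out-of-plane motion for RBC-sized tracers behind a 2.5 μm sheet,
  while the finite-sphere model reproduces both the tolerance and its
  collapse beyond ~5 μm.
* **Axial visibility.**  For small tracers the sheet weight
  w(z) = exp(−4 ln2 (z−z_f)²/FWHM²) applies directly (w = 1 in plane,
  exactly ½ at ±FWHM/2); for large tracers the effective axial profile is
  the sphere-sheet integral above (wider than the sheet by roughly the
  tracer radius).
* **Volume-illumination blur.**  No defocus model is prescribed by the
  source experiments, so the simulator uses the simplest model that
  reproduces the observed clutter mechanism: spot width grows linearly,
  σ(z) = σ₀(1 + c|Δz|) with c = 0.5/μm, and peak amplitude decays as
  (1 + c|Δz|)^(−p) with p = 0.5.  p was chosen once to reproduce the
  published brightfield phenomenology on the tube phantom (profile
  stretched along z with b/a ≈ 1.5–2.1 increasing with flow rate, y-axis
  profile preserved, peak velocity underestimated): p = 0 (constant
  amplitude) lets defocused tracers dominate everything and the fits
  diverge; p ≥ 1 weakens the clutter until the distortion nearly
  disappears.
* **Seeding.**  Density is defined as tracers per reference IW area per
  illuminated slab (depth 6 × sheet FWHM, the slab actually populated in
  sheet mode; >3 FWHM contributions are numerically negligible).  Tube
  scenes populate the full tube depth in volume mode with the same
  volumetric density.  Out-of-field tracers are kept and clipped at
  render time so advection can move them in and out of frame.  Tracer
  brightness is unit by default with optional lognormal variation.
* **Noise** is additive Gaussian (read-noise approximation), clipped at
  zero, default 0 so oracle tests separate algorithmic error from noise.
* **Contrast convention.**  Both illumination modes render bright
  tracers on a dark background; no absorption/brightfield contrast
  inversion is modelled.

Advection is exact (positions move by v·dt before rasterisation, to
<10⁻⁹ μm), so displacement errors measured downstream are attributable
to the estimator, not the scene.

### Scene inventory

* **Tube phantom** — steady Poiseuille flow, u = V_max(1 − r²/R²), along
  +x in a 50 μm tube at 0.5 or 1.0 μl/min (V_max = 2Q/πR² = 8.49 or
  16.98 μm/ms), pixel 0.3225 μm, dt 0.3/0.5 ms, sheet FWHM 2 μm.
* **OOPM experiment** — beads fixed in a volume; frame B is rendered from
  a focal plane displaced by Δz and then rolled by an integer pixel shift
  (24 px), so the in-plane truth is exact by construction.  The ensemble
  is sized to ~200 visible tracers (centre brightness ≥ 5 % of an
  in-sheet tracer) per field of view.
* **Heart phantom** — the tube phantom driven by a periodic waveform
  with a sin² forward lobe on [0, π) and a negative lobe of 0.6 relative
  amplitude on [π, 1.5π) (regurgitant fraction exactly 0.3), period
  400 ms, peak centreline velocity 2.5 μm/ms.  Acquisition is stratified:
  each z-plane is imaged over its own beats, one pair per phase slot per
  beat with seeded jitter inside the slot; a dense (timestamp, phase)
  anchor series emulates the synchronisation channel, and the analysis
  recovers phases only by interpolating it.
* **Gradient scene** — a dense tracer texture translating uniformly with
  a linear brightness ramp across the field; the scene that separates
  SAD from product-correlation behaviour.

## 3. Phase handling

Anchors are unwrapped (strictly increasing timestamps, non-decreasing
unwrapped phase), interpolated linearly and re-wrapped; no extrapolation
— pairs outside the anchored interval are dropped with a logged count.
A pair's phase is evaluated at the midpoint of its two exposures.  Bins
are half-open [kΔ, (k+1)Δ) with Δ = 2π/30 by default; binning with one
bin reproduces the steady-flow analysis exactly.  Split-half uncertainty
interleaves even/odd acquisition order so both halves span the whole
acquisition (removing drift confounds), computes the metric on each half
and reports the absolute difference.

## 4. Profile fit and flow metrics

The elliptic-paraboloid fit uses Levenberg–Marquardt least squares with
tight tolerances (1e−15), initialised from the 95th percentile of u
(V_max), the u-weighted centroid of fast samples (centres), and the
nominal radius (both axes); tilt enters as a linear drift of the profile
centre with x, reported in degrees.  Two passes: after the first fit,
samples whose tube-coordinate radius exceeds the nominal radius by more
than 2 % (on r²) are discarded and the remainder refit; the discard count
is reported.  Model values are not clipped at zero during fitting, and
samples are unweighted (no validity-ratio weighting).  Parameter standard
errors come from the Jacobian at the solution.

Cross-section flow rate sums (normal velocity × cell area) over the
valid cells of one IW column at fixed x through all z-planes, with cell
area = transverse IW step × z-step; invalid or excluded cells contribute
zero flow and are reported as reduced coverage rather than interpolated,
so the bias risk is visible per bin.  Per-beat volumes integrate the
binned flow-rate series over an explicitly supplied period; forward and
regurgitant volumes are the positive and negative parts.  Units are
centralised in one module: μm/ms internally, nL/s for flow rates,
μl/min for pump settings (Q[μl/min] = πabV_max/2 × 6·10⁻⁵ with a, b in
μm and V_max in μm/ms).

## 5. Reference studies and problem sizes

The studies in `spimpiv.experiments` are the package's reproduction
experiments, sized for minutes on one CPU:

* *OOPM tolerance*: full 696×520 sensor frame, ~200 visible beads,
  Δz ∈ {0…6} μm, 8 pairs per Δz, read noise 2 % of tracer amplitude,
  4 independent repeats; reports the seed-averaged |Δu| curve.
* *Effective tracer count*: 250 ensembles at 0.2/IW; counts tracers per
  IW footprint.
* *Tube mode study*: 176×192 px frames, 9 z-planes (−20…20 μm), 40
  pairs/plane, seeding 1.0/IW (a realistic bead-phantom density; the
  sparse 0.2/IW figure models in-vivo microinjection).  Fits use all
  finite vectors screened by the physical discard rules (non-negative u,
  nominal-radius discard) rather than the ratio threshold, which under
  heavy volume-mode clutter would remove exactly the biased vectors the
  study quantifies.
* *Heart phantom*: 224×96 px frames, 11 z-planes at 5 μm, 30 phase bins,
  14 beats per plane (~14 pairs/bin), RBC-like 6 μm tracers at 0.5/IW,
  plane at the image-centre column.
* *Gradient bias*: 30 pairs, 24×24 IWs, slope 8 counts/px across rows.

## 6. What passing tests show — and do not

The simulator shares the statistical structure of the real experiments
(sparse Poisson seeding, sheet-weighted visibility, defocus clutter,
periodic flow with regurgitation, asynchronous timestamps) but not their
full physics: no diffraction or aberrations, no tube-wall refraction, no
RBC shape or orientation, no shadowing/stripe artefacts, Gaussian noise
instead of full shot-noise statistics, and an invented (though
calibrated) defocus model.  Passing studies therefore demonstrate that
the *analysis chain* is correct and behaves as reported under controlled
conditions matching the published parameters — not that any particular
microscope will achieve the same numbers.  Quantities tied to the
original instruments and specimens (the exact fitted values from the
deposited tube datasets, the absolute in-vivo pumped volumes) are
reproducible only from the deposited data, which this package reads but
does not ship.

## 7. Known limitations

* Two velocity components only; the transverse-component scan
  (`oopm_proxy_scan`) bounds out-of-plane motion under a cylindrical-
  symmetry assumption but no 3-component reconstruction is attempted.
* No iterative window deformation or multi-pass grid refinement; strong
  intra-window shear shows up as peak broadening, as in any single-pass
  analysis.
* The cross-section plane is grid-aligned (one IW column per z); oblique
  planes are out of scope.
* `validate_field`'s radius rule assumes the tube axis runs along x in
  image coordinates.
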