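# Methods

This note records the models, conventions and numerical choices behind
`nodulescan`, and what the built-in simulator does and does not emulate.

## Measurement model

The pipeline assumes reflectometric pulse-echo data: a needle probe in
direct (dry) contact with the sample fires a short burst at each point of
a rectangular indentation grid and records the echo returned by a steel
plate under the sample.  Only that plate echo is analysed — direct
reflections from inclusion tops are orders of magnitude weaker and carry
too little SNR.  Detection rests on two effects of a stiff inclusion in
the two-way beam path:

1. **Amplitude attenuation.**  Over agar-in-agar inclusions the plate
   echo drops by about 60 %; over agar-in-liver inclusions by only about
   20 %.  These two contrasts are the defaults of the corresponding
   built-in scenarios.
2. **Edge shape distortion.**  Where the beam straddles an inclusion
   boundary, diffraction removes proportionally more energy above the
   centre frequency, visibly distorting the echo; fully covered and fully
   uncovered beams keep the transmitted shape.

CIA responds to (1); CIS, being amplitude-scale invariant, responds
to (2).  Their AND/OR fusion trades specificity (AND: fewer false
positives, inclusion cores) against sensitivity (OR: fewer false
negatives, full extent including rims).

## Coordinate and grid conventions

X–Y is the lateral plane (X along the slab length), Z is depth from the
probed surface; all positions in mm; the origin sits at the corner of the
scan area.  Grids are cell-centred: an area of W × H mm at pitch p holds
round(W/p) · round(H/p) points, each half a pitch in from the area edge.
Oversampling by factor f splits every native cell into f × f sub-pixels
on the same area (so 378 points at f = 6 give 13 608 classified
sub-pixels, and a 72 × 14 mm area at 2 mm pitch gives 252 points).

Ground truth is the lateral projection of each inclusion (disk, ellipse
or capsule), rasterized with a strict interior test on cell centres —
appropriate because the measurement integrates the whole through-thickness
path.

## Simulator

Each A-scan is built phenomenologically (no wave propagation):

* **Pulse**: Gaussian-enveloped cosine; the Gaussian's spectral std is
  chosen so the −6 dB full width equals `fbw · f0` (defaults f0 = 16 MHz,
  fbw = 0.25).  Sampling 200 MHz, record 10 µs gated to start 2 µs before
  the nominal plate echo (two-way travel through 15 mm of tissue at
  1540 m/s ≈ 19.5 µs); these acquisition parameters are package choices,
  not measured values.
* **Delay**: two-way travel through the local thickness; thickness carries
  a smooth ±0.2 % spatial ripple so echoes arrive with realistic
  point-to-point delay differences.
* **Attenuation**: the beam footprint is a 2 mm disk (the element size);
  coverage `f_cover` of inclusion projections is evaluated on a fixed
  symmetric quadrature grid (~200 points) inside the disk, and the echo is
  scaled by `1 − contrast · f_cover` (pointwise max contrast where
  inclusions overlap).
* **Edge spectral loss**: when `0 < f_cover < 1` the spectrum is
  multiplied by `10^(−(L/20)·(f/f0)^4)` with
  `L = 12 dB · 4·f_cover·(1−f_cover)`.  The quartic law concentrates the
  loss above f0, which is what gives edge echoes their distorted shape
  (and a strong amplitude dip — edge echoes are *dimmer* than echoes from
  deep inside a weak-contrast inclusion, so echo energy is monotone in
  coverage only for the deterministic amplitude factor, or when the edge
  re-shaping is disabled).  The 12 dB peak and exponent 4 are model
  choices; the physical effect is only known qualitatively.
* **Heterogeneity**: a per-point multiplicative amplitude jitter,
  Gaussian with fractional RMS 0.02 for agar and 0.12 for liver-like
  backgrounds (liver tissue is structurally far noisier than poured agar).
* **Bubbles**: Poisson-placed per inclusion volume (defaults 0.01–0.02
  per mm³), each multiplying the amplitude of nearby beam positions by a
  random factor in [0.2, 0.8].  Bubble placement is seeded by the phantom,
  not the acquisition: the same phantom keeps its defects across repeat
  scans.
* **Noise**: additive white Gaussian, default 30 dB SNR relative to the
  background echo peak.

The same (phantom, seed) pair reproduces every sample bit-identically.

What the simulator does **not** model: real diffraction beam patterns,
probe tilt, tissue motion under indentation, near-field effects and
frequency-dependent absorption.  Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the stated amplitude/shape
perturbations — not detection performance on real excised tissue, where
false classifications arise from exactly the unmodelled physics.

### Built-in scenarios

* `agar_fig5`: 100 × 60 × 15 mm agar block, four spheres of 12, 9, 6 and
  3 mm diameter at half depth (7.5 mm), contrast 0.6, scanned over
  72 × 14 mm (252 points).  The exact lateral centres of the physical
  prototype are not documented; the scenario spaces the spheres evenly
  (x = 9, 27, 45, 63 mm) on the scan mid-line.
* `liver_sample_like`: 30 × 40 × 15 mm liver-like slab with a small
  quasi-spherical deposit, an elongated channel filling and a flat
  ellipsoidal vessel filling, contrast 0.2, heterogeneity 0.12, scanned
  over 24 × 30 mm (180 points).

## Index computation

* **Gating**: a 0.5 µs window (~8 cycles at 16 MHz, long enough for the
  whole burst) centred on the maximum of the Hilbert envelope.  Windows
  are mean-subtracted before any sum so baseline offsets cannot leak into
  the indices.  A record whose envelope peak is below 4.5× the median
  envelope (pure noise peaks near 3–4×) is flagged as containing no echo.
* **Unclassifiable points**: flagged points get CIA = CIS = 1 in the maps
  (an absent plate echo is maximally unlike the reference — the same
  convention CIA uses for a zero-energy signal) and are marked
  `classifiable = False` in the exported table.  This keeps the index
  field complete for interpolation while preserving the audit trail.
* **Reference selection**: candidates default to the four grid corners.
  Among those that gate successfully, the candidate whose CIA against the
  lower-middle-energy candidate is smallest wins — the "most typical"
  background echo.  A candidate over an inclusion has a very different
  energy and loses.  The lower-middle order statistic (rather than
  "closest to the median") makes the choice stable under last-bit
  perturbations for even candidate counts.
* **CIS alignment**: sample thickness varies, so echoes arrive at
  different delays; computing the CIS product at a fixed lag would measure
  delay, not shape.  The per-point echo is aligned to the reference by
  normalized cross-correlation over integer lags with parabolic
  sub-sample refinement of the correlation peak, and
  `CIS = 1 − ρ²_peak`.  The refinement matters: at 200 MHz sampling a
  half-sample misalignment of a 16 MHz carrier costs ρ ≈ cos(0.25 rad),
  i.e. a spurious CIS of ~0.05 — the same order as a genuine edge
  signature.  `compute_cis` itself stays the pure zero-lag formula, so
  the analytic identities (proportional → 0, orthogonal → 1) hold exactly.

## Mapping and classification

* **Interpolation**: bilinear between native cell centres with edge
  clamping (default); nearest-neighbour replication available.  Default
  oversample factor 6 (2 mm → 0.33 mm).
* **Binarization**: 1-D k-means with k = 2 on the (sub-pixel) index
  values; the higher-mean cluster is "inclusion".  k-means is the
  simplest unsupervised two-class rule consistent with the yellow/blue
  map convention; Otsu is provided as an alternative and classifies the
  bimodal reference fixture identically.  The recorded threshold is the
  midpoint between the closest members of the two clusters.  A constant
  map classifies as all-background (with a warning); equal cluster means
  break toward background — conservative detection.
* **Binarization happens after oversampling** (sub-pixels are
  classified), so confusion counts are sub-pixel counts.

## Evaluation

* **Confusion percentages are row-normalized** (within each ground-truth
  class): TN% + FP% = 100 and FN% + TP% = 100.  This is the convention
  under which published confusion tables for this method are internally
  consistent, and the one frozen in the acceptance tests.
* **Localization**: connected components (8-connectivity) of a binary
  map; component centroids are matched one-to-one to nominal inclusion
  centres greedily by increasing distance (no matching rule is prescribed
  by the method itself; greedy nearest is the simplest deterministic
  choice).  An inclusion with any matched component counts as detected,
  however small the component — a single sub-pixel over the 3 mm sphere
  is a find.

## Problem sizes and determinism

Default runs use the native scenario sizes (252 and 180 points,
2 000-sample records); the acceptance script repeats the agar scenario for
five seeds (1 260 scanned points, 45 360 classified sub-pixels in total).
All randomness flows from explicit integer seeds (`numpy` PCG64 streams,
`KMeans(random_state=0)`), so every table, mask and CSV regenerates
bit-identically from its config and seed.

## Known limitations

* The simulator's edge-loss law and bubble model are qualitative stand-ins
  calibrated to the described effects, not fitted to measured spectra.
* Reference selection assumes at least one corner of the scan is
  inclusion-free; scans whose corners all sit on inclusions need explicit
  candidate points.
* Percentages are undefined (NaN) for ground truths with an empty class;
  callers scoring inclusion-free scenes should use raw counts.
* No morphological post-processing is applied to binary maps; isolated
  false-positive sub-pixels survive and are counted as such.
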