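# Methods

## The measurement model

A light curtain array (LC) is a pair of vertical poles, one emitting and
one receiving infrared beams, with barriers every `v = 2.5 mm` of height.
The pair travels past a bench of plants; at each sampling instant every
beam reports interrupted/clear.  The result is a binary matrix whose rows
are barrier heights (row 0 at bench level) and whose columns are travel
positions.  Because the sensor samples at a fixed temporal rate, the
horizontal pitch is proportional to travel speed:

    h = h_ref * speed / speed_ref,    h_ref = 2.5 mm at 0.9 m min^-1.

The sampling rate of the real instrument is not published; this
proportional convention is the package's definition of `h_pitch` and is
what makes raw pixel area inversely proportional to speed while leaving
heights (a purely vertical measure) untouched.  Pixel (r, c) covers the
half-open cell `[c·h, (c+1)·h) × [r·v, (r+1)·v)`.

## Segmentation

Per pot, in order:

1. **Seeding.** The foreground pixel nearest (Euclidean, pixel units) to
   (row 0, column = pot centre / h) within the growth radius; none found
   means an empty-plant record, not an error, so batch runs continue.
2. **Radial growth.** The smallest superset of the seed closed under
   "any foreground pixel within 25 px (Euclidean) of the set joins the
   set".  Distance is measured in pixel units, not mm — the radius is a
   property of the sensor resolution, and pitch anisotropy is deliberately
   ignored.  Closure over the *set* (not just the seed) is required so
   that chains of detached fragments (petioles, stem pieces) are collected
   outward.  Implementation: 8-connected components are merged while the
   minimum component gap (by distance transform) is within the radius;
   this equals the pixel-level closure whenever radius ≥ √2 and is
   verified against a brute-force pairwise oracle in the tests.
3. **Pot-edge rule.** With `n_r` the pixel count of silhouette row `r`,
   scanning upward, the rim is the smallest `r` with `n_r > 0` and
   `(n_r − n_{r+1})/n_r > 0.8`; the plant base is `r + 1` and everything
   below is discarded.  The denominator is the *lower* row — the pot is
   wide and the stem narrow, so an upward drop marks the rim.  If counts
   never drop (a bare pot ends in a drop to zero at its top row), the rule
   fires at the top and the plant is empty-flagged, which is the desired
   behaviour for plant-free pots.  When several rows qualify, the first
   from the bottom wins.
4. **Claim resolution.** In multi-plant scans a pixel reachable from
   several seeds goes to the horizontally nearest pot centre; ties go to
   the lower pot index.  Output order is pot order, deterministic.

## Traits and multi-view statistics

Pixel area is `|S|`; maximum height is `(r_max − r_base + 1)·v` (the top
cell's upper edge, so a single pixel at the base row is one pitch tall).

A *view stack* holds the 18 silhouettes at 0–170° in 10° steps; θ and
θ+180° give the same silhouette, so subset angles wrap modulo 180 and all
18 start positions are valid for any (n, step).  The maximum deviation to
the mean (MDM) of a subset scheme is the worst over the 18 starts of the
relative difference between the subset mean and a reference mean.  The
default reference is the mean of all 18 views; `window16` instead
references each start's mean of 16 consecutive views — both conventions
appear in practice, so both are exposed.  MDM(n) can never exceed MDM(1)
(a mean of deviations is bounded by the largest), and on seeded rosette
populations its mean falls monotonically from n = 1 to n = 4 at 50° steps.

Calibration is ordinary least squares *with* intercept of the measured
response (leaf area cm², or dry weight g) on pixel area; R² is the squared
Pearson correlation.  A model is stored with its speed and species group
and refuses application at another speed unless areas are normalized
first (`area · speed/ref_speed`).

## Synthetic plants

Two archetypes, both built from planar blades with an elliptical width
profile so the blade area is exactly `πLW/4`:

* **dicot_rosette** — 4–14 broad blades on petioles radiating from a short
  stem (20–60 mm), inclinations in the 15–40° planophile band; default
  true areas 12–350 cm².
* **monocot** — 3–9 long narrow tapering blades from a short culm,
  inclinations 60–80° arching over by 30–70°; default areas 7–317 cm²,
  heights up to 680 mm.

A population emulates a single cultivar at different developmental stages:
**size varies, shape is canalized**.  Leaf area targets are stratified
over the archetype's range; canopy diameter follows `√area` (±5 %);
plant-level habit values for inclination, petiole fraction and blade
aspect ratio are drawn from the central 10–20 % of each admissible range,
with small leaf-level jitter, and leaf count is solved from size and the
aspect habit.  This dispersion structure is what makes the prescribed
recovery property hold (R² ≥ 0.95 of mean-of-18 pixel area on true area
per archetype): letting shape vary independently of size at full-range
width degrades R² to ≈ 0.93 because projected area per unit leaf area
tracks inclination and self-overlap, not just area.

Sampling hits the target leaf area *exactly*: blade lengths follow from
the sampled canopy/height geometry, area is distributed over blades ∝ L²,
and widths are solved from the ellipse formula; draws violating the
admissible width/length ratios or the height range are resampled (≤ 50
tries).  `true_max_height` is the highest vertex of the geometric model.
Generation is deterministic given (archetype, params, seed).

**Rendering.** LC beams are parallel, so projection is orthographic: the
model is rotated about its vertical axis by the view angle and projected
onto the (travel, height) plane.  Each primitive (blade strip, midrib
segment, petiole, stem, pot) carries an occlusion thickness — the chord
length of a beam through the tissue, `t/|n·b|` for a slab of thickness
`t` with normal `n` (long for edge-on blades, the bare tissue thickness
face-on), capped at 30 mm.  A grid cell is foreground iff a shape covers
its centre and the thickness summed over shapes reaches the threshold
(default 1 mm; the real beam diameter is unpublished).  Blade tissue
tapers from 2 mm to 0.2 mm over the distal fifth, so thin erect tips fail
the threshold in near-face-on views: monocot height is underestimated
relative to threshold-0 renders and never overestimated — the thin-tip
artefact reported for barley.  Self-occlusion within a plant is automatic
because a pixel is simply interrupted or not.

**Sampling phase.** The instrument's sampling phase relative to the bench
is arbitrary per run, and anchoring a plant's axis exactly on a cell
boundary is a degenerate alignment that systematically hides thin axial
structures at coarse pitches.  Each rendered view therefore gets its own
deterministic phase offset (golden-ratio sequence over one pixel pitch);
`spread_phase=False` disables this for exact-symmetry tests.

**What a green test does not establish.**  The generator emulates size
ranges, planophile/erectophile contrast and thin-tip dropout, but not
leaf curvature/undulation, growth stages, leaf overlap with neighbouring
rows in depth, or any real instrument noise (sun flecks, vibration).
Calibration slopes recovered on synthetic populations demonstrate the
pipeline's ability to separate architectures, not the field slopes of any
real species.

## Numerical choices

* Rasterization uses exact cell-centre coverage of convex triangles
  (sign tests); triangles of one primitive count their thickness once,
  distinct primitives accumulate.
* The pot is an opaque rectangle, default 130 mm tall (printed value) and
  150 mm wide (unpublished; a 2 L pot's top diameter).
* Spacing composition aligns silhouettes on their base rows (both plants
  stand on the same bench) and pot-centre reference columns, with the
  spacing rounded to the nearest column; sub-pixel placement is out of
  scope.  Spacing is centre-to-centre: 0 cm means two rows scanned
  simultaneously, coincident centres.
* Seeds: every stochastic routine takes an explicit integer seed; derived
  child seeds stay below 2^31.

## Known limitations

* The 80 % rim rule can swallow plant rows when foliage directly above the
  rim is wider than 20 % of the pot width; the synthetic archetypes avoid
  this by construction (stem-only tissue at rim level), real scans may not.
* Exact inverse-proportionality of pixel area to speed degrades once
  projected features approach the coarse pitch (≲ 2 beam widths), exactly
  as thin-tissue dropout does at the native pitch.
* The spacing simulation is pairwise only; rows of many plants are handled
  by segmentation, not by composing more than two silhouettes.
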