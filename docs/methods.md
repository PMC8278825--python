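# Methods

## Interferometric forward model and inversion

The forward model treats each pixel independently: incident amplitude `a`,
scattered amplitude `b`, phase difference `Δφ`, and recorded intensity
`I(φ_m) = a² + b² + 2ab·cos(Δφ − φ_m)` at the four modulator phases
`{0, π/2, π, 3π/2}`. The sign convention (modulation subtracted from `Δφ`)
is fixed once; any self-consistent convention round-trips exactly, and the
test suite checks the implementation against an independent complex-
arithmetic oracle `|a + b·e^{i(Δφ − φ_m)}|²` rather than against itself.

The inversion is closed-form. `Δφ` comes from the quadrant-aware arctangent
of the two quadratures; the amplitude pair from `S = ΣI = 4(a² + b²)` and
`C = 4ab` by solving `t² − (S/4)t + (C/4)² = 0`, taking the branch `a ≥ b`
because SLIM assumes the unscattered field dominates. `β = b/a` is clipped
to `[0, 1]` and the reported phase is `φ = arg(1 + β e^{iΔφ})`.

Numerical choices:

- Degenerate pixels (both quadratures below `1e−12` of the stack maximum —
  no modulated signal) return `Δφ = 0`, `β = 0`, `φ = 0` and are flagged in
  a validity mask instead of NaN, so downstream statistics stay total.
- A negative quadratic discriminant beyond `1e−9` relative tolerance
  (inconsistent stack, e.g. heavy noise) is clamped to zero and flagged.
- Camera noise is additive Gaussian with clamping at zero intensity. Shot
  (Poisson) noise is not modeled; the noise hook is a single `noise_sd`
  parameter, so a different model could be substituted at the call site.
- All angles are radians wrapped to `(−π, π]`.

## Scan geometry, focus and stitching

A scan is an `n_rows × n_cols` grid of `tile_shape` frames with integer
lateral steps; overlap is `tile − step` per axis. The native geometry used
as default is a 1624 × 1224 px frame with steps 1580 (horizontal) and 1180
(vertical). Those step values are read in **pixels**: read in micrometres
they would exceed the ~255 × 170 µm field of view by a factor of six,
whereas the pixel reading leaves 44-px overlap strips on both axes, which
is what stitching requires. Steps are plain integers, so either convention
can be supplied.

Focus is interpolated bilinearly from four corner z-values (corner-based
rather than edge-based interpolation; a 1 × 1 grid sits at the top-left
corner). Coordinates are row-major, origin top-left, y down, 0-based,
half-open crops.

Blend modes: `overwrite` (row-major last tile wins), `average`, and
`feather` (separable linear ramp across each overlap strip, weight
`k/(ov+1)` so opposing ramps sum to one). Where overlapping tiles agree,
all modes return the common value, which makes stitch∘tile an exact
identity on consistent tiles — the property the tests rely on. No
cross-correlation registration is attempted: tiles are assumed to sit on
the planned grid.

## Dry mass, masks, histograms

`ρ = λφ/(2πγ)`. Defaults `λ = 0.55 µm` (central wavelength of the
broadband illumination) and `γ = 0.2 µm³/pg` (standard protein/lipid
refractive increment); both are arguments. Stain normalization is a global
affine map `φ′ = gain·φ + offset` with user-supplied coefficients recorded
in the output metadata — the first-order correction for the optical path
added by a histological stain.

Myelin masks threshold the phase map, by a fixed value or by Otsu's
between-class-variance criterion (delegated to scikit-image and verified in
the tests against a brute-force variance scan). A constant image has no
Otsu threshold; the mask comes back all-False with a logged warning.

Histograms pool pixels over maps (per class, not per image) into half-open
bins, 256 uniform bins over −0.5…3.0 rad by default. The group-overlap
statistic is the histogram intersection coefficient `Σ min(p_i, q_i)` —
symmetric, in `[0, 1]`, 1 iff the normalized histograms coincide — computed
for all six pairings of the four classes.

## Synthetic tissue generator

No deposited image set exists, so the generator stands in for
internal-capsule white matter. Each frame is a compound-Poisson fiber
field: `N ~ Poisson(density × area)` line segments with von Mises
orientations (κ = 4) around a per-map dominant axis, gamma-distributed
lengths (mean 40 px, shape 4), Gaussian cross-sections (width scale 3 px),
per-fiber amplitude 0.2 rad ± 15%, additive phase accumulation, a 0.05 rad
background and 0.02 rad Gaussian noise. The default density is 360 fibers
per 192 × 256 frame (the 4:3 aspect of the native camera frame at desk
scale); the amplitude/density pair was calibrated once so that (a) the
mean frame phase lands in the few-tenths-of-a-radian range typical of
thin tissue sections and (b) under the null (no class effects) the four
class-pooled histograms at 50 maps/class overlap at ≥ 0.95 — i.e. class
information is carried by texture, not by trivially separable pixel
statistics, reproducing the heavily overlapping group histograms seen in
real tissue.

The two binary factors act multiplicatively on the expected fiber count:
`size_effect` (AGA > SGA) and `diet_effect` (HF > CON), encoding the
direction "appropriate gestational size and the hydrolyzed-fat diet mean
more myelin". Both default to moderate values (1.5, 1.3) and are the knobs
the recovery tests turn. Note the deliberate consequence: with both
effects active, SGA-HF and AGA-CON frames have similar mean density and
are distinguishable mainly by texture, so the four-class task is partially
degenerate — the same confound the real screen exhibits.

Slides: each class's maps are spread round-robin over 4 synthetic source
slides; each slide carries a small random background offset
(σ = 0.01 rad), the within-animal correlation that makes held-out-slide
evaluation meaningful. Per-map seeds derive from
`SeedSequence((master, class_index, map_index))`, so datasets are
reproducible map-for-map.

What the generator does *not* emulate: biophysical axon packing, the
stain's chromatic signature, halo/shade-off artifacts, absolute piglet
phase values, and stage jitter. Passing recovery tests therefore show that
the pipeline detects texture-density differences of the modeled kind, not
that it would reach any particular accuracy on real tissue.

## Classification stage

The classifier head follows the screening design: two dropout layers at
rate 0.75 around dense layers (128, 64 units) and a softmax of 2 units
(diet or size) or 4 (joint). The feature extractor is pluggable; the
default `tinycnn` backbone is two 3×3-conv + average-pool stages, and
`pooled` (block-average downsampling) is a non-learned fast baseline. The
network, its backpropagation and the Adam optimizer are plain numpy,
fully seeded — training runs are bit-reproducible, and the backward pass
is verified against finite differences in the tests. A `fine_tune_all`
flag switches between training every weight (default) and head-only
training.

Defaults: learning rate 1e−3, batch 32, 10 epochs, inputs resized to
48 × 64 and linearly rescaled by the training split's min/max (values
outside the range pass through unclipped). Augmentation applies each of
{rot180, flip_x, flip_y} with probability 1/2; these generate the
4-element symmetry group of a rectangular frame (rot180 = flip_x∘flip_y),
so 90° rotations are excluded by construction.

Splits are seeded permutations; stratified splitting balances each split's
quota across classes as evenly as the counts allow (the survey-scale
10 000 → 8016/992/992 split is exactly class-balanced). Evaluation reports
accuracy, mean cross-entropy and a confusion matrix with row percentages.
Held-out-slide screening requires the joint model, refuses a slide that
appears in train/val (leak check), and reports the fractions of the
slide's images correct on both factors, diet alone, and size alone; the
joint rate is bounded by each marginal by construction.

Benchmark problem sizes (also used by `scripts/acceptance.py`): the
strong-separation diet task trains on 800 images (200/class, diet effect
3×) with 200 validation images; the null control on 400/100/100 with both
effects at 1; the joint/held-out-slide run on 360/100/100 at effects
(2.5, 2.0) with one slide fully excluded. Images are generated at 48 × 64
px for these runs — the texture model is scale-calibrated, so this keeps
training minutes-fast on one CPU while exercising the identical code path
as full-size frames.

## Known limitations

- The `β` recovery assumes the incident field dominates (`a ≥ b`); stacks
  violating it fold onto the `β ≤ 1` branch (flagged, clipped).
- Phase is reported wrapped; fiber crossings exceeding π alias in `Δφ`
  (the reconstructed `φ` is unaffected, being periodic in `Δφ`).
- The held-out-slide screen inherits the generator's mild slide effect; a
  stronger slide covariate (staining batch, section thickness) would make
  it harder and is not modeled.
- The null-control accuracy band is a statistical statement at the tested
  sample size, not a proof of independence.
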