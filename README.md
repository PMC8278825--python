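# picslim

Quantitative phase imaging of brain tissue with computational specificity:
simulation and reconstruction of SLIM (spatial light interference microscopy)
phase maps, whole-slide scan planning and mosaic stitching, dry-mass /
myelin densitometry, and a classification stage that screens tissue phase
maps by gestational size (AGA vs SGA) and diet (control vs hydrolyzed fat).

## The problem

Myelin adequacy in the developing brain is hard to quantify: standard
histology is qualitative, and the differences between adequately and
inadequately myelinated white matter are invisible to a pathologist's eye.
SLIM measures the optical path-length shift of the *unstained* tissue at
nanometer sensitivity, turning myelin content into numbers (phase, and from
it dry mass). Pairing those label-free maps with a learned classifier gives
computational specificity: single phase maps of internal-capsule tissue can
be screened for gestational-size and dietary effects on myelination.

`picslim` implements that computational chain end to end, with a synthetic
fiber-texture tissue generator so every stage is exercisable and testable
without microscope data.

## The model

SLIM decomposes the image field into the incident (unscattered) component
`U_i` and the scattered component `U_s`. A spatial light modulator adds four
phase delays `φ_m ∈ {0, π/2, π, 3π/2}` between them; the camera records

    I(φ_m) = |U_i|² + |U_s|² + 2|U_i||U_s| cos(Δφ − φ_m)

per pixel. Writing `a = |U_i|`, `b = |U_s|`, the four frames invert in closed
form:

    Δφ = atan2(I(π/2) − I(3π/2), I(0) − I(π))
    4ab = hypot(I(0) − I(π), I(π/2) − I(3π/2)),  4(a² + b²) = ΣI
    β  = b/a  (branch a ≥ b),   φ = arg(1 + β e^{iΔφ})

`φ` is the phase of the total field relative to the incident field — the
SLIM phase map. Dry-mass surface density follows from the refractive
increment `γ` (≈ 0.2 µm³/pg for protein/lipid):

    ρ = λ φ / (2π γ)    [pg/µm²]

A whole-slide scan tiles the sample into overlapping 1624 × 1224 px frames
(lateral steps 1580 / 1180 px → 44 px overlap strips) with focus
interpolated bilinearly from four corner z-values, and stitches the tiles
into a mosaic. Group comparisons pool per-class pixel histograms and measure
their intersection coefficient; classification trains a network whose head
has two dropout-0.75 layers around dense layers and a 2- or 4-way softmax
(diet, size, or joint task).

## Worked example

```python
import numpy as np
from picslim import (FieldDecomposition, simulate_interferograms, reconstruct_phase,
                     phase_to_dry_mass, myelin_mask, masked_dry_mass_stats)
from picslim.synth import FiberTextureParams, CLASS_LABELS, generate_fiber_phase_map

# one synthetic AGA-CON internal-capsule frame
params = FiberTextureParams()
tissue = generate_fiber_phase_map(params, CLASS_LABELS[0], seed=7)
print("mean tissue phase [rad]:", round(float(tissue.phi.mean()), 4))

# drive the four-frame forward model and invert it
decomp = FieldDecomposition(np.ones(tissue.shape), np.full(tissue.shape, 0.4),
                            tissue.phi, pixel_pitch=tissue.pixel_pitch)
stack = simulate_interferograms(decomp)
recon = reconstruct_phase(stack)
err = np.abs(recon.phi - np.angle(1 + 0.4 * np.exp(1j * decomp.delta_phi))).max()
print("reconstruction max error [rad]:", float(err))

# dry-mass densitometry under an Otsu myelin mask
mass = phase_to_dry_mass(tissue, wavelength=0.55, refractive_increment=0.2)
mask = myelin_mask(tissue, method="otsu")
stats = masked_dry_mass_stats(mass, mask)
print("otsu threshold [rad]:", round(mask.threshold, 4))
for k, v in stats.items():
    print(f"  {k}: {round(v, 3) if isinstance(v, float) else v}")
```

prints

```
mean tissue phase [rad]: 0.3816
reconstruction max error [rad]: 1.6653345369377348e-16
otsu threshold [rad]: 0.4261
  total_mass_pg: 120.464
  mean_density: 0.265
  area_um2: 455.218
  pixel_count: 18468
```

The synthetic frame carries a mean phase of 0.38 rad; the four-frame
round trip is exact to machine precision; Otsu picks a 0.43 rad myelin
threshold, under which the masked fibers carry 120 pg of dry mass at a mean
surface density of 0.27 pg/µm².

The same stages are available from the shell:

```
picslim synth --n-per-class 100 --seed 11 --out data/
picslim simulate --ground-truth gt.tif --beta 0.5 --noise 0 --seed 7 --out stack.tif
picslim reconstruct --stack stack.tif --out phase.tif
picslim stitch --plan plan.json --tiles tiles/ --blend feather --out mosaic.tif
picslim drymass --phase phase.tif --mask otsu --out stats.csv
picslim train --manifest data/manifest.csv --task diet --epochs 10 --seed 3 --out run1/
picslim demo   # tiny end-to-end pipeline
```

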