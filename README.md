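# swirlquant

Label-free quantification of cellular swirl patterns in mesenchymal
stromal cell (MSC) monolayers.

Confluent MSC cultures organize into nematic "swirl" patterns whose
topological defects mark sites of mesenchymal condensation — an early
morphological sign of chondrogenic commitment. `swirlquant` turns a
whole-well grayscale image (actin, phase-contrast, or nucleus channel)
into pattern statistics that can be screened against downstream potency
readouts, giving cell-therapy labs an imaging-based early quality
attribute for cartilage-repair cell batches.

## What it computes

- **Orientation & coherency** — per-pixel structure tensor
  J = ⟨∇I ∇Iᵀ⟩_w with Gaussian gradients and a Gaussian analysis
  window; orientation θ = ½ atan2(2Jxy, Jyy − Jxx) ∈ [−90°, +90°) and
  coherency C = (λmax − λmin)/(λmax + λmin) ∈ [0, 1].
- **Topological defects** — coarse-grained nematic tensor
  Q = ⟨(cos 2θ, sin 2θ)⟩, plaquette winding numbers
  k = (1/2π)∮dθ, clustering and confirming-loop charge assignment;
  taxonomy comet (+1/2), spiral (+1), tri-radius (−1/2).
- **Variance of coherency (VoC)** — the population variance of
  coherency over a circular analysis mask: low for fully ordered or
  fully disordered patterns, high when defects are present. The
  headline potency statistic.
- **Condensation area** — nucleus-channel pipeline (CLAHE, dual
  global/adaptive background subtraction, Gaussian density heatmap,
  0.5 threshold) yielding total aggregate area per well.
- **Donor-panel statistics** — replicate means ± SEM and per-day
  Pearson correlations with matrix-protein readouts (sGAG µg/µg DNA,
  Col2 ng/µg DNA), with linear fits.
- **Synthetic ground truth** — fiber textures and nuclei patterns with
  planted defects of known charge, and simulated donor panels with a
  planted defect-density → potency mapping, so the entire chain is
  testable without microscope data.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
import numpy as np
from swirlquant import (comet_spec, synthesize_texture, compute_orientation_field,
                        coarse_grain_director, detect_defects, variance_of_coherency,
                        CircularMask, TextureSpec)

# a 512x512 fibrous well with one planted +1/2 defect at the center
spec = comet_spec(512, seed=42)
image, _ = synthesize_texture(spec)

field = compute_orientation_field(image, window_sigma=10)
grid = coarse_grain_director(field, block_px=20)
found = detect_defects(grid, field)
for d in found.defects:
    print(f"defect at ({d.x_px:.0f}, {d.y_px:.0f}) px: charge {d.charge:+.1f} "
          f"({d.type}), raw winding {d.raw_winding:+.3f}")

mask = CircularMask.centered(image.shape, 230)
res = variance_of_coherency(field, mask)
print(f"VoC = {res.voc:.4f} over {res.n_pixels} pixels "
      f"(mean coherency {res.mean_coherency:.3f})")

ordered, _ = synthesize_texture(TextureSpec(width_px=512, height_px=512,
                                            background_theta_deg=25.0, seed=42))
res_o = variance_of_coherency(compute_orientation_field(ordered, window_sigma=10), mask)
print(f"ordered-texture VoC = {res_o.voc:.4f}")
```

Output:

```
defect at (250, 250) px: charge +0.5 (comet), raw winding +0.500
VoC = 0.0028 over 166196 pixels (mean coherency 0.752)
ordered-texture VoC = 0.0020
```

The planted comet is recovered at the right position with the right
half-integer charge (the raw, unrounded loop winding is printed for
diagnostics), and the defect-bearing well shows a higher VoC than the
same rendering with a uniform director — the ordering that makes VoC a
defect readout. VoC grows further with defect count (tested across 0,
2, 4 and 8 planted defects).

## Command line

```sh
swirlquant simulate texture --seed 3 --out well.tif     # synthetic well
swirlquant orient well.tif --window-sigma 10 --out out/ # orientation layers
swirlquant defects well.tif --window-sigma 10 --out defects.csv
swirlquant voc well.tif --window-sigma 10 --out voc.csv
swirlquant clusters nuclei.tif --out clusters.csv       # nucleus pipeline
swirlquant correlate --metrics voc.csv --proteins proteins.csv --out corr.csv
swirlquant run --images table.csv --proteins proteins.csv --out results/
```

Full-scale defaults (window 100 px, mask radii 3636/3336/2136 px,
pixel size 1.6 µm) apply to whole-well images; pass scaled parameters
for smaller images as above.

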