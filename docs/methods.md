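# Methods

## Background and model

Confluent monolayers of mesenchymal stromal cells (MSCs) behave as an
active nematic: elongated cells and their actin fibers align locally
along a common axis with no head–tail distinction, so the local
orientation is defined modulo 180°. The resulting "swirl" patterns
carry topological defects — points where the director field is singular
— characterized by a half-integer winding number (charge) *k*: +1/2
cores look like comets, +1 like spirals, −1/2 like tri-radii. Cells
aggregate at positive-charge cores (mesenchymal condensations, an early
marker of chondrogenic commitment) and recede from −1/2 cores. The
package quantifies these patterns from whole-well grayscale images and
relates them to chondrogenic potency readouts (sGAG in µg/µg DNA, Col2
in ng/µg DNA) across donors.

## Orientation and coherency

Local orientation is estimated from the structure tensor
J = ⟨∇I ∇Iᵀ⟩_w, with Gaussian-derivative gradients (scale
`gradient_sigma`, default 1 px) and Gaussian window averaging (scale
`window_sigma`, default 100 px — the whole-well analysis window at
1.6 µm/px). From the tensor's eigen-structure:

- orientation θ = ½·atan2(2Jxy, Jyy − Jxx), reported in degrees in
  [−90, +90);
- coherency C = (λmax − λmin)/(λmax + λmin)
  = √((Jyy − Jxx)² + 4Jxy²)/(Jxx + Jyy) ∈ [0, 1];
- energy E = Jxx + Jyy.

Degenerate pixels (E = 0, e.g. constant regions) are assigned C = 0 and
θ = 0: a featureless neighborhood is isotropic by the definition of
coherency. All convolutions use reflective boundary padding. Coherency
is never energy-weighted. Angles follow the display convention (x
right, y up, counter-clockwise positive); with gradients taken along
array columns and rows, the atan2 form above returns that display angle
directly, which the stripe-recovery tests lock in. Coherency is
invariant, and θ equivariant, under 90° rotations, flips, and positive
affine intensity rescaling — all property-tested.

## Defect detection

Winding numbers on raw per-pixel orientation are noise-dominated, so
the field is first coarse-grained: the nematic tensor
Q = ⟨(cos 2θ, sin 2θ)⟩ is averaged over blocks of `block_px` (default
20 px), coherency-weighted by default so isotropic pixels carry no
vote. Averaging Q rather than raw angles respects the mod-180 topology
(+89° and −89° average to the ±90° boundary, not to 0°).

Detection: (1) the winding of every 2×2 block plaquette is computed,
each director increment wrapped into (−90°, +90°]; (2) plaquettes with
|winding| ≥ `min_abs_charge` (default 0.25) are clustered by single
linkage within `merge_radius_blocks` (default 2); (3) each cluster is
confirmed by a circular loop of radius 3 blocks (directors read by
bilinear interpolation of Q), its charge is the confirming winding
rounded to the nearest half integer, and its core sits at the cluster's
coherency minimum. Equal-charge detections whose confirming loops
overlap (closer than the confirming radius) are collapsed to one
defect, so a +1 spiral — whether a topologically single defect or a
tight +1/2 pair — is reported as a single entity under the default
merge configuration; both readings remain reachable through
`merge_radius_blocks`. Confirming readings farther than 0.15 from every
half integer are labelled `other` rather than forced into the taxonomy.
Charge conservation (sum of detected charges = boundary winding) and
loop-radius independence at radii 2/3/5 blocks are tested invariants;
detection achieves precision and recall ≥ 0.9 on a seeded suite of 20
textures with 1–6 planted defects.

## Variance of coherency (VoC)

Coherency is uniformly high in ordered regions, uniformly low in
disordered ones, and spreads from low to high around a defect; its
variance over an analysis region is therefore a scalar readout of
defect content. VoC is the population variance (divisor n) of raw
masked per-pixel coherency values over a circular mask (default radius
3336 px on whole wells, shrunk proportionally on smaller images); the
256-bin histogram is produced for reporting only — a binned variance
would differ by at most bin_width²/12 ≈ 1.3e-6, and the raw value is
better defined. At well scale (~10⁷ pixels) the population/sample
distinction is negligible; population is fixed for reproducibility.
Replicate reproducibility is summarized as CV% = 100·sd(ddof=1)/mean.

## Nucleus condensation pipeline

Nucleus images are circularly cropped (default radius 2136 px, removing
uneven illumination at well corners), CLAHE-enhanced (clip limit 0.01,
8×8 tiles), and background-subtracted using the AND of a global Otsu
foreground and a local adaptive (neighborhood-mean, 101-px window,
offset 0) foreground; AND is the conservative reading of combining two
masks for background removal, with OR available via configuration. The
cleaned image is smoothed — "radius 100 px" realized as a Gaussian with
σ = 50 px, or a uniform 100-px kernel for density colormaps —
max-normalized to [0, 1], thresholded at 0.5, and the surviving area
summed (px and µm²). Manual debris curation is replaced by a
reproducible minimum-component-area filter (default 5000 px²). The
half-max level set of a Gaussian cluster of scale σ is a disc of radius
σ√(2 ln 2); the measured area matches that closed form within 10% in
the tests.

## Donor-panel statistics

Per-well metrics are summarized to per-(donor, day) means with standard
errors (sd(ddof=1)/√n, undefined for n = 1); each day's donor means are
correlated against donor protein readouts by Pearson's r with an
ordinary least-squares line. Correlation on replicate means (matching
how donor panels are plotted, typically 5 points) is the default;
pooled per-replicate correlation is available behind a flag. No
p-values are attached by default; a permutation p-value option exists.
At least 3 complete donors per day are required; sparser days are
skipped with a warning.

## Synthetic data

The generator defines the test-bench conditions; no real images ship
with the package.

- **Director fields** use the standard isolated-defect solution
  θ(x, y) = Σᵢ kᵢ·atan2(y − yᵢ, x − xᵢ) + θ₀, which reproduces the
  comet/spiral/tri-radius geometries exactly; winding around any loop
  equals the sum of enclosed charges (brute-force-integrated in tests).
- **Fiber textures** scatter Poisson-distributed anti-aliased line
  segments (default length 15 px, width 1.5 px, density 0.02/px²,
  noise sd 0.05) oriented by the local director, chosen over
  line-integral convolution for determinism and simplicity. Orientation
  estimation on rendered textures recovers the planted field with mean
  absolute error < 5° outside core-exclusion discs of 3× fiber length
  (orientation is undefined at the singularity).
- **Nuclei** are Poisson point patterns (points/px²) rendered as 2-px
  Gaussian spots, enriched ×5 in 40-px discs around positive charges
  and thinned to ×0.2 around negative ones.
- **Donor panels** emulate a 5-donor × 4-day × 3-replicate design. Each
  donor draws a latent defect density (evenly spread over 2–10 defects
  per well plus jitter); proteins come from a strictly monotone potency
  map (defaults landing in plausible assay ranges: sGAG ≈ 4–16 µg/µg
  DNA, Col2 ≈ 10–100 ng/µg DNA) with 5% multiplicative noise. Replicate
  wells are either fully rendered textures (`mode="images"`) or direct
  VoC draws from a fixed monotone response (`mode="voc"`) for fast
  statistical experiments. Actual defect densities per well in real
  cultures are not published; the 2–10 range is a free, documented
  choice. All randomness flows through explicit per-spec seeds; outputs
  are bit-reproducible.

What the generator does *not* emulate: stitching seams, uneven
illumination in the actin channel, cell-shape heterogeneity, day-to-day
pattern evolution within a donor, and biological donor-to-donor
variability beyond a single latent scalar. Passing recovery tests
therefore demonstrate that the measurement chain is correct and
self-consistent, not that real-donor correlations of any particular
magnitude will be observed.

## Problem sizes and numerical choices

Synthetic wells are 512×512 px (a ~14× linear scale-down of a ~7300-px
whole well) with the analysis window scaled to σw = 10 px and the VoC
mask radius to 230 px; full-scale defaults remain in `RunConfig`. The
end-to-end recovery run (60 rendered wells through the full pipeline)
completes in well under a minute on one CPU. The null-panel experiment
(200 seeded repeats) uses the fast VoC mode. Ties, degenerate inputs
and empty results follow explicit conventions: empty masks and
zero-variance correlations raise; empty foregrounds and empty defect
sets are valid results; all-zero heatmaps skip normalization.

## Known limitations

- The structure-tensor window couples nearby defects; cores closer than
  about one window cannot be resolved separately.
- Charges of magnitude > 1 are reported but typed `other`.
- The condensation pipeline is density-based; it neither counts nuclei
  nor segments instances.
- Defect tracking over time and flow/stress inference at defects are
  out of scope.
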