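# Methods

## Scope and data model

fretleaf quantifies a nuclear-localised ratiometric FRET biosensor in
multi-channel confocal z-stacks and classifies the segmented nuclei into
five leaf cell types; companion modules quantify stomatal aperture/density
from 2D impressions and stained area from RGB leaf-disk images. Arrays are
kept in numpy (z, y, x) order with anisotropic voxel sizes in µm; tables
(ground truth, per-nucleus "Result Table", pore records, summaries) are
pandas DataFrames written as CSV. Stacks round-trip through 16-bit ImageJ
TIFF with voxel-size metadata.

## The phantom generator

No raw imagery of this kind is publicly deposited, so validation rests on
a synthetic scene model with exact ground truth.

**Layered leaf geometry.** Nucleus centres are placed by rejection
sampling inside class-specific depth bands of an 80 µm stack (abaxial
imaging order): stomata and pavement 0–15 µm, spongy mesophyll 15–60 µm,
bundle sheath 35–70 µm, vascular bundle 50–80 µm. Each nucleus is inset
by its axial semi-axis so it lies wholly inside its tissue band, and two
placement constraints hold pairwise: centre distance ≥ 8 µm, and ≥ the sum
of the two largest semi-axes + 0.5 µm, which guarantees the rendered
ellipsoids are disjoint (rendering still verifies this and raises rather
than blending). Vascular nuclei are strung along a random vein axis at
8.5–9.5 µm spacing, ±1.2 µm lateral jitter, at a coherent vein depth
(shared base ± 1.5 µm): veins are physically contiguous structures, and
this makes 3D neighbour density a usable classification feature.

**Shape priors.** Per class, semi-axes (a, b in-plane, c axial, µm) are
truncated normals (±2 sd, absolute floor 1.2 µm — nuclei are never thinner
than the axial sampling): stomata 2.6/2.4/2.2 ± 0.25; pavement
9.0/7.0/2.8 ± 0.8 (large, flat); mesophyll 4.2/3.4/3.0 ± 0.45; bundle
sheath 8.0/2.8/2.5 ± 0.4 (elongated, horizontal major axis); vascular
2.8/2.5/2.3 ± 0.25. In-plane orientation is uniform (vein nuclei align
with the vein).

**Ratio scenario.** Every nucleus carries a true emission ratio
R = baseline + Δ(class)·[infested] + N(0, 0.05), floored at 0.05.
Baseline is 0.6 in all classes. Infestation deltas are largest for
stomata (0.30) and vascular bundle (0.28), intermediate for bundle sheath
(0.15), and 0.12 for pavement and mesophyll — the qualitative pattern the
pipeline is asked to recover, encoded as ground truth rather than as a
hard-coded result. No absolute per-class ratio values are published for
this sensor/tissue combination, so these magnitudes are free parameters
chosen once. Under `condition="infested"` each mesophyll nucleus is
independently dropped with probability 0.3 (the viability effect of
mesophyll-feeding damage); all other class counts are condition-invariant.

**Rendering.** Inside each ellipsoid, with donor-excited total emission T
(default 300 ± 30 counts) and sensor abundance A (default 500 ± 50):
DxDm = T/(1+R), DxAm = T·R/(1+R), AxAm = A; outside, each channel sits at
its background level (default 2 counts). This partition makes
DxAm/DxDm = R an identity in the noiseless limit and conserves
DxDm + DxAm = T. Noise (applied after composition) is Poisson shot noise
plus Gaussian read noise (sd 2 counts), matching a photon-counting
detector with a small electronic floor. Writing to disk clips to
[0, 65535] and rounds (16-bit).

The *analytic* scenario used for exact ratio-recovery checks is the same
model with noise off, zero background and a bright acquisition
(T = 12000, A = 20000): at those counts 16-bit rounding perturbs a ratio
by ≲ 2×10⁻⁴, so recovery can be asserted at 10⁻³ relative through the
file contract. At the noisy default of 300 counts, integer rounding alone
can move a per-nucleus ratio by ~0.7%, which is why the exactness claim
is tied to the bright scenario and the noisy scenario carries a bias
bound (< 2%) instead.

**2D phantoms.** Impression fields render dark elliptical pores with 4×
supersampled partial-volume edges (boundary pixels take intermediate
grays, as in transmitted-light images); truth records each pore's
analytic length, width and width/length ratio. Stained disks place random
blobs of the stain colour inside a circular disk until a target area
fraction is reached, trimming the final blob so the stained pixel count
is *exact*; geometry depends only on the seed, so the same seed with
different stains yields identical masks. Requested fractions above 0.9
are rejected as unreachable packing.

## Segmentation and features

The AxAm channel is Gaussian-smoothed (σ = 1 µm, converted to voxels per
axis), thresholded (Otsu by default; a fixed threshold above the channel
maximum yields zero labels with a logged warning), connected-component
labeled (26-connectivity default) and volume-filtered to [15, 4000] µm³;
labels are compacted to 1..N. There is no watershed splitting: the
generator guarantees separation, and real merges are caught by the volume
ceiling. Features are measured in physical µm on the **raw** channels —
smoothing shapes the mask only, never the intensities. Second-moment
semi-axes use the voxel-binning correction (add h²/12 per axis to the
covariance before a = √(5λ)), which matters for nuclei only 2–3 z-slices
thick; single/few-voxel objects get voxel-sized axes and a
`degenerate_shape` flag. Depth is measured from the shallowest nucleus
centroid (robust to mounting offset; the absolute stack reference is
available by using `z_um` where a scene lacks epidermal nuclei).
Background is the per-channel median over unlabeled voxels (requires ≥ 1%
background).

A known mask effect: the smoothing halo dilates thin axes by up to ~10%
and erodes long axes slightly, so *measured* diameters and elongations
sit below the generative priors. Classifier defaults are therefore
calibrated against measured phantom feature tables, not against the
priors.

## Ratiometry

Per-nucleus ratio = background-corrected mean DxAm / mean DxDm (ratio of
means, not mean of voxelwise ratios, which would amplify noise and
diverge at dim voxels). With a common background estimate the partial
inclusion of boundary/background voxels cancels exactly between numerator
and denominator. Nuclei whose corrected donor mean falls below the floor
(5 counts) are excluded (`low_donor_signal`) rather than producing
unstable ratios; negative corrected numerators clamp to 0 — ratios are
never negative. The DxAm band is the 525–560 nm acceptor-emission band
and DxDm the 460–500 nm donor band under donor excitation; for data whose
channel convention is reversed, `RatioParams(invert_ratio=True)` flips
the ratio without touching the data.

## Cell typing

A fixed-order rule cascade (exhaustive and exclusive by construction):
epidermal depth (≤ 12 µm) splits small (< 7 µm equivalent diameter →
stomata) from large (≥ 9 µm → pavement) nuclei, with the intermediate
band resolved by a configurable tie-break that defaults to pavement
(erosion shrinks large flat nuclei into the band far more often than it
inflates guard-cell nuclei); deep nuclei (≥ 45 µm) with ≥ 2 neighbours
within 20 µm are vascular; remaining nuclei with elongation ≥ 1.6 are
bundle sheath (midway between measured mesophyll ≈ 1.1–1.4 and measured
bundle sheath ≈ 2.0–2.3); everything else is spongy mesophyll. Rules
rather than a trained classifier keep the stage auditable, deterministic
and threshold-transparent; every threshold is configurable. Scoring
against truth matches predicted to true nuclei by greedy nearest-centroid
pairing within 4–5 µm (collisions logged), reports a 5×5 confusion matrix
(rows truth), and counts unmatched nuclei separately.

## Morphometrics and stain quantification

Pores are dark objects under an inverted global threshold, size-filtered
(20–2000 px²). The ellipse fit takes the major axis from
partial-volume-weighted second moments (weights from the gray ramp
between pore core and background) and the minor axis from the weighted
area via area = π·a·b — markedly more robust than λ_min moments for pores
a few pixels wide (measured: ≤ 1% aperture error at ≥ 30 px major axis,
≤ 3% at ≥ 10 px). Aperture is width/length in (0, 1]; density is
count/area in pores·mm⁻². Stain rules: trypan blue by blue-over-red
dominance (margin 20 of 255); DAB brown and chlorotic yellow by HSV hue
windows (0.02–0.11 and 0.12–0.19) with saturation/value guards — hue is
invariant to illumination scaling, and the three rules are mutually
exclusive on each other's phantoms. The stained mask is always
intersected with the disk (or rosette) mask — auto-detected as the
largest non-background component with holes filled, or supplied
explicitly. Area in mm² = pixels × (pixel size µm)² / 10⁶; DAB areas can
be normalised to a control-group mean (relative staining units).

## Statistics

Welch's unequal-variance t is the default two-sample test (a
pooled-variance Student mode exists); the variance assumption is rarely
defensible for per-image counts, and Welch costs little when variances
are equal. Degenerate conventions: two constant samples with equal means
→ p = 1 (statistic 0, noted); unequal constant samples → p = 0. Two-way
factorial ANOVA uses type-II sums of squares on (near-)balanced designs
via statsmodels OLS; effects with zero SS (exactly additive data) are
reported as F = 0, p = 1 rather than 0/0; post-hoc (Tukey HSD or
Sidak-corrected pairwise Welch, selectable) is computed only when an
effect is significant, and skipped with a note when the residual variance
is exactly zero. BH-FDR is implemented directly as the step-up
q = min over ranks of p·m/rank (cross-checked in tests against an
independent implementation); BH was chosen as the standard step-up FDR
procedure. The count comparison runs Welch per cell type on per-image
nucleus counts plus the total, BH-corrected across those six tests.
Pearson R² requires n ≥ 3 and non-constant inputs.

## Pipeline, determinism and problem sizes

`run_pipeline` simulates n images per condition (default 8, mirroring the
replicate count of a multi-leaf biosensor comparison), runs each through
segmentation → ratiometry → typing, and emits per-class summaries,
deltas, the condition × cell-type ANOVA, the per-class ratio comparison
(five classes + all cells, BH over six), the count comparison, per-stage
CSVs and a JSON manifest (config, derived per-image seeds, versions) from
which any run reproduces byte-identically. Every random draw descends
from one integer seed via numpy `default_rng` seed sequences.
`imaging=False` feeds generator truth straight to the statistics — the
right mode for calibration studies of the statistical layer (hundreds of
runs in seconds).

Evaluation problem sizes, chosen as the package's own defaults: the
segmentation/typing suite uses 20 seeds of the full 512×512×40 default
stack; pattern-recovery runs use 256×256×40 stacks (same voxel size,
proportionally fewer nuclei) over 20 runs × 16 images; the null
calibration uses 200 truth-mode runs. These sizes keep a complete
evaluation under ~6 minutes on one CPU without altering any modelled
effect size, noise level or per-group replicate count.

## What passing the phantom suite does and does not show

The phantoms reproduce the *statistical* structure relevant to each
stage: class-dependent shape/depth/clustering, exact FRET partition
arithmetic, shot + read noise, partial-volume edges, exact stained
fractions. They deliberately omit optical point-spread blur, spectral
bleed-through, photobleaching, chromatic shift, autofluorescence and
illumination gradients. Passing therefore validates the correctness and
calibration of the algorithms under the stated imaging model — not
robustness to every real-world artefact; on real data the classifier
thresholds and stain hue windows are the parameters most likely to need
re-tuning, and both are fully exposed in configuration.

## Known limitations

- Touching nuclei are not split; the volume ceiling flags merges instead.
- Classification thresholds are calibrated to this phantom suite; they
  are starting points, not universal constants.
- The emission ratio is a relative ABA readout; conversion to absolute
  concentration would require an in-vitro sensor calibration that is out
  of scope.
- Two-way ANOVA assumes (near-)balanced designs; heavily unbalanced
  designs would warrant type-III SS or mixed models, which are not
  implemented.
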