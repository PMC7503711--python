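# Methods

This note documents the measurement model, the synthetic-scene
generator, the classical segmenter and the evaluation suite: what each
assumes, the parameters that matter, and where the design was genuinely
open.

## Measurement model (morphometry)

**Calliper.** Particle size is the horizontal extent of the instance
mask, `(max col − min col + 1) · nm/px`. Because the horizontal axis is
a random direction relative to each particle, the calliper is a
direction-randomised size. The mask delimits the *inner* edge of the
dark stain rim — the convention used when measuring "between inner edges
of positive contrast" — so all sizes refer to the particle proper, not
the stain.

**Moment ellipse.** `fit_axes` reports the major/minor axes of the
second-central-moment-equivalent ellipse (scikit-image regionprops),
converted to nm. Masks under 5 px or collinear masks are rejected.

**Spheroid-equivalent diameter.** Thin embedding films orient flattened
spheroids *en face*, so the measured major axis approximates the
equatorial diameter `D`. To compare with orientation-averaging methods
(NMR, DLS, rotational averages), the oblate spheroid with axes
`(D, D, rD)` is summarised by the arithmetic mean of its three axes:

```
D_eq = D · (2 + r) / 3,      r = ref_minor / ref_major = 12.1 / 21.4
```

The reference aspect comes from cryo-EM LDL axes 21.4 ± 1.3 by
12.1 ± 1.1 nm. The mean-of-axes form is the only simple reading of a
"mean radius of the corresponding spheroid" that reproduces the
published corrected values from their published inputs (23.41 → 20.019,
23.82 → 20.369, 24.00 → 20.523, 25.02 → 21.396); note the first two
reference values are printed truncated (20.01, 20.36), so agreement is
asserted at the printed resolution of 0.01 nm rather than as exact
rounding. The map is linear (`f(aD) = a·f(D)`) and the identity for a
sphere (`r = 1`).

**Summaries.** Mean, sample SD (n−1 denominator; SD = 0 for n = 1),
CV% = 100·SD/mean, and a relative-frequency histogram over half-open
2-nm bins `[lower, lower+2)` labelled by lower limit. Frequencies sum to
100 % by construction; CV·mean/100 reproduces SD to 1e-9.

**Profiles and contrast.** `edge_profile` samples intensities at 1-px
steps with nearest-pixel lookup; `contrast_range` is max − min along
the profile, the conventional scalar for edge contrast. The SEC trend
(`sec_trend_fit`) is ordinary least squares of mean size on fraction
index with R²; a constant response leaves R² undefined (NaN).

## Unbiased sampling rules

The central evaluation window (default 820 px square, centered with
floor division) keeps an instance when ≥ 50 % of its area lies inside
(the boundary case is kept). The scanning band keeps events wholly
between its two lines or touching the *acceptance* line, and rejects
anything touching the *forbidden* line; the forbidden line wins when
both are touched, the standard unbiased-counting-frame convention. For
convex particles this keeps exactly those whose topmost pixel row lies
in the half-open interval between the lines, so counts per band area
are unbiased density estimates — the property the test suite checks by
Monte Carlo. "Touching a line" means the mask intersects the 1-px line
row. Fields of view are drawn by systematic uniform random sampling: a
regular tiling with one random phase, every k-th tile from a random
start (k = round(1/fraction)).

## Synthetic scenes

The generator emulates mixed-metal MC appearance with a flat bright
background (grey 200), particle interiors slightly darker (182), dark
rims (70 thin-film / 112 thick-film, 1.5 nm thick), antibody blobs
darker still (40), and faint sub-14-nm clutter (168, 4–13 nm discs at
`clutter_density` per µm²). The frame is 2048² px at 0.5 nm/px
(≈ 1 µm²) by default. Rendering is darkest-wins compositing, followed
by Gaussian blur (σ = 1 px) and additive Gaussian noise (SD 6 grey
levels), quantised to 8 bit. Identical parameters (including the seed)
give bit-identical scenes.

Key modelling choices:

* **Sizes.** True en-face diameters are drawn from a normal
  (default mean 23.7 nm, SD 2.0 nm) truncated at ≥ 14 nm, the lower
  limit at which distinct rim-contrasted particles are observed; the
  2.0 nm default spread populates several 2-nm histogram bins, as real
  LDL preparations do.
* **Orientation and film mode.** The projected major/minor ratio is
  drawn from a truncated normal (≥ 1): mean 1.29, SD 0.06 in thin mode;
  mean 1.42, SD 0.12 in thick mode — matching the observed mean ratios,
  with the width a free choice since only means are reported. Projected
  ellipses are oriented with the major axis near-horizontal (angular
  jitter SD 6°) so the horizontal-calliper convention reads the en-face
  diameter and the generator's size truth is directly recoverable; under
  uniform in-plane orientation the expected calliper of a 1.29-ratio
  ellipse is only 0.89 × the major axis, which would build a systematic
  ~2.6 nm deficit into every recovery experiment.
* **Film mode and contrast.** Thin films get darker rims than thick
  films, reproducing the observed ordering of edge contrast between
  preparations; absolute grey levels are free parameters.
* **Labelling.** Each particle is labelled independently with
  probability `labelled_fraction`; a labelled particle receives
  `1 + Poisson(μ − 1)` blobs (mean μ = `blobs_per_labelled`, always
  ≥ 1, so the labelled flag and blob count stay consistent). Blob
  diameters are uniform on `blob_size_range` (default 7–22 nm) and each
  blob is seated on the rim, tangent to the mask ellipse with 1 px
  overlap — antibodies bind the particle periphery, and this keeps
  truth blobs within the 2-px attachment gap used downstream.
* **Aggregates.** A fraction of particles form chains of 2–4 members
  (probabilities 0.55/0.30/0.15) placed tangentially with 1 px overlap
  so masks touch; all other placements respect a 4 nm minimum gap by
  rejection sampling (failure after `max_retries` raises).

What the generator does **not** model: electron-optical effects (CTF,
stain granularity), intensity gradients across the film, collapsed
extracellular-vesicle morphologies, sub-pixel partial-volume rim
profiles, or correlated noise. Passing recovery tests therefore shows
the pipeline is correct under an idealised but geometrically faithful
contrast model, not that it meets the same error bounds on real
micrographs.

## Classical segmenter

`segment_particles` is a deterministic, training-free baseline for
rim-contrasted particles: Gaussian smoothing (σ = 1 px); gradient
voting, where strong-gradient pixels (above the 92nd percentile, with a
floor of 5 % of the maximum so sparse-edge noiseless images still vote)
cast votes along their gradient direction — which at the inner rim edge
points at the particle centre — for every radius in the expected range
(14–80 nm diameters by default); peak detection on the smoothed
accumulator with non-maximum suppression at the minimum expected
radius; Otsu partition of the smoothed image into stain (rims, blobs)
and bright regions; each non-background bright component owning one
peak becomes an instance, and components with several peaks are split
by marker-based watershed on the distance transform. Confidence is the
peak vote normalised by the image's largest peak vote.

Because pre-smoothing turns the rim trench into a shallower, wider
valley, the threshold crossing lands about 1 px inside the true inner
rim edge; a single 4-connected dilation (`edge_recover_px = 1`)
restores the inner-edge convention (residual mean calliper bias
≈ −0.25 nm at default noise). Hard filters discard instances below
`min_area_px2` or with mask-equivalent diameter outside the expected
range — note the equivalent diameter of an elliptical mask is the
geometric mean of its axes, so particles whose major axis sits just
above the lower bound can be rejected; with the default size
distribution this affects < 0.01 % of particles.

`detect_blobs` finds dark compact densities outside the particle masks:
pixels within `exclusion_px` (default 4) of a particle are removed so
rims do not bridge into blob components, and remaining dark components
are kept when their equivalent diameter lies in the antibody size range
widened by the excluded margin (blobs seated on rims lose a sliver to
the exclusion zone). Detected blob masks are clipped by the same zone,
so blob *counts and positions* are reliable while blob *areas* are
slight underestimates.

## Evaluation suite

Matching is greedy in descending IoU (ties: higher prediction score,
then lower index), one-to-one, with pairs below the threshold rejected.
For spatially disjoint instance sets — the practical regime, since a
prediction cannot exceed 0.5 IoU with two disjoint truths — greedy
matching attains the optimal assignment, which the tests verify by
brute force. Detection rate is 100·matched/n_truth; false detections
per 100 use *detections* as denominator (per the text's definition,
even though summary tables often abbreviate the column name). mAP
averages AP over IoU 0.50:0.05:0.95 with score-ordered greedy matching
and all-point (precision-envelope) interpolation; the published phrase
"median average precision" is read as the COCO mean over that grid, and
`reduce="median"` is available. Overlapping pairs are counted after
dilating every mask by 1 px with the 3×3 square element (8-connected),
closing Chebyshev gaps ≤ 2; the count is monotone in the dilation
radius. Bland–Altman reports bias (mean of a−b) and bias ± 1.96·sample
SD.

## Aggregation and labelling statistics

The aggregate census groups particles by transitive "touching"
(minimum Chebyshev pixel distance ≤ `touch_gap_px`; 0 = shared pixel,
1 = 8-adjacent) into events categorised {1, 2, 3, ≥4}. Two censuses are
compared by a 2×4 contingency chi-square (expected counts from
marginals, no continuity correction, df 3); categories with zero
expected count are pooled right-to-left (≥4 into 3, then 3 into 2),
preserving the low-count tail last, with df reduced accordingly.
Redistribution between categories is particle-weighted — a category-k
event contributes k particles, and ≥4 events contribute their recorded
component sizes (or 4 when unrecorded) — since "x % of the particles
redistributing" refers to particles, not events; the event-weighted
variant is a one-line change on the same census. Saturation of
labelling is declared when the longest top-concentration run (≥ 2
points) of labelled fractions spans ≤ 2 percentage points; its mean is
the plateau. Distribution comparisons use tie-corrected Kruskal–Wallis
and pairwise two-sample KS (scipy).

## Numerical and testing choices

* Coordinates are 0-based (row, col); windows half-open; all seeds go
  through `numpy.random.default_rng`.
* The recovery experiments run 20 scenes of 200 particles (end-to-end
  segmentation) and 5 scenes of 200 particles (labelling), sizes chosen
  so the whole suite completes in about a minute while leaving binomial
  noise well inside the asserted bounds.
* The distributional-recovery KS test compares measured callipers with
  generating-distribution draws passed through the same observation
  model (integer column counts at 0.5 nm/px): calliper quantization
  alone contributes a KS distance of ~0.05, which at n = 1000 would sit
  on the α = 0.01 rejection boundary and mask genuine recovery error.
* Instance masks are stored as bounding-box crops internally (memory
  proportional to particle area, not image area); full-frame masks are
  materialised on demand.

## Known limitations

* The segmenter assumes dark-on-bright rim polarity and roughly
  elliptical particles; heavily overlapping (not merely touching)
  particles are split by watershed markers and may lose rim-adjacent
  pixels to their neighbour.
* Blob detection near rims reports clipped masks (see above).
* The printed reference summaries include one internally inconsistent
  triplet (SD 1.27 / CV 2.28 % attached to means whose sample SD is
  0.30 / CV 1.26 %) and a corrected plasma mean printed as 22.3 where
  the stated procedure yields 22.21; the package computes the
  internally consistent values and does not special-case these.
* Micrograph calibration is always user-supplied; TIFF metadata is
  ignored.
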