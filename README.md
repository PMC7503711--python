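# lipograin

Quantitative electron microscopy of plasma lipoproteins, in software:
simulate mixed-metal-stained micrographs with full ground truth, segment
and measure rim-contrasted lipoprotein particles, quantify antibody
labelling and aggregation with unbiased stereological sampling rules, and
score any instance segmentation with a standard metric suite.

## Who this is for

Plasma lipoproteins (LDL, IDL, VLDL, Lp(a), remnants) are nanoparticles
of 14–80 nm whose size distribution and subpopulation composition carry
cardiovascular-risk information. Negative/positive-stain EM with methyl
cellulose (MC) embedding renders each particle as a bright-interior
spheroid with a dark stain rim on a bright background, which makes
per-particle morphometry feasible at scale — manually, with classical
image processing, or with a trained instance-segmentation model. This
package provides the measurement, sampling and evaluation machinery
around that workflow, plus a seeded synthetic-scene generator so every
stage is testable without annotated micrographs.

## The core quantities

* **Horizontal calliper** `d = (max col − min col + 1) · nm/px` over a
  particle mask: the extent along a fixed direction, which is a random
  direction relative to each particle.
* **Spheroid-equivalent diameter.** Flattened particles adsorbed to thin
  films lie *en face*, so calliper measurements report the maximal
  (equatorial) diameter `D`. The orientation-averaged size of the
  corresponding oblate spheroid with axes `(D, D, rD)` is the mean of
  its three axes:

  `D_eq = D · (2 + r) / 3`,  with aspect `r = 12.1 / 21.4` from
  reference LDL cryo-EM axes (21.4 × 12.1 nm) by default.
* **Size summaries**: mean, sample SD (n−1), CV%, and a relative-
  frequency histogram in 2-nm bins labelled by bin lower limit.
* **Labelling**: antibody "blobs" (7–22 nm dark densities) are attached
  to their nearest particle within a pixel gap; percent-labelled,
  saturation plateaus and per-size-bin positivity follow.
* **Aggregation**: events (particles or touching aggregates) are
  counted under a forbidden-/acceptance-line rule and categorised by
  component count {1, 2, 3, ≥4}; censuses are compared by a 2×4
  chi-square (df 3) and by the particle-weighted redistribution between
  small and large categories.
* **Segmentation metrics**: greedy IoU matching, detection rate (% of
  ground truth matched), false detections per 100 detections, mean AP
  over IoU 0.50:0.05:0.95 (COCO convention, with a median option), the
  number of touching/overlapping pairs after 1-px mask dilation, and
  Bland–Altman limits of agreement between paired size estimates.

## Worked example

```python
import lipograin as lg

params = lg.SceneParams(n_particles=200, size_dist=(23.7, 2.0),
                        film_mode="thin", labelled_fraction=0.366, seed=1)
mic, truth = lg.simulate_micrograph(params)

pred = lg.segment_particles(mic)
report = lg.evaluate(pred, truth.instances)
table = lg.measure_instances(pred, mic.nm_per_pixel)
summary = lg.summarize_sizes(table.calliper_h_nm.tolist())
counts, unbound = lg.attach_densities(truth.instances, truth.blobs)

print(f"detected {report.n_pred} of {report.n_truth} particles "
      f"(rate {report.detection_rate:.1f}%, {report.false_per_100:.1f} false/100, "
      f"mAP {report.mAP:.2f})")
print(f"mean calliper {summary.mean:.2f} nm (SD {summary.sd:.2f}, "
      f"CV {summary.cv_percent:.2f}%)")
print(f"spheroid-equivalent diameter "
      f"{lg.spheroid_equivalent_diameter(summary.mean):.2f} nm")
print(f"labelled fraction {lg.labelling_fraction(counts):.1f}%")
```

prints

```
detected 198 of 200 particles (rate 98.5%, 0.5 false/100, mAP 0.97)
mean calliper 23.67 nm (SD 2.10, CV 8.86%)
spheroid-equivalent diameter 20.24 nm
labelled fraction 38.0%
```

The scene was generated with a mean true diameter of 23.7 nm and a
36.6 % labelled fraction: the classical segmenter recovers 198 of the
200 particles with one false detection, the measured mean calliper lands
within 0.05 nm of the generating mean, the orientation correction maps
it to the ~20 nm rotational-average scale, and the per-particle blob
counts recover the labelled fraction up to binomial noise (77 of 200
particles were truly labelled in this draw).

A command-line interface mirrors the library:

```sh
lipograin simulate --seed 1 --out scene/
lipograin segment  --image scene/micrograph.tif --nm-per-pixel 0.5 --out pred.tif
lipograin measure  --masks pred.tif --nm-per-pixel 0.5 --out particles.csv --summary summary.json
lipograin evaluate --pred pred.tif --truth scene/truth_masks.tif --out report.json
```

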