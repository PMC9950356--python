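# tendonmri

Quantitative analysis of superficial digital flexor tendon (SDFT) lesions
in low-field MRI follow-up studies — for veterinary imaging researchers who
need reproducible, scanner-independent lesion measurements, and for anyone
validating ROI-based measurement pipelines against known ground truth.

MRI signal intensity (SI) is unitless and scanner-dependent, so lesion SI
must be standardised against a reference region before examinations can be
compared. The package implements the four standard approaches, with
`SI_lesion` the mean intensity in the lesion ROI and `SI_SDFT` the mean of
the healthy tendon:

```
SDNR = (SI_lesion − SI_SDFT) / SD_background          signal-difference-to-noise ratio
SDNR = (SI_lesion − SI_SDFT) / SD_cortical_bone
relative SI = SI_lesion / SI_background
relative SI = SI_lesion / SI_cortical_bone
```

Around these it provides the full measurement toolbox such a study needs:

* **ROI strategies** — free-hand (mask) whole-lesion ROIs, the largest
  circle inscribed in the lesion (exact Euclidean distance transform), a
  1 mm² circle at the lesion's deepest interior point, and 50 mm² circular
  reference ROIs on cortical bone and in the background lateral, medial
  and palmar to the limb.
* **Lesion geometry** — per-slice cross-sectional area (CSA), CSA at a
  fixed level vs at each examination's own maximum level, lesion volume
  `V = Σ CSA · slice spacing`, and the proximo-distal shift of the maximum
  lesion level over time.
* **Automated segmentation** — a locally adaptive threshold (default
  filter width 30 px) inside the manually drawn SDFT ROI, with robust
  noise-scaled offset and small-component removal.
* **Histology** — blue-pixel percentage of Masson's-trichrome-stained
  sections (collagen-rich repair tissue stains blue) as the severity
  reference standard.
* **Method-comparison statistics** — tie-aware Spearman rank correlation
  (exact permutation p-value for n ≤ 10), Bland–Altman limits of agreement
  on log-transformed data (backtransformed to ratio scale), and percent
  agreement for binary lesion detection.
* **A synthetic phantom generator** with exact ground truth (anatomy,
  lesion time courses, sequence-dependent noise, trichrome-like histology),
  so every stage is testable without clinical data.

## Worked example

```python
import numpy as np
from tendonmri import (ImageGeometry, LesionPhantomParams, generate_stack,
                       place_reference_rois, pool_background, measure_si,
                       largest_inscribed_circle, rasterise_circle,
                       standardise_si, AdaptiveSegParams, automated_measurement)

geometry = ImageGeometry()                      # 171 mm FOV, 256x256, 5+1 mm
params = LesionPhantomParams(severity=0.8, max_csa_mm2=30.0, seed=42)
stack, truth = generate_stack(params, geometry)

level = int(np.argmax(truth.true_csa_per_level))  # peak lesion slice
sl = stack.slices[level]
lesion = truth.lesion_masks[level]
print(f"peak lesion level: {level}, true CSA {truth.true_csa_per_level[level]:.1f} mm^2")

refs = place_reference_rois(sl, truth.bone_roi_centre_mm, truth.limb_mask, geometry)
background = pool_background([measure_si(sl, r) for r in refs[1:]])
rel = standardise_si(measure_si(sl, lesion), None, background, "REL_background")
print(f"relative SI (lesion / background): {rel.value:.2f}")

circle = largest_inscribed_circle(lesion, geometry)
print(f"largest inscribed circle: radius {circle.radius_mm:.2f} mm, "
      f"{rasterise_circle(circle, geometry, clip_to=lesion).n_pixels} pixels")

record = automated_measurement(sl, truth.sdft_masks[level],
                               AdaptiveSegParams(), geometry)
print(f"automated lesion CSA: {record.csa_mm2:.1f} mm^2 "
      f"(manual {lesion.area_mm2(geometry):.1f} mm^2)")
```

prints

```
peak lesion level: 6, true CSA 30.3 mm^2
relative SI (lesion / background): 6.43
largest inscribed circle: radius 2.07 mm, 29 pixels
automated lesion CSA: 29.4 mm^2 (manual 30.3 mm^2)
```

The severity-0.8 phantom lesion is hyperintense (relative SI ≈ 6.4 against
a background mean of ~20), the inscribed circle covers the lesion core, and
the automated mask recovers the manual CSA to within one pixel row — the
rim pixels with the lowest contrast fall below the local threshold, which
is why automated CSA sits slightly below manual CSA.

A command-line interface mirrors the library:
`tendonmri synth|histology|segment|standardise|roi-compare|csa-study|automation-study|all`
(see `tendonmri --help`).

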