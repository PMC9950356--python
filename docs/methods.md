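# Methods

This note documents the conventions, defaults and design choices behind
`tendonmri`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## Coordinate and measurement conventions

Pixels are indexed 0-based as (row, column) with row 0 at the image top;
a pixel's physical position is its centre, `((row+0.5)·s, (col+0.5)·s)`
with `s = field_of_view / matrix_size` (0.668 mm for the default 171 mm /
256 protocol). Slice `level_index` sits at `level_index × (thickness +
gap)` along the tendon; proximal means smaller index, and a shift of the
maximum-lesion level toward proximal is reported as a positive distance.
ROI statistics use the population SD (divide by n), the convention of
image-viewer ROI readouts. Raw intensities are used as-is: no window/level
or vendor rescaling is applied, because making values comparable is
precisely the job of the standardisation formulas.

## SI standardisation

Four formulas: SDNR against background or cortical-bone SD, and relative
SI against background or cortical-bone mean. All four are invariant to
multiplying the image by a positive constant, which is what makes them
scanner-comparable. The background reference combines the three 50 mm²
background ROIs as the unweighted mean of their means (for relative SI)
and as the SD of their pooled pixels (for SDNR); a single-ROI reference
can be passed instead. The healthy-tendon term is measured on the SDFT
mask with lesion pixels excluded, so the numerator contrasts lesion
against genuinely healthy tendon.

## Circular ROIs

A circle contains a pixel when the pixel centre lies within the radius
(boundary inclusive), and the pixel containing the circle centre is always
included, so a vanishing circle still yields one pixel. At the default
spacing this rasterisation reproduces target areas within 10% for areas of
5 mm² and up (0.06% at 50 mm²). A 1 mm² target is below the resolution at
which that tolerance is meaningful: areas are quantised in steps of one
pixel ≈ 0.45 mm², so the best achievable count (2 pixels, 0.89 mm²) is
~11% off; the minimal-mask guarantee is what holds there.

The largest inscribed circle is centred on the lesion pixel maximising the
exact Euclidean distance to the mask complement (image border counts as
complement); the radius is that distance minus half a pixel, which makes
the rasterised circle a strict subset of the lesion. Ties are broken
toward the smallest (row, column). The 1 mm² central ROI is placed at the
same distance-transform maximum — the deepest interior point — rather than
the centroid, which for crescent-shaped lesions can fall outside the
lesion; its rasterisation is clipped to the lesion mask.

## Lesion geometry

Volume is `Σ CSA × slice spacing` with spacing = thickness + gap (6 mm by
default): the 1 mm gap is unsampled tissue that each slice represents.
A thickness-only multiplier is available (`spacing_mm=5.0`) for users who
prefer the conservative rule. The maximum-CSA level resolves ties toward
proximal. An examination with no lesion yields a summary row of zeros
with the level shift flagged undefined (None), keeping time-series tables
rectangular rather than dropping rows.

## Automated segmentation

Within the manually drawn SDFT ROI, a pixel is lesion if it exceeds the
mean of its filter_width × filter_width neighbourhood (default 30 px ≈
20 mm) by more than an offset. The local mean is computed over SDFT
pixels only, so bright structures outside the tendon cannot raise the
local baseline. Connected components smaller than `min_lesion_px`
(default 5, 8-connectivity) are removed and the largest surviving
component is kept (multi-lesion mode keeps all); detection is positive
when the surviving count reaches `min_lesion_px`.

The default offset is `3.0 ×` a robust noise scale — the median absolute
deviation of the SDFT ROI intensities times 1.4826 (the MAD→SD factor for
Gaussian noise). A plain-SD fraction was considered and rejected: on
lesion-free slices the ROI SD equals the noise SD, so a small fraction of
it admits roughly half the noise pixels (mass false positives), while on
lesion-bearing slices the lesion itself inflates the SD and thus its own
detection threshold. The MAD is insensitive to the (minority) lesion
pixels and gives a threshold ~3σ above the local mean: false positives
are rare at any noise level, and sensitivity degrades gracefully as noise
grows — which is exactly the sequence-quality behaviour the automation
study measures. Offsets as a fraction of the plain SD (`offset_mode="sd"`)
and in absolute intensity units (`"absolute"`) remain available. Because
thresholding is relative to a local mean, all modes are invariant to
adding a constant to the image; the relative modes are additionally
invariant to rescaling, the absolute mode is not.

## Histology quantification

The red and blue channels are extracted; a pixel is background when both
channels are ≥ 0.9 × channel-max (unstained white) or ≤ 0.05 ×
channel-max (black), otherwise blue- or red-stained when one channel
dominates the other by ≥ 0.05 × channel-max, with ambiguous pixels
assigned to the larger channel and exact ties to red. The blue percentage
divides by stained tissue pixels (blue ∪ red) by default so that the
arbitrary slide background area cannot dilute the severity score; a
whole-image denominator is available via `denominator="all"` since the
original measure's denominator convention is a judgment call.

## Statistics

Spearman's r is the Pearson correlation of mid-ranks, correct under ties
(the classical 1 − 6Σd²/(n(n²−1)) shortcut is biased with ties). The
two-sided p-value enumerates all n! permutations exactly for n ≤ 10 and
uses the t-approximation with n − 2 df above. Bland–Altman limits of
agreement are computed on natural-log-transformed data — d = ln a − ln b,
mean ± 1.96 SD (sample SD) — and backtransformed through exp, yielding the
geometric mean ratio and ratio-scale limits; the method-swap reciprocity
(swapping a and b inverts the ratio and swaps/inverts the limits) is exact.
Percent agreement is the share of images with the same present/absent
call. Significance is read at p < 0.05.

## The phantom generator

Each slice paints, onto N(20, σ) background noise, a 30 mm-radius
soft-tissue limb disc (SI 80), a cortical-bone annulus (outer 15 mm /
inner 6.5 mm, SI 10) around marrow (SI 85), and a palmar SDFT ellipse
(5.5 × 9 mm semi-axes, SI 60). Lesion-bearing levels add an ellipse inside
the SDFT whose mean SI is `SDFT SI × (1 + k·severity)` with contrast
factor k = 1.5, and whose intensity falls off radially from the core
(profile `1 − 0.5·e²` in normalised elliptical radius, normalised so the
mean hits the target) — freshly injured core lesions read brighter in the
centre than at the rim, which is what makes the small-central-ROI vs
whole-lesion comparison non-trivial. Per-level CSA follows a parabola
peaking at `max_level_index`; time courses shrink the peak geometrically
per examination and drift the peak level, emulating healing follow-ups.
Ground-truth masks are the exact painted pixel sets, so mask-derived CSA,
volume and truth-mask SI carry no tolerance.

Noise defaults: σ = 8 on the T1w GRE reference (contrast-to-noise ≈ 9 for
a severity-1 lesion), with sequence multipliers 1.0 / 1.25 / 3.0 / 3.0 for
T1w GRE / T2*w GRE / T2w FSE / STIR — a reduced model of the longer, more
motion-prone FSE/STIR acquisitions of low-field systems. These are
calibration choices, exposed as parameters; no physics is simulated.

Trichrome-like histology paints an elliptical tissue region in a white
margin; blue-dominant pixels are clustered (thresholded Gaussian random
field) and their count is chosen to hit the requested blue fraction
exactly up to integer rounding (±0.5 percentage points at worst); the
realised fraction is returned as ground truth.

**What the phantoms do not show.** They contain no anatomical variation,
partial-volume rim, bias field, motion ghosting or stain variability, and
lesions are single, elliptical and SDFT-centred. Passing the synthetic
studies therefore demonstrates correctness of the measurement and
comparison machinery under known conditions — not clinical performance of
the segmentation or of any particular threshold on real images.

## Study cohort sizes

The default cohorts are sized like a small longitudinal animal study:
23 paired MRI–histology samples, 60 single-lesion images for the ROI
comparison, 6 subjects × 10 examinations for the CSA/volume study, and
8 subjects × 12 slices per sequence (384 images) for the automation study.
The histology coupling (blue fraction = 0.15 + 0.7·severity + N(0, 0.05),
clipped to [0, 1]) is a generator parameter, including its direction; the
rank-correlation analyses assume nothing about it.

## Known limitations

DICOM reading is minimal (InstanceNumber ordering, no spatial-metadata
validation against the declared geometry). Reference-ROI placement walks
straight rays from the limb centroid and can fail (with a geometry error)
for exotic limb shapes. Examination indices are capped at 10, matching the
follow-up design the package targets. The exact permutation p-value is
enumerated, so n = 10 takes a couple of seconds; larger n switches to the
t-approximation automatically.
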