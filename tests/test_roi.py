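"""Circle ROIs, inscribed circles, SI measurement and the four
standardisation formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tendonmri import (
    GeometryError,
    ImageGeometry,
    ImageSlice,
    InputError,
    LesionPhantomParams,
    RoiMask,
    SiMeasurement,
    UndefinedResultError,
    central_small_roi,
    generate_stack,
    largest_inscribed_circle,
    make_circle_roi,
    measure_si,
    place_reference_rois,
    pool_background,
    rasterise_circle,
    standardise_si,
)

CENTRE = (80.3, 76.2)  # generic off-grid point well inside the FOV


def brute_force_inscribed_circle(mask: np.ndarray, step: float = 0.05):
    """Exhaustive search oracle: every mask pixel centre as candidate centre,
    radius grown in ``step``-pixel increments while the circle still fits.

    A circle of radius r at centre c fits when no complement pixel centre
    (image border included) lies within r + 0.5, i.e. the rasterised circle
    cannot contain a complement pixel.  Ties go to the first centre in scan
    order (smallest row, then column).
    """
    padded = np.pad(mask, 1, constant_values=False)
    comp = np.argwhere(~padded).astype(float) - 1.0
    best_r, best_c = -1.0, None
    radii = np.arange(0.0, max(mask.shape) + 1, step)
    for r0, c0 in np.argwhere(mask):
        d = np.sqrt(((comp[:, 0] - r0) ** 2 + (comp[:, 1] - c0) ** 2)).min()
        fits = radii[radii + 0.5 <= d + 1e-9]
        r = float(fits[-1]) if fits.size else 0.0
        if r > best_r + 1e-12:
            best_r, best_c = r, (int(r0), int(c0))
    return best_r, best_c


class TestMakeCircleRoi:
    def test_fifty_mm2_pixel_count(self, geometry):
        roi = make_circle_roi(CENTRE, 50.0, geometry)
        expected = 50.0 / geometry.pixel_area_mm2  # ≈ 112.06 pixels
        assert abs(roi.n_pixels - expected) / expected < 0.10

    def test_one_mm2_contains_centre_pixel(self, geometry):
        roi = make_circle_roi(CENTRE, 1.0, geometry)
        assert roi.n_pixels >= 1
        s = geometry.pixel_spacing_mm
        assert roi.mask[int(CENTRE[0] / s), int(CENTRE[1] / s)]

    def test_vanishing_area_gives_exactly_centre_pixel(self, geometry):
        roi = make_circle_roi(CENTRE, 1e-9, geometry)
        assert roi.n_pixels == 1

    def test_rasterisation_matches_exhaustive_containment_count(self, geometry):
        """Independent oracle: count pixel centres inside the radius by a
        plain double loop."""
        area = 50.0
        radius = math.sqrt(area / math.pi)
        s = geometry.pixel_spacing_mm
        count = 0
        for row in range(geometry.matrix_size):
            for col in range(geometry.matrix_size):
                pr, pc = (row + 0.5) * s, (col + 0.5) * s
                if (pr - CENTRE[0]) ** 2 + (pc - CENTRE[1]) ** 2 <= radius ** 2:
                    count += 1
        assert make_circle_roi(CENTRE, area, geometry).n_pixels == count

    def test_area_error_shrinks_with_target_area(self, geometry):
        """Relative area error is non-increasing over growing target areas
        and below 10% once the circle spans several pixels.  At 1 mm² the
        pixel grid quantises areas in steps of ~0.45 mm², so only the
        minimal-mask guarantee applies."""
        errors = {}
        for area in (1.0, 5.0, 10.0, 50.0):
            roi = make_circle_roi(CENTRE, area, geometry)
            errors[area] = abs(roi.area_mm2(geometry) - area) / area
        assert errors[5.0] < 0.10 and errors[10.0] < 0.10 and errors[50.0] < 0.10
        values = [errors[a] for a in (1.0, 5.0, 10.0, 50.0)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_circle_beyond_image_bounds_rejected(self, geometry):
        with pytest.raises(GeometryError):
            make_circle_roi((2.0, 85.5), 50.0, geometry)


class TestMeasureSi:
    def test_constant_field(self, geometry):
        img = np.full((8, 8), 7.0)
        roi = RoiMask(np.ones((8, 8), dtype=bool), role="sdft")
        m = measure_si(img, roi)
        assert m.mean_si == 7.0 and m.sd_si == 0.0 and m.n_pixels == 64

    def test_two_pixel_population_sd(self):
        img = np.array([[1.0, 3.0]])
        roi = RoiMask(np.ones((1, 2), dtype=bool), role="sdft")
        m = measure_si(img, roi)
        assert m.mean_si == 2.0 and m.sd_si == 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(InputError):
            measure_si(np.ones((4, 4)), RoiMask(np.zeros((4, 4), bool), role="sdft"))

    def test_background_roi_statistics_on_phantom(self, geometry):
        """On pure N(20, 4) background noise, a 50 mm² ROI's sample SD must
        fall in the chi-square band [3.2, 4.8] and its mean within
        3·SD/sqrt(n) of 20."""
        params = LesionPhantomParams(severity=0.5, noise_sd=4.0, seed=7)
        stack, truth = generate_stack(params, geometry)
        sl = stack.slices[6]
        rois = place_reference_rois(sl, truth.bone_roi_centre_mm,
                                    truth.limb_mask, geometry)
        for roi in rois[1:]:
            m = measure_si(sl, roi)
            assert 3.2 <= m.sd_si <= 4.8
            assert abs(m.mean_si - 20.0) <= 3 * 4.0 / math.sqrt(m.n_pixels)


class TestInscribedCircle:
    def _circle_px(self, circle, geometry):
        s = geometry.pixel_spacing_mm
        return (circle.centre_mm[0] / s - 0.5, circle.centre_mm[1] / s - 0.5,
                circle.radius_mm / s)

    def test_solid_square_matches_oracle(self, geometry):
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:12, 3:12] = True  # 9×9 square
        circle = largest_inscribed_circle(RoiMask(mask), geometry)
        row, col, r = self._circle_px(circle, geometry)
        oracle_r, oracle_c = brute_force_inscribed_circle(mask)
        assert (round(row), round(col)) == oracle_c == (7, 7)
        assert oracle_r <= r + 1e-9 < oracle_r + 0.05

    def test_single_pixel_lesion(self, geometry):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        circle = largest_inscribed_circle(RoiMask(mask), geometry)
        assert circle.radius_mm == pytest.approx(0.5 * geometry.pixel_spacing_mm)

    def test_l_shape_circle_in_thick_arm(self, geometry):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:18, 2:6] = True    # thin arm, 4 wide
        mask[10:18, 2:16] = True  # thick arm, 8 tall
        circle = largest_inscribed_circle(RoiMask(mask), geometry)
        row, col, r = self._circle_px(circle, geometry)
        oracle_r, oracle_c = brute_force_inscribed_circle(mask)
        assert oracle_r <= r + 1e-9 < oracle_r + 0.05
        assert 10 <= round(row) < 18  # inside the thick arm
        raster = rasterise_circle(circle, geometry)
        assert not np.any(raster.mask[: mask.shape[0], : mask.shape[1]] & ~mask)

    def test_random_masks_match_oracle(self, geometry, rng):
        """Distance-transform implementation vs exhaustive centre/radius
        search on random blobs (the full 200-mask sweep runs in the
        acceptance suite)."""
        from scipy import ndimage

        checked = 0
        while checked < 40:
            blob = ndimage.binary_dilation(
                rng.random((32, 32)) > 0.92, iterations=2
            )
            if not blob.any():
                continue
            circle = largest_inscribed_circle(RoiMask(blob), geometry)
            _, _, r = self._circle_px(circle, geometry)
            oracle_r, oracle_c = brute_force_inscribed_circle(blob)
            assert oracle_r <= r + 1e-9 < oracle_r + 0.05
            # the returned centre attains the global maximum depth
            d = ndimage.distance_transform_edt(
                np.pad(blob, 1, constant_values=False))[1:-1, 1:-1]
            s = geometry.pixel_spacing_mm
            crow = round(circle.centre_mm[0] / s - 0.5)
            ccol = round(circle.centre_mm[1] / s - 0.5)
            assert d[crow, ccol] == d.max()
            checked += 1

    def test_empty_mask_rejected(self, geometry):
        with pytest.raises(InputError):
            largest_inscribed_circle(RoiMask(np.zeros((4, 4), bool)), geometry)


class TestCentralSmallRoi:
    def test_disc_centre_recovered(self, geometry):
        s = geometry.pixel_spacing_mm
        mask = make_circle_roi((50.0, 50.0), 40.0, geometry).mask
        circle = central_small_roi(RoiMask(mask), geometry)
        assert circle.centre_mm[0] == pytest.approx(50.0, abs=s)
        assert circle.centre_mm[1] == pytest.approx(50.0, abs=s)

    def test_crescent_centre_stays_inside_lesion(self, geometry):
        """For a crescent the centroid falls in the concavity; the
        distance-transform argmax must still be a lesion pixel."""
        outer = make_circle_roi((50.0, 50.0), 60.0, geometry).mask
        inner = make_circle_roi((50.0, 51.0), 55.0, geometry).mask
        crescent = outer & ~inner
        s = geometry.pixel_spacing_mm
        rows, cols = np.nonzero(crescent)
        centroid = (int((rows.mean())), int(round(cols.mean())))
        assert not crescent[centroid]  # centroid lies outside the crescent
        circle = central_small_roi(RoiMask(crescent), geometry)
        px = (int(circle.centre_mm[0] / s), int(circle.centre_mm[1] / s))
        assert crescent[px]

    def test_single_pixel_lesion_is_its_own_roi(self, geometry):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 5] = True
        circle = central_small_roi(RoiMask(mask), geometry)
        raster = rasterise_circle(circle, geometry, clip_to=RoiMask(mask))
        assert raster.n_pixels == 1 and raster.mask[2, 5]


class TestReferenceRois:
    def test_background_rois_clear_the_limb(self, geometry, lesion_stack):
        stack, truth = lesion_stack
        sl = stack.slices[6]
        rois = place_reference_rois(sl, truth.bone_roi_centre_mm,
                                    truth.limb_mask, geometry)
        roles = [r.role for r in rois]
        assert roles == ["cortical_bone", "background_lateral",
                         "background_medial", "background_palmar"]
        for roi in rois[1:]:
            assert not np.any(roi.mask & truth.limb_mask.mask)

    def test_limb_filling_frame_is_infeasible(self, geometry):
        sl = ImageSlice(np.zeros((256, 256)), level_index=0)
        full = RoiMask(np.ones((256, 256), dtype=bool), role="sdft")
        with pytest.raises(GeometryError):
            place_reference_rois(sl, (85.5, 85.5), full, geometry)


def _m(mean, sd=1.0, n=10, role="lesion_whole"):
    return SiMeasurement(mean_si=mean, sd_si=sd, n_pixels=n, role=role)


class TestStandardiseSi:
    def test_zero_numerator_gives_zero_sdnr(self):
        for fid in ("SDNR_background", "SDNR_cortical"):
            v = standardise_si(_m(90.0), _m(90.0), _m(30.0, sd=12.0), fid)
            assert v.value == 0.0

    def test_identity_quotient_gives_one(self):
        v = standardise_si(_m(30.0), None, _m(30.0), "REL_background")
        assert v.value == 1.0

    def test_worked_arithmetic(self):
        sdnr = standardise_si(_m(240.0), _m(90.0), _m(30.0, sd=12.0),
                              "SDNR_background")
        assert sdnr.value == 12.5
        rel = standardise_si(_m(240.0), None, _m(30.0), "REL_background")
        assert rel.value == 8.0

    def test_zero_denominator_named_in_error(self):
        with pytest.raises(UndefinedResultError, match="SDNR_cortical"):
            standardise_si(_m(240.0), _m(90.0), _m(30.0, sd=0.0), "SDNR_cortical")
        with pytest.raises(UndefinedResultError, match="REL_cortical"):
            standardise_si(_m(240.0), None, _m(0.0), "REL_cortical")

    @settings(deadline=None, max_examples=50)
    @given(
        c=st.floats(min_value=0.01, max_value=100.0),
        lesion=st.floats(min_value=1.0, max_value=500.0),
        sdft=st.floats(min_value=1.0, max_value=500.0),
        ref_mean=st.floats(min_value=1.0, max_value=500.0),
        ref_sd=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_scale_invariance(self, c, lesion, sdft, ref_mean, ref_sd):
        """Multiplying the whole image by c > 0 scales every SI and SD by c
        and leaves all four standardised values unchanged."""
        for fid in ("SDNR_background", "REL_cortical"):
            base = standardise_si(_m(lesion), _m(sdft), _m(ref_mean, sd=ref_sd), fid)
            scaled = standardise_si(
                _m(c * lesion), _m(c * sdft), _m(c * ref_mean, sd=c * ref_sd), fid
            )
            assert scaled.value == pytest.approx(base.value, rel=1e-12)


class TestPoolBackground:
    def test_pooled_sd_matches_union_of_pixels(self, rng):
        groups = [rng.normal(20, 4, size=50), rng.normal(22, 3, size=70),
                  rng.normal(18, 5, size=60)]
        ms = [
            _m(float(g.mean()), sd=float(g.std(ddof=0)), n=len(g),
               role="background_lateral")
            for g in groups
        ]
        pooled = pool_background(ms)
        union = np.concatenate(groups)
        assert pooled.sd_si == pytest.approx(union.std(ddof=0), rel=1e-12)
        assert pooled.mean_si == pytest.approx(
            np.mean([g.mean() for g in groups]), rel=1e-12)
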