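import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from softlabeler.errors import (DegenerateMaskError, DimensionError,
                                InvalidParameterError)
from softlabeler.softlabel import (EXTERIOR, INTERIOR, ON_CONTOUR, REMAPPED,
                                   RegionRelation, classify_superpixels,
                                   distance_to_boundary, extract_boundary,
                                   generate_soft_label, membership_value)
from softlabeler.superpixel import SlicParams, slic_segment
from softlabeler.synthetic import SynthConfig, generate_pair

from conftest import random_blob_mask


def brute_force_distance(mask):
    """O(pixels x boundary) nearest-contour distance, the independent oracle."""
    pts = extract_boundary(mask).points.astype(float)
    h, w = mask.shape
    rr, cc = np.mgrid[0:h, 0:w]
    d = np.full((h, w), np.inf)
    for (br, bc) in pts:
        d = np.minimum(d, np.hypot(rr - br, cc - bc))
    return d


class TestExtractBoundary:
    def test_empty_for_constant_masks(self):
        assert len(extract_boundary(np.zeros((8, 8), dtype=np.uint8))) == 0
        assert len(extract_boundary(np.ones((8, 8), dtype=np.uint8))) == 0

    def test_isolated_pixel_is_its_own_contour(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[3, 3] = 1
        pts = extract_boundary(mask).points
        assert pts.tolist() == [[3, 3]]

    def test_solid_square_perimeter(self):
        """A 4x4 solid square has exactly its 12 perimeter pixels on the
        contour (enumerated 4-neighbour oracle)."""
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 1
        got = set(map(tuple, extract_boundary(mask).points))
        expect = {(r, c) for r in range(2, 6) for c in range(2, 6)
                  if r in (2, 5) or c in (2, 5)}
        assert got == expect
        assert len(expect) == 12


class TestDistanceField:
    def test_zero_on_contour_positive_elsewhere(self, disk_mask_32):
        field = distance_to_boundary(disk_mask_32)
        on = field.inside == ON_CONTOUR
        assert (field.d[on] == 0).all()
        assert (field.d[~on] > 0).all()

    def test_adjacent_background_distance_one(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[3:5, 3:5] = 1
        field = distance_to_boundary(mask)
        assert field.d[3, 2] == 1.0
        assert field.inside[3, 2] == EXTERIOR

    def test_center_of_9x9_square(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[3:12, 3:12] = 1
        field = distance_to_boundary(mask)
        assert field.d[7, 7] == pytest.approx(4.0)
        assert field.inside[7, 7] == INTERIOR

    def test_matches_brute_force_oracle(self, rng):
        """Exact EDT equals the exhaustive boundary-point minimum on random
        masks up to 32x32."""
        for _ in range(10):
            mask = random_blob_mask((rng.integers(8, 33), rng.integers(8, 33)), rng)
            field = distance_to_boundary(mask)
            assert np.allclose(field.d, brute_force_distance(mask), atol=1e-9)

    def test_degenerate_mask_raises(self):
        with pytest.raises(DegenerateMaskError):
            distance_to_boundary(np.zeros((5, 5), dtype=np.uint8))


class TestMembership:
    @pytest.mark.parametrize("d,flag,expect", [
        (0.0, ON_CONTOUR, 0.5),
        (1.0, INTERIOR, 0.75),
        (1.0, EXTERIOR, 0.25),
        (3.0, EXTERIOR, 0.125),
    ])
    def test_mapping_values(self, d, flag, expect):
        assert membership_value(d, flag) == pytest.approx(expect, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(InvalidParameterError):
            membership_value(-0.1, INTERIOR)

    @given(d=st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_ranges_and_symmetry(self, d):
        """Interior values live in [0.5, 1), exterior in (0, 0.5], and the
        two branches mirror around 0.5."""
        inside = membership_value(d, INTERIOR)
        outside = membership_value(d, EXTERIOR)
        assert 0.5 <= inside < 1.0
        assert 0.0 < outside <= 0.5
        assert inside + outside == pytest.approx(1.0, abs=1e-12)
        if d > 1e-9:  # below ~1e-16 the float mapping saturates at 0.5
            assert inside > 0.5 > outside

    @given(st.tuples(st.floats(0, 1e3), st.floats(0, 1e3)))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_distance(self, pair):
        d1, d2 = sorted(pair)
        assert membership_value(d1, INTERIOR) <= membership_value(d2, INTERIOR)
        assert membership_value(d1, EXTERIOR) >= membership_value(d2, EXTERIOR)


class TestClassify:
    def test_three_cases_on_blob(self, small_fixture, small_params):
        img, mask = small_fixture
        spmap = slic_segment(img, small_params)
        rel = classify_superpixels(spmap, mask)
        assert set(np.unique(rel)) == {RegionRelation.OUTSIDE,
                                       RegionRelation.INSIDE,
                                       RegionRelation.INTERSECTING}
        # inside regions are pure lesion, outside pure background
        for r in range(spmap.n_regions):
            vals = mask[spmap.labels == r]
            if rel[r] == RegionRelation.INSIDE:
                assert vals.all()
            elif rel[r] == RegionRelation.OUTSIDE:
                assert not vals.any()

    def test_mixed_region_is_intersecting(self):
        from softlabeler.superpixel import SuperpixelMap
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[:, 2:] = 1
        spmap = SuperpixelMap(labels, 2, 2.0)
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[:, :1] = 1  # region 0 holds the whole lesion and background
        rel = classify_superpixels(spmap, mask)
        assert rel[0] == RegionRelation.INTERSECTING
        assert rel[1] == RegionRelation.OUTSIDE

    def test_shape_mismatch(self, small_fixture, small_params):
        img, _ = small_fixture
        spmap = slic_segment(img, small_params)
        with pytest.raises(DimensionError):
            classify_superpixels(spmap, np.zeros((4, 4), dtype=np.uint8))


class TestGenerateSoftLabel:
    def test_composed_oracles_on_disk(self, disk_mask_32):
        """16 superpixels on a centered disk: remapped pixels only in
        contour-touching regions, every contour pixel exactly 0.5."""
        img = np.dstack([disk_mask_32 * 200] * 3).astype(np.uint8)
        sl = generate_soft_label(img, disk_mask_32, SlicParams(n_segments=16))
        contour = extract_boundary(disk_mask_32).points
        assert (sl.p[tuple(contour.T)] == 0.5).all()
        assert (sl.provenance[tuple(contour.T)] == REMAPPED).all()
        # kept-hard pixels carry exactly their hard values
        kept = sl.provenance == 0
        assert np.array_equal(sl.p[kept], disk_mask_32[kept].astype(float))

    def test_roundtrip_and_ordering(self, small_fixture, small_params):
        img, mask = small_fixture
        sl = generate_soft_label(img, mask, small_params)
        assert np.array_equal(sl.threshold(), mask)
        remapped = sl.provenance == REMAPPED
        ext = remapped & (mask == 0)
        interior = remapped & (mask == 1) & (sl.p != 0.5)
        assert sl.p[ext].max() < 0.5
        assert sl.p[interior].min() > 0.5
        assert sl.p.min() >= 0 and sl.p.max() <= 1

    def test_monotone_along_interior_ray(self, disk_mask_32):
        """Membership grows with contour distance moving inward."""
        img = np.dstack([disk_mask_32 * 200] * 3).astype(np.uint8)
        sl = generate_soft_label(img, disk_mask_32, SlicParams(n_segments=4))
        row = sl.p[15, :]
        lesion_cols = np.where(disk_mask_32[15] == 1)[0]
        left = row[lesion_cols[0]:16]  # contour toward center
        assert (np.diff(left) >= 0).all()

    def test_remapped_count_decreases_with_n_segments(self):
        """More superpixels -> smaller blocks -> fewer contour-intersecting
        pixels (the N_Segment trade-off at the working size)."""
        img, mask = generate_pair(SynthConfig(seed=9))
        counts = []
        for n in (500, 1000, 1500):
            sl = generate_soft_label(img, mask, SlicParams(n_segments=n))
            counts.append(int((sl.provenance == REMAPPED).sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_degenerate_and_mismatched_inputs(self, small_fixture, small_params):
        img, _ = small_fixture
        with pytest.raises(DegenerateMaskError):
            generate_soft_label(img, np.zeros(img.shape[:2], dtype=np.uint8),
                                small_params)
        with pytest.raises(DimensionError):
            generate_soft_label(img, np.ones((4, 4), dtype=np.uint8),
                                small_params)
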