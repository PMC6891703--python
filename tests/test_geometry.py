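import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigmount.geometry_features import (
    bbox_centre,
    build_eigenvector,
    feature_layout,
    frames_to_feature_table,
    half_body_areas,
    mask_perimeter,
    pairwise_centre_distances,
    read_feature_csv,
    write_feature_csv,
)
from pigmount.segmentation_io import BoundingBox, FrameRecord, InstanceMask, PigInstance

from conftest import random_blob_mask


def rect_mask(h, w, r0, c0, rh, rw):
    g = np.zeros((h, w), dtype=bool)
    g[r0 : r0 + rh, c0 : c0 + rw] = True
    return InstanceMask(g)


class TestPerimeter:
    def test_rectangle_close_to_geometric_perimeter(self):
        m = rect_mask(40, 40, 5, 5, 20, 10)  # 10 wide x 20 tall
        assert mask_perimeter(m) == pytest.approx(60, abs=2)

    def test_additive_over_disjoint_components(self):
        both = np.zeros((30, 30), dtype=bool)
        both[2:7, 2:7] = True
        both[20:25, 20:25] = True
        single = rect_mask(30, 30, 2, 2, 5, 5)
        total = mask_perimeter(InstanceMask(both))
        assert total == pytest.approx(2 * mask_perimeter(single), rel=1e-9)
        assert total == pytest.approx(40, abs=4)

    def test_disk_matches_circumference_and_chain_code_oracle(self):
        # the marching-squares staircase overestimates smooth curves by a
        # few percent (it cannot cut corners shallower than 45 degrees), so
        # the disk check carries the convention's measured discretization
        # bias on top of the ideal circumference
        r = 8
        yy, xx = np.mgrid[0:40, 0:40]
        disk = InstanceMask((xx - 20) ** 2 + (yy - 20) ** 2 <= r**2)
        per = mask_perimeter(disk)
        assert per == pytest.approx(2 * math.pi * r, rel=0.10)
        assert per >= 2 * math.pi * r  # staircase bias never undershoots
        # independent oracle: boundary pixels (4-neighbour background contact)
        # chained by angle around the centre, summed step lengths
        fg = disk.pixels
        boundary = fg & ~(
            np.roll(fg, 1, 0) & np.roll(fg, -1, 0) & np.roll(fg, 1, 1) & np.roll(fg, -1, 1)
        )
        rows, cols = np.nonzero(boundary)
        order = np.argsort(np.arctan2(rows - 20.0, cols - 20.0))
        pts = np.c_[rows[order], cols[order]].astype(float)
        steps = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        chain_len = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        assert per == pytest.approx(chain_len, rel=0.07)

    def test_exceeds_equal_area_disk_perimeter(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            m = random_blob_mask(rng)
            iso = 2 * math.sqrt(math.pi * m.area)  # isoperimetric lower bound
            assert mask_perimeter(m) >= iso * 0.95


class TestHalfBodyAreas:
    def test_full_rectangle_splits_evenly(self):
        m = rect_mask(30, 40, 4, 2, 12, 30)
        hba = half_body_areas(m, m.tight_bbox())
        assert hba.s_small == hba.s_large == m.area // 2
        assert hba.split_axis == "vertical"  # box wider than tall
        assert hba.total == m.area

    def test_odd_length_split_differs_by_one_column(self):
        m = rect_mask(20, 20, 3, 3, 4, 7)  # 7 wide: 3/4 column split
        hba = half_body_areas(m, m.tight_bbox())
        assert (hba.s_small, hba.s_large) == (12, 16)

    def test_mask_in_one_half_gives_degenerate_split(self):
        # mask occupies only the left 25% of a wide bbox
        m = rect_mask(20, 60, 5, 0, 10, 15)
        bbox = BoundingBox(0, 5, 60, 15)
        hba = half_body_areas(m, bbox)
        assert hba.s_small == 0
        assert hba.s_large == m.area

    def test_two_component_mask_halves_equal_component_areas(self):
        g = np.zeros((20, 50), dtype=bool)
        g[5:15, 0:10] = True  # 100 px left of split
        g[5:15, 38:50] = True  # 120 px right of split
        m = InstanceMask(g)
        hba = half_body_areas(m, BoundingBox(0, 5, 50, 15))
        assert (hba.s_small, hba.s_large) == (100, 120)
        assert hba.n_components == 2

    def test_area_conservation_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = random_blob_mask(rng)
            hba = half_body_areas(m, m.tight_bbox())
            assert hba.s_small + hba.s_large == m.area
            assert hba.s_small >= 0

    def test_square_bbox_tie_uses_x_parallel_long_sides(self):
        m = rect_mask(20, 20, 0, 0, 10, 10)
        hba = half_body_areas(m, BoundingBox(0, 0, 10, 10))
        assert hba.split_axis == "vertical"


class TestCentresAndDistances:
    def test_centre_examples(self):
        assert bbox_centre(BoundingBox(0, 0, 10, 10)) == (5, 5)
        assert bbox_centre(BoundingBox(2, 4, 6, 8)) == (4, 6)

    @given(
        st.tuples(
            st.floats(-50, 50), st.floats(-50, 50), st.floats(0.5, 40), st.floats(0.5, 40)
        ),
        st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
    )
    def test_centre_translation_equivariance(self, box, t):
        x0, y0, w, h = box
        b = BoundingBox(x0, y0, x0 + w, y0 + h)
        dx, dy = t
        cx, cy = bbox_centre(b)
        tx, ty = bbox_centre(b.translated(dx, dy))
        assert tx == pytest.approx(cx + dx, abs=1e-9)
        assert ty == pytest.approx(cy + dy, abs=1e-9)

    def test_unit_square_corner_distances(self):
        d = pairwise_centre_distances([(0, 0), (1, 0), (0, 1), (1, 1)])
        assert len(d) == 6
        assert sorted(np.round(d, 12)) == pytest.approx([1, 1, 1, 1, math.sqrt(2), math.sqrt(2)])

    def test_coincident_points_all_zero(self):
        assert np.all(pairwise_centre_distances([(3, 3)] * 4) == 0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        pts = [tuple(p) for p in rng.uniform(0, 100, size=(4, 2))]
        got = pairwise_centre_distances(pts)
        expected = []
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                expected.append(math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1]))
        assert got == pytest.approx(expected)

    def test_triangle_inequality_every_triple(self):
        rng = np.random.default_rng(6)
        pts = [tuple(p) for p in rng.uniform(0, 50, size=(5, 2))]
        d = pairwise_centre_distances(pts)
        pair_index = {p: k for k, p in enumerate(combinations(range(5), 2))}
        for i, j, k in combinations(range(5), 3):
            assert d[pair_index[(i, j)]] <= d[pair_index[(i, k)]] + d[pair_index[(j, k)]] + 1e-9

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            pairwise_centre_distances([(0, 0)])


def _corner_frame(scale=1, size=120):
    """Four rectangles near the canvas corners; every slot value is known."""
    size *= scale
    instances = []
    spots = [(10, 10), (10, 70), (70, 10), (70, 70)]
    for r0, c0 in spots:
        m = rect_mask(size, size, r0 * scale, c0 * scale, 20 * scale, 10 * scale)
        instances.append(PigInstance(mask=m, bbox=m.tight_bbox()))
    return FrameRecord(frame_id="c", image_size=(size, size), instances=instances)


class TestBuildEigenvector:
    def test_dimension_and_layout(self):
        fv = build_eigenvector(_corner_frame())
        assert len(fv.values) == 18
        assert fv.layout == feature_layout(4)
        assert fv.layout[0] == "pig1_perimeter"
        assert fv.layout[-1] == "dist_3_4"

    def test_slots_match_independent_per_part_computation(self):
        frame = _corner_frame()
        fv = build_eigenvector(frame)
        ordered = sorted(frame.instances, key=lambda i: (i.bbox.centre[1], i.bbox.centre[0]))
        for k, inst in enumerate(ordered):
            assert fv.values[3 * k] == pytest.approx(mask_perimeter(inst.mask))
            hba = half_body_areas(inst.mask, inst.bbox)
            assert fv.values[3 * k + 1] == hba.s_small
            assert fv.values[3 * k + 2] == hba.s_large
        d = pairwise_centre_distances([i.bbox.centre for i in ordered])
        assert fv.values[12:] == pytest.approx(d)

    def test_input_order_invariance(self):
        frame = _corner_frame()
        base = build_eigenvector(frame)
        rng = np.random.default_rng(3)
        for _ in range(5):
            perm = list(rng.permutation(4))
            shuffled = FrameRecord(
                frame_id="c",
                image_size=frame.image_size,
                instances=[frame.instances[i] for i in perm],
            )
            assert build_eigenvector(shuffled).values == pytest.approx(base.values)

    def test_missing_pig_padded_with_sentinels(self):
        frame = _corner_frame()
        three = FrameRecord(
            frame_id="c", image_size=frame.image_size, instances=frame.instances[:3]
        )
        fv = build_eigenvector(three, expected_pigs=4)
        assert len(fv.values) == 18
        assert list(fv.values[9:12]) == [0.0, 0.0, 0.0]  # absent pig's own slots
        diag = math.hypot(*frame.image_size)
        # three distances involve the absent pig: the far-away sentinel
        assert sorted(fv.values[12:])[-3:] == pytest.approx([diag] * 3)

    def test_extra_detections_truncated_by_score(self):
        frame = _corner_frame()
        extra = rect_mask(120, 120, 50, 50, 6, 6)
        noisy = FrameRecord(
            frame_id="c",
            image_size=frame.image_size,
            instances=[
                PigInstance(mask=i.mask, bbox=i.bbox, score=0.9) for i in frame.instances
            ]
            + [PigInstance(mask=extra, bbox=extra.tight_bbox(), score=0.1)],
        )
        fv = build_eigenvector(noisy, expected_pigs=4)
        assert fv.values == pytest.approx(build_eigenvector(frame).values)

    def test_zero_instances_is_a_distinct_error(self):
        empty = FrameRecord(frame_id="e", image_size=(50, 50), instances=[])
        with pytest.raises(ValueError, match="no instances"):
            build_eigenvector(empty)

    def test_scale_covariance(self):
        base = build_eigenvector(_corner_frame(scale=1))
        doubled = build_eigenvector(_corner_frame(scale=2))
        for k in range(4):
            assert doubled.values[3 * k] == pytest.approx(2 * base.values[3 * k], rel=0.02)
            assert doubled.values[3 * k + 1] == pytest.approx(4 * base.values[3 * k + 1], rel=0.02)
            assert doubled.values[3 * k + 2] == pytest.approx(4 * base.values[3 * k + 2], rel=0.02)
        assert doubled.values[12:] == pytest.approx(2 * base.values[12:], rel=0.02)

    def test_normalized_features_dimensionless(self):
        fv = build_eigenvector(_corner_frame(), normalize=True)
        assert np.all(fv.values <= math.sqrt(2) + 1e-9)  # diag-relative lengths <= sqrt2
        assert np.all(fv.values >= 0)


class TestFeatureTable:
    def test_roundtrip_csv(self, tmp_path):
        table = frames_to_feature_table([_corner_frame()])
        assert list(table.columns[:2]) == ["frame_id", "label"]
        write_feature_csv(table, tmp_path / "f.csv")
        back = read_feature_csv(tmp_path / "f.csv")
        assert back.shape == table.shape
        np.testing.assert_allclose(
            back.iloc[:, 2:].to_numpy(float), table.iloc[:, 2:].to_numpy(float)
        )
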