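import dataclasses
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupdisc import (
    AdapterConfig,
    GrayscaleMask,
    LabelFormatError,
    PhantomSpec,
    PolygonAnnotation,
    extract_row_extremes,
    generate_phantom,
    mask_to_annotations,
    read_yolo_labels,
    sort_clockwise,
    subsample_boundary,
    write_yolo_labels,
)
from cupdisc.adapter import is_clockwise, signed_area

from oracles import densify_polygon, ellipse_boundary, symmetric_hausdorff


def rectangle_mask(shape, rows, cols, value=128):
    arr = np.full(shape, 255, dtype=np.uint8)
    arr[rows[0]:rows[1] + 1, cols[0]:cols[1] + 1] = value
    return GrayscaleMask(arr)


class TestExtractRowExtremes:
    def test_empty_when_value_absent(self):
        mask = GrayscaleMask(np.full((10, 10), 255, dtype=np.uint8))
        assert extract_row_extremes(mask, 128).points == ()

    def test_rectangle_extremes(self):
        mask = rectangle_mask((10, 10), rows=(2, 4), cols=(3, 6))
        got = set(extract_row_extremes(mask, 128).points)
        assert got == {(3, 2), (6, 2), (3, 3), (6, 3), (3, 4), (6, 4)}

    def test_single_column_gives_one_point_per_row(self):
        mask = rectangle_mask((10, 10), rows=(1, 3), cols=(5, 5))
        pts = extract_row_extremes(mask, 128).points
        assert pts == ((5.0, 1.0), (5.0, 2.0), (5.0, 3.0))

    def test_circle_extremes_near_true_boundary(self):
        # every extracted point must be within 1 px of the analytic circle
        spec = PhantomSpec(100, 100, (50, 50), (30, 30), (50, 50), (10, 10),
                           vessel_noise=False, seed=0)
        _, mask = generate_phantom(spec)
        pts = extract_row_extremes(mask, 128).points
        assert len(pts) > 0
        for x, y in pts:
            r = math.hypot(x + 0.5 - 50, y + 0.5 - 50)
            assert abs(r - 30) <= 1.0

    def test_at_most_two_points_per_row(self, centered_phantom):
        _, mask = centered_phantom
        pts = extract_row_extremes(mask, 128).points
        rows = [y for _, y in pts]
        assert max(rows.count(r) for r in set(rows)) <= 2


class TestSubsampleBoundary:
    def test_row_stride_with_forced_last_row(self):
        mask = rectangle_mask((40, 20), rows=(0, 29), cols=(2, 9))
        pts = extract_row_extremes(mask, 128)
        kept = subsample_boundary(pts, 15)
        assert sorted({int(y) for _, y in kept.points}) == [0, 15, 29]
        assert len(kept.points) == 6

    def test_stride_one_is_identity(self):
        mask = rectangle_mask((40, 20), rows=(3, 17), cols=(2, 9))
        pts = extract_row_extremes(mask, 128)
        assert subsample_boundary(pts, 1) == pts

    def test_single_row_always_retained(self):
        mask = rectangle_mask((10, 10), rows=(4, 4), cols=(1, 8))
        pts = extract_row_extremes(mask, 128)
        assert subsample_boundary(pts, 100).points == pts.points

    def test_stride_counts_occupied_rows(self):
        # occupied rows 10..19: stride 4 keeps occupied-row indices 0,4,8 + last
        mask = rectangle_mask((30, 10), rows=(10, 19), cols=(2, 7))
        pts = extract_row_extremes(mask, 128)
        kept = subsample_boundary(pts, 4)
        assert sorted({int(y) for _, y in kept.points}) == [10, 14, 18, 19]


class TestSortClockwise:
    SQUARE = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]

    def test_all_square_permutations_recover_cyclic_order(self):
        for perm in itertools.permutations(self.SQUARE):
            out = sort_clockwise(perm)
            assert is_clockwise(out)
            # must be a cyclic rotation of the canonical clockwise order
            k = out.index(self.SQUARE[0])
            assert out[k:] + out[:k] == self.SQUARE

    def test_fewer_than_three_distinct_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            sort_clockwise([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="3 distinct"):
            sort_clockwise([(0, 0), (1, 1), (0, 0)])

    def test_idempotent_on_clockwise_convex_polygon(self):
        out1 = sort_clockwise(self.SQUARE)
        assert sort_clockwise(out1) == out1

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 12))
    def test_random_convex_points_pass_shoelace_sign(self, seed, n):
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        radii = rng.uniform(5, 20, n)
        pts = [(50 + r * np.cos(t), 50 + r * np.sin(t)) for r, t in zip(radii, angles)]
        if len(set(pts)) < 3:
            return
        assert signed_area(sort_clockwise(pts)) > 0


class TestMaskToAnnotations:
    def test_all_background_gives_empty_list(self):
        mask = GrayscaleMask(np.full((50, 50), 255, dtype=np.uint8))
        assert mask_to_annotations(mask) == []

    def test_phantom_yields_disc_and_cup(self, centered_phantom):
        _, mask = centered_phantom
        anns = mask_to_annotations(mask)
        assert sorted(a.class_id for a in anns) == [0, 1]
        for ann in anns:
            assert is_clockwise(ann.vertices)
            assert len(ann.vertices) >= 3
            assert not ann.normalized

    def test_vertical_extent_conserved_exactly(self, centered_phantom):
        _, mask = centered_phantom
        anns = mask_to_annotations(mask)
        disc = next(a for a in anns if a.class_id == 0)
        rows = np.flatnonzero((mask.pixels != 255).any(axis=1))
        ys = [y for _, y in disc.vertices]
        assert max(ys) - min(ys) == rows[-1] - rows[0]

    def test_tiny_region_omitted_with_warning(self, caplog):
        arr = np.full((20, 20), 255, dtype=np.uint8)
        arr[5, 5] = 128  # single pixel: one vertex, below min_vertices
        mask = GrayscaleMask(arr)
        with caplog.at_level("WARNING", logger="cupdisc.adapter"):
            anns = mask_to_annotations(mask)
        assert anns == []
        assert any("min_vertices" in rec.message for rec in caplog.records)

    def test_hausdorff_within_stride_of_true_ellipse(self, centered_spec):
        _, mask = generate_phantom(centered_spec)
        anns = mask_to_annotations(mask, AdapterConfig(sampling_stride=15))
        disc = next(a for a in anns if a.class_id == 0)
        truth = ellipse_boundary(centered_spec.disc_center, centered_spec.disc_semi_axes)
        d = symmetric_hausdorff(densify_polygon(disc.vertices), truth)
        assert d <= 15.0


class TestYoloLabelIO:
    def make_annotations(self, rng, n, size=(640, 480)):
        out = []
        for _ in range(n):
            cx, cy = rng.uniform(100, 400, 2)
            radius = rng.uniform(20, 80)
            k = int(rng.integers(3, 30))
            t = np.sort(rng.uniform(0, 2 * np.pi, k))
            verts = tuple(
                (float(np.clip(cx + radius * np.cos(a), 0, size[0])),
                 float(np.clip(cy + radius * np.sin(a), 0, size[1])))
                for a in t
            )
            out.append(PolygonAnnotation(
                class_id=int(rng.integers(0, 2)), vertices=verts,
                normalized=False, image_size=size,
            ))
        return out

    def test_round_trip_within_quantization(self, rng, tmp_path):
        size = (640, 480)
        anns = self.make_annotations(rng, 8, size)
        path = write_yolo_labels(anns, size, tmp_path / "labels.txt")
        back = read_yolo_labels(path, size)
        assert len(back) == len(anns)
        for a, b in zip(anns, back):
            assert a.class_id == b.class_id
            for (x0, y0), (x1, y1) in zip(a.vertices, b.vertices):
                assert abs(x0 - x1) / size[0] <= 5.1e-7
                assert abs(y0 - y1) / size[1] <= 5.1e-7

    def test_known_normalization(self, tmp_path):
        # pixel (817, 408) in a 1634x1634 frame -> 0.500000 0.249694
        ann = PolygonAnnotation(
            class_id=0,
            vertices=((817.0, 408.0), (900.0, 500.0), (800.0, 600.0)),
            normalized=False, image_size=(1634, 1634),
        )
        path = write_yolo_labels([ann], (1634, 1634), tmp_path / "one.txt")
        line = path.read_text().splitlines()[0]
        assert line.startswith("0 0.500000 0.249694")

    def test_odd_coordinate_count_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.6\n")
        with pytest.raises(LabelFormatError, match="line 1"):
            read_yolo_labels(p, (100, 100))

    def test_bad_class_and_out_of_range_coords(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.1 0.1 0.2 0.1 0.2 0.2\n5 0.1 0.1 0.2 0.1 0.2 0.2\n")
        with pytest.raises(LabelFormatError, match="line 2"):
            read_yolo_labels(p, (100, 100))
        p.write_text("1 0.1 0.1 1.2 0.1 0.2 0.2\n")
        with pytest.raises(LabelFormatError, match=r"outside \[0, 1\]"):
            read_yolo_labels(p, (100, 100))

    def test_confidence_dialect(self, rng, tmp_path):
        size = (320, 320)
        anns = self.make_annotations(rng, 3, size)
        path = write_yolo_labels(anns, size, tmp_path / "p.txt", confidences=[0.9, 0.8, 0.75])
        back, confs = read_yolo_labels(path, size, with_confidence=True)
        assert confs == [0.9, 0.8, 0.75]
        assert len(back) == 3

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_property(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        size = (800, 600)
        anns = self.make_annotations(rng, int(rng.integers(1, 5)), size)
        path = tmp_path_factory.mktemp("labels") / "x.txt"
        write_yolo_labels(anns, size, path)
        back = read_yolo_labels(path, size)
        for a, b in zip(anns, back):
            av = np.asarray(a.vertices) / size
            bv = np.asarray(b.vertices) / size
            assert np.max(np.abs(av - bv)) <= 5.1e-7
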