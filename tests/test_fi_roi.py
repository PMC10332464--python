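import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from flyfi.fi import (
    RoiContour,
    ZStack,
    measure_neuron,
    measure_roi_slice,
    polygon_mask,
    read_rois_json,
    write_rois_json,
)
from flyfi.synth import generate_brain

from oracles import (
    gaussian_window_integral,
    random_star_polygon,
    roi_measurement_bruteforce,
)


def roi(polygon, z_first=0, z_last=0, **kw):
    kw.setdefault("neuron_id", "n1")
    kw.setdefault("cluster", "PAL")
    kw.setdefault("hemisphere", "R")
    return RoiContour(polygon=np.asarray(polygon, float),
                      z_first=z_first, z_last=z_last, **kw)


def uniform_stack(value, shape=(1, 8, 8), pixel_size=0.25):
    return ZStack(np.full(shape, float(value)), pixel_size_um=pixel_size)


SQUARE_9PX = [[0.5, 0.5], [3.5, 0.5], [3.5, 3.5], [0.5, 3.5]]


class TestRoiValidation:
    def test_two_vertices_rejected(self):
        with pytest.raises(ValueError, match="3"):
            roi([[0, 0], [1, 1]])

    def test_self_intersection_rejected(self):
        bowtie = [[0, 0], [2, 2], [2, 0], [0, 2]]
        with pytest.raises(ValueError, match="self-intersecting"):
            roi(bowtie)

    def test_bad_cluster_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            roi(SQUARE_9PX, cluster="XYZ")

    def test_z_order_rejected(self):
        with pytest.raises(ValueError):
            roi(SQUARE_9PX, z_first=5, z_last=2)


class TestMeasureRoiSlice:
    def test_uniform_square_9_pixels(self):
        m = measure_roi_slice(uniform_stack(10.0), roi(SQUARE_9PX), 0)
        assert m.area_px == 9
        assert m.intensity_sum == pytest.approx(90.0)
        assert m.intensity_mean == pytest.approx(10.0)
        assert m.area_um2 == pytest.approx(9 * 0.25**2)

    def test_triangle_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        plane = rng.random((16, 16)) * 100
        tri = [[2.2, 1.1], [13.7, 3.9], [6.1, 14.2]]
        stack = ZStack(plane[None], pixel_size_um=1.0)
        m = measure_roi_slice(stack, roi(tri), 0)
        area, total = roi_measurement_bruteforce(plane, tri)
        assert m.area_px == area
        assert m.intensity_sum == pytest.approx(total)

    def test_mean_times_area_is_sum(self):
        rng = np.random.default_rng(3)
        plane = rng.random((16, 16)) * 50
        m = measure_roi_slice(ZStack(plane[None], pixel_size_um=1.0),
                              roi(SQUARE_9PX), 0)
        assert m.intensity_mean * m.area_px == pytest.approx(m.intensity_sum)

    def test_empty_roi_rejected(self):
        tiny = [[0.1, 0.1], [0.2, 0.1], [0.2, 0.2]]
        with pytest.raises(ValueError, match="empty ROI"):
            measure_roi_slice(uniform_stack(1.0), roi(tiny), 0)

    def test_slice_outside_window_rejected(self):
        with pytest.raises(ValueError, match="z-window"):
            measure_roi_slice(uniform_stack(1.0), roi(SQUARE_9PX), 3)

    def test_oracle_equivalence_200_random_polygons(self):
        # exhaustive pixel-center oracle + shapely cross-check
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            plane = rng.random((16, 16)) * 100
            poly = random_star_polygon(
                rng, center=rng.uniform(3, 13, 2), r_min=0.5, r_max=6.0)
            area, total = roi_measurement_bruteforce(plane, poly)
            shapely_poly = shapely.Polygon(poly)
            stack = ZStack(plane[None], pixel_size_um=1.0)
            if area == 0:
                with pytest.raises(ValueError, match="empty ROI"):
                    measure_roi_slice(stack, roi(poly), 0)
            else:
                m = measure_roi_slice(stack, roi(poly), 0)
                assert m.area_px == area
                assert m.intensity_sum == pytest.approx(total)
                # independent geometry oracle on the same membership set
                mask = polygon_mask(poly, plane.shape)
                ys, xs = np.nonzero(mask)
                for x, y in zip(xs, ys):
                    assert shapely_poly.contains(shapely.Point(x, y))
            checked += 1


class TestMeasureNeuron:
    def test_uniform_default_window(self):
        stack = uniform_stack(7.0, shape=(11, 8, 8))
        m = measure_neuron(stack, roi(SQUARE_9PX, z_first=0, z_last=10))
        assert m.n_slices == 11
        assert m.neuron_fi == pytest.approx(11 * 9 * 7.0)

    def test_window_exceeding_stack_rejected(self):
        with pytest.raises(ValueError, match="exceeds stack depth"):
            measure_neuron(uniform_stack(1.0, shape=(5, 8, 8)),
                           roi(SQUARE_9PX, z_first=0, z_last=10))

    def test_default_synthetic_window_is_11(self, default_hemisphere):
        _, (stack, _, rois) = default_hemisphere
        m = measure_neuron(stack, rois[0])
        assert m.n_slices == 11
        assert all(r.n_slices == 11 for r in rois)

    def test_per_slice_polygons(self):
        stack = uniform_stack(2.0, shape=(2, 8, 8))
        r = roi(SQUARE_9PX, z_first=0, z_last=1)
        small = [[0.5, 0.5], [2.5, 0.5], [2.5, 2.5], [0.5, 2.5]]  # 4 px
        m = measure_neuron(stack, r, per_slice_polygons=[SQUARE_9PX, small])
        assert [s.area_px for s in m.slices] == [9, 4]
        assert m.neuron_fi == pytest.approx(2.0 * (9 + 4))

    def test_gaussian_neuron_within_5pct_of_analytic(self, tiny_config):
        stack, truth, rois = generate_brain(tiny_config, "control", seed=3)
        m = measure_neuron(stack, rois[0])
        n = truth.neurons.iloc[0]
        z_offsets = [z - n["z"] for z in range(rois[0].z_first, rois[0].z_last + 1)]
        expected = gaussian_window_integral(
            n["amplitude"], n["sigma"], 2.5 * n["sigma"], z_offsets)
        assert m.neuron_fi == pytest.approx(expected, rel=0.05)

    @given(k=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scaling_voxels_scales_fi_linearly(self, k):
        rng = np.random.default_rng(5)
        data = rng.random((3, 8, 8)) * 10
        r = roi(SQUARE_9PX, z_first=0, z_last=2)
        base = measure_neuron(ZStack(data, pixel_size_um=1.0), r)
        scaled = measure_neuron(ZStack(data * k, pixel_size_um=1.0), r)
        assert scaled.neuron_fi == pytest.approx(k * base.neuron_fi, rel=1e-9)

    def test_median_background_subtraction(self):
        data = np.full((1, 32, 32), 50.0)
        data[0, 4, 4] += 100.0
        r = roi([[3.5, 3.5], [4.5, 3.5], [4.5, 4.5], [3.5, 4.5]])
        raw = measure_neuron(ZStack(data, pixel_size_um=1.0), r)
        sub = measure_neuron(ZStack(data, pixel_size_um=1.0), r,
                             subtract_background="median")
        assert raw.neuron_fi == pytest.approx(150.0)
        assert sub.neuron_fi == pytest.approx(100.0)


def test_roi_json_round_trip(tmp_path, default_hemisphere):
    _, (_, _, rois) = default_hemisphere
    path = tmp_path / "rois.json"
    write_rois_json(rois, path)
    back = read_rois_json(path)
    assert len(back) == len(rois)
    assert back[0].neuron_id == rois[0].neuron_id
    assert back[0].z_first == rois[0].z_first
    assert np.allclose(back[0].polygon, rois[0].polygon)
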