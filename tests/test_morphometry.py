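"""Contour morphometry against analytic and sampling oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from matplotlib.path import Path as MplPath

from spinecoupling import (
    CylinderObservation,
    SpineRecord,
    Trace,
    TraceStack,
    estimate_section_thickness,
    generate_contour_stacks,
    measure_psd_area,
    measure_volume,
    merge_multisynaptic,
    polygon_area,
)


def square(side=1.0, x0=0.0, y0=0.0):
    return ((x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side))


def grid_area(vertices, h=0.001):
    """Pixel-counting area oracle: fraction of cell centres inside × cell area."""
    verts = np.asarray(vertices)
    path = MplPath(verts, closed=False)
    lo = verts.min(axis=0) - h
    hi = verts.max(axis=0) + h
    xs = np.arange(lo[0] + h / 2, hi[0], h)
    ys = np.arange(lo[1] + h / 2, hi[1], h)
    gx, gy = np.meshgrid(xs, ys)
    inside = path.contains_points(np.column_stack([gx.ravel(), gy.ravel()]))
    return inside.sum() * h * h


class TestPolygonArea:
    @pytest.mark.parametrize(
        "vertices, expected",
        [
            (square(), 1.0),
            (((0, 0), (1, 0), (0, 1)), 0.5),
        ],
    )
    def test_known_shapes(self, vertices, expected):
        assert polygon_area(vertices) == pytest.approx(expected)

    def test_orientation_and_start_vertex_irrelevant(self):
        verts = ((0, 0), (2, 0), (2, 1), (0, 1))
        area = polygon_area(verts)
        assert polygon_area(verts[::-1]) == pytest.approx(area)
        assert polygon_area(verts[2:] + verts[:2]) == pytest.approx(area)

    def test_monte_carlo_estimate_convex_12gon(self, rng):
        # rejection-sampling oracle: hit fraction of uniform points in the bbox
        angles = np.sort(rng.uniform(0, 2 * math.pi, 12))
        verts = [(1.3 * math.cos(a), 0.8 * math.sin(a)) for a in angles]
        area = polygon_area(verts)
        pts = rng.uniform(-1.3, 1.3, size=(1_000_000, 2))
        pts[:, 1] *= 0.8 / 1.3
        hits = MplPath(np.asarray(verts), closed=False).contains_points(pts)
        mc = hits.mean() * 2.6 * 1.6
        assert area == pytest.approx(mc, rel=0.01)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError, match="vertices"):
            polygon_area([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="self-intersecting"):
            polygon_area([(0, 0), (1, 1), (1, 0), (0, 1)])  # bow-tie

    @given(
        theta=st.floats(0, 2 * math.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_rigid_transform_invariance(self, theta, tx, ty):
        verts = np.array([(0.0, 0.0), (0.7, 0.1), (0.9, 0.8), (0.2, 0.6)])
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = verts @ rot.T + (tx, ty)
        assert polygon_area(moved) == pytest.approx(polygon_area(verts), abs=1e-8)


def stack_of_squares(areas_by_section, t=0.05, label="spine"):
    traces = []
    for i, area in enumerate(areas_by_section):
        traces.append(
            Trace(
                section_index=i,
                kind="closed_polygon",
                label=label,
                vertices=square(side=math.sqrt(area)),
            )
        )
    return TraceStack(object_id="obj", section_thickness=t, traces=traces)


class TestMeasureVolume:
    def test_cavalieri_sum(self):
        assert measure_volume(stack_of_squares([1.0, 1.0, 1.0], t=0.05)) == (
            pytest.approx(0.15)
        )
        assert measure_volume(stack_of_squares([0.02], t=0.06)) == (
            pytest.approx(0.0012)
        )

    def test_sphere_against_analytic_volume(self):
        r, t = 0.3, 0.01
        n = int(2 * r / t)
        traces = []
        for i in range(n):
            z = -r + (i + 0.5) * t
            rad = math.sqrt(r * r - z * z)
            verts = tuple(
                (rad * math.cos(a), rad * math.sin(a))
                for a in np.linspace(0, 2 * math.pi, 256, endpoint=False)
            )
            traces.append(
                Trace(section_index=i, kind="closed_polygon", label="spine",
                      vertices=verts)
            )
        stack = TraceStack(object_id="sphere", section_thickness=t, traces=traces)
        assert measure_volume(stack) == pytest.approx(4 / 3 * math.pi * r**3, rel=0.02)

    def test_matches_voxelisation_oracle_on_convex_stack(self):
        rec = SpineRecord(
            id="s", sample_id="x", condition="control",
            volume=0.12, psd_area=0.08, psd_core_volume=0.002,
        )
        stack = generate_contour_stacks(rec, thickness=0.05, seed=4)
        voxel = sum(
            grid_area(t.vertices) for t in stack.traces if t.label == "spine"
        ) * stack.section_thickness
        assert measure_volume(stack, "spine") == pytest.approx(voxel, rel=0.005)

    def test_additivity_under_polygon_split(self):
        whole = stack_of_squares([1.0], t=0.05)
        halves = TraceStack(
            object_id="obj",
            section_thickness=0.05,
            traces=[
                Trace(0, "closed_polygon", "spine",
                      ((0, 0), (0.5, 0), (0.5, 1), (0, 1))),
                Trace(0, "closed_polygon", "spine",
                      ((0.5, 0), (1, 0), (1, 1), (0.5, 1))),
            ],
        )
        assert abs(measure_volume(whole) - measure_volume(halves)) < 1e-9

    def test_scaling_laws(self):
        rec = SpineRecord(
            id="s", sample_id="x", condition="control",
            volume=0.1, psd_area=0.06, psd_core_volume=0.002,
        )
        stack = generate_contour_stacks(rec, thickness=0.05, seed=8)
        k = 1.7
        scaled = TraceStack(
            object_id="s",
            section_thickness=stack.section_thickness * k,
            traces=[
                Trace(t.section_index, t.kind, t.label,
                      tuple((x * k, y * k) for x, y in t.vertices))
                for t in stack.traces
            ],
        )
        assert measure_volume(scaled, "spine") == pytest.approx(
            k**3 * measure_volume(stack, "spine")
        )
        assert measure_psd_area(scaled) == pytest.approx(
            k**2 * measure_psd_area(stack)
        )

    def test_open_traces_ignored_with_warning(self):
        stack = stack_of_squares([1.0], t=0.05)
        stack.traces.append(
            Trace(0, "open_polyline", "spine", ((0, 0), (1, 1)))
        )
        with pytest.warns(UserWarning, match="open polyline"):
            assert measure_volume(stack) == pytest.approx(0.05)

    def test_no_matching_traces_rejected(self):
        with pytest.raises(ValueError, match="psd_core"):
            measure_volume(stack_of_squares([1.0]), label="psd_core")


class TestMeasurePsdArea:
    def test_polyline_and_parallel_contributions(self):
        t = 0.06
        lines = [
            Trace(0, "open_polyline", "psd_core", ((0, 0), (0.2, 0))),
            Trace(1, "open_polyline", "psd_core", ((0, 0), (0.3, 0))),
        ]
        parallel = [
            Trace(2, "closed_polygon", "psd_core", square(side=0.2))
        ]
        only_lines = TraceStack("a", t, list(lines))
        only_parallel = TraceStack("b", t, list(parallel))
        mixed = TraceStack("c", t, lines + parallel)
        assert measure_psd_area(only_lines) == pytest.approx(0.03)
        assert measure_psd_area(only_parallel) == pytest.approx(0.04)
        assert measure_psd_area(mixed) == pytest.approx(0.07)

    def test_rejects_stack_without_psd(self):
        with pytest.raises(ValueError, match="psd_core"):
            measure_psd_area(stack_of_squares([1.0]))


class TestSectionThickness:
    def test_diameter_over_span(self):
        t, per = estimate_section_thickness([CylinderObservation(0.30, 5)])
        assert t == pytest.approx(0.06)
        t, per = estimate_section_thickness(
            [CylinderObservation(0.30, 5), CylinderObservation(0.35, 5)]
        )
        assert t == pytest.approx(0.065)
        np.testing.assert_allclose(per, [0.06, 0.07])

    def test_forward_simulated_cylinders(self, rng):
        # a cylindrical organelle lying in-plane appears on every section
        # whose mid-plane falls within its diameter along the cutting axis
        t_true = 0.055
        obs = []
        for _ in range(300):
            d = rng.uniform(0.2, 0.45)
            z0 = rng.uniform(0, 10)
            mids = np.arange(0, 12, t_true) + t_true / 2
            span = int(np.sum((mids >= z0) & (mids <= z0 + d)))
            obs.append(CylinderObservation(diameter=d, span=span))
        estimate, _ = estimate_section_thickness(obs)
        assert estimate == pytest.approx(t_true, rel=0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="observation"):
            estimate_section_thickness([])
        with pytest.raises(ValueError, match="span"):
            CylinderObservation(0.3, 0)


class TestMergeMultisynaptic:
    def base(self, **kw):
        defaults = dict(
            id="sp1", sample_id="s1", condition="control",
            volume=0.2, psd_area=0.02, psd_core_volume=0.001,
        )
        defaults.update(kw)
        return SpineRecord(**defaults)

    def test_sums_psd_parameters_and_or_combines_flags(self):
        merged = merge_multisynaptic(
            [self.base(psd_area=0.02), self.base(psd_area=0.03, has_ser=True)]
        )
        assert merged.psd_area == pytest.approx(0.05)
        assert merged.has_ser and merged.n_synapses == 2
        three = merge_multisynaptic([self.base(psd_core_volume=0.001)] * 3)
        assert three.psd_core_volume == pytest.approx(0.003)

    def test_single_record_identity(self):
        rec = self.base()
        assert merge_multisynaptic([rec]) == rec

    def test_conflicting_volumes_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            merge_multisynaptic([self.base(volume=0.2), self.base(volume=0.3)])
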