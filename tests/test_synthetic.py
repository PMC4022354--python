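"""Synthetic plants: ground truth, projection geometry, rasterization, renders."""

import math
from dataclasses import replace

import numpy as np
import pytest

import lcshoot as lc
from lcshoot.errors import GenerationError, LayoutError, ValidationError
from lcshoot.synthetic import Leaf, SyntheticPlant, _PHASE_STEP
from lcshoot.traits import stack_mean


def one_leaf_plant(**leaf_kw):
    kw = dict(
        base=(0.0, 0.0, 40.0), azimuth=0.0, elevation=30.0, length=100.0,
        width=50.0, thickness=2.5, tip_thickness=2.5,
    )
    kw.update(leaf_kw)
    leaf = Leaf(**kw)
    return SyntheticPlant(
        archetype="dicot_rosette",
        leaves=(leaf,),
        stem_height=40.0,
        stem_diameter=8.0,
        true_leaf_area=leaf.blade_area_mm2 / 100.0,
        true_max_height=200.0,
    )


class TestMakePlant:
    @pytest.mark.parametrize("archetype", ["dicot_rosette", "monocot"])
    def test_deterministic_given_seed(self, archetype):
        a = lc.make_plant(archetype, seed=42)
        b = lc.make_plant(archetype, seed=42)
        assert a == b
        assert a != lc.make_plant(archetype, seed=43)

    def test_elliptical_blade_area_formula(self):
        leaf = Leaf(base=(0, 0, 0), azimuth=0, elevation=20, length=100.0, width=50.0)
        assert leaf.blade_area_mm2 == pytest.approx(math.pi * 100 * 50 / 4)
        assert leaf.blade_area_mm2 / 100 == pytest.approx(39.27, abs=0.01)

    def test_target_area_hit_exactly(self):
        p = lc.make_plant("dicot_rosette", seed=3, target_area_cm2=123.0)
        assert p.true_leaf_area == pytest.approx(123.0)
        assert p.true_leaf_area * 100 == pytest.approx(
            sum(l.blade_area_mm2 for l in p.leaves)
        )

    def test_height_range_respected(self):
        params = replace(lc.DICOT_ROSETTE, height_mm=(25.0, 200.0))
        for seed in range(5):
            p = lc.make_plant("dicot_rosette", params, seed=seed)
            assert p.true_max_height <= 200.0
            assert p.true_max_height >= p.stem_height

    def test_area_within_default_range(self):
        for seed in range(5):
            lo, hi = lc.MONOCOT.area_cm2
            p = lc.make_plant("monocot", seed=seed)
            assert lo <= p.true_leaf_area <= hi

    def test_unsatisfiable_range_raises(self):
        bad = replace(lc.DICOT_ROSETTE, width_ratio=(0.89, 0.9), canopy_diameter_mm=(280, 280))
        with pytest.raises(GenerationError):
            lc.make_plant("dicot_rosette", bad, seed=0, target_area_cm2=12.0)

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValidationError):
            lc.make_plant("tree", seed=0)

    def test_population_spans_area_range(self):
        pop = lc.make_population("dicot_rosette", 8, seed=2)
        areas = sorted(p.true_leaf_area for p in pop)
        lo, hi = lc.DICOT_ROSETTE.area_cm2
        assert areas[0] < lo + 0.2 * (hi - lo)
        assert areas[-1] > hi - 0.2 * (hi - lo)


class TestProjection:
    def test_mirror_symmetry_0_vs_180(self):
        p = lc.make_plant("dicot_rosette", seed=5)
        s0 = lc.rasterize(lc.project(p, 0.0))
        s180 = lc.rasterize(lc.project(p, 180.0))
        mirrored = {(r, -c - 1) for r, c in s0.pixels}
        assert mirrored == set(s180.pixels)
        assert lc.pixel_area(s0) == lc.pixel_area(s180)

    def test_full_face_projection_preserves_blade_area(self):
        # erect blade turned square to the beam: projected area = mesh area
        # (the blade's width axis lies 90 deg from its azimuth)
        from lcshoot.synthetic import _plant_primitives, _project_prims

        p = one_leaf_plant(elevation=90.0, azimuth=0.0)
        quads = [pr for pr in _plant_primitives(p) if pr[0] == "quad"]
        tri_area = 0.0
        for tris, _ in _project_prims(quads, 90.0):
            for (x1, z1), (x2, z2), (x3, z3) in tris:
                tri_area += abs((x2 - x1) * (z3 - z1) - (x3 - x1) * (z2 - z1)) / 2
        assert tri_area == pytest.approx(p.true_leaf_area * 100, rel=0.03)

    def test_horizontal_leaf_edge_on_is_degenerate(self):
        # planophile blade seen by horizontal beams: thin strip, tiny area
        flat = one_leaf_plant(elevation=0.0)
        face = one_leaf_plant(elevation=90.0)
        a_flat = lc.pixel_area(lc.rasterize(lc.project(flat, 0.0)))
        a_face = lc.pixel_area(lc.rasterize(lc.project(face, 90.0)))
        assert a_flat < 0.25 * a_face


class TestRasterize:
    def square_shapes(self, size=10.0, t=5.0):
        c = np.array([[0, 0], [size, 0], [size, size], [0, size]], dtype=float)
        return [(np.stack([c[[0, 1, 2]], c[[0, 2, 3]]]), t)]

    def test_square_cell_centre_rule(self):
        sil = lc.rasterize(self.square_shapes(), 2.5, 2.5, thickness_threshold=0.0)
        assert lc.pixel_area(sil) == 16  # 4 x 4 covered centres

    def test_below_threshold_everywhere_empty(self):
        sil = lc.rasterize(self.square_shapes(t=0.5), 2.5, 2.5, thickness_threshold=1.0)
        assert sil.is_empty

    def test_halving_h_pitch_doubles_columns(self):
        cols = lambda s: len({c for _, c in s.pixels})
        coarse = lc.rasterize(self.square_shapes(), 2.5, 2.5, 0.0)
        fine = lc.rasterize(self.square_shapes(), 2.5, 1.25, 0.0)
        assert abs(cols(fine) - 2 * cols(coarse)) <= 1

    def test_thickness_accumulates_over_stacked_shapes(self):
        shapes = self.square_shapes(t=0.6) + self.square_shapes(t=0.6)
        sil = lc.rasterize(shapes, 2.5, 2.5, thickness_threshold=1.0)
        assert lc.pixel_area(sil) == 16


class TestThinStructureDropout:
    def test_monocot_height_never_overestimated_without_threshold(self, small_monocot):
        with_thr = lc.make_view_stack(small_monocot, thickness_threshold=1.0, with_pots=False)
        no_thr = lc.make_view_stack(small_monocot, thickness_threshold=0.0, with_pots=False)
        h1 = [lc.max_height(with_thr.views[a]) for a in lc.VIEW_ANGLES]
        h0 = [lc.max_height(no_thr.views[a]) for a in lc.VIEW_ANGLES]
        assert all(a <= b for a, b in zip(h1, h0))
        assert np.mean(h1) < np.mean(h0)  # thin leaf tips are lost


class TestRenderScan:
    def test_two_plants_disjoint_at_default_spacing(self):
        p1 = lc.make_plant("dicot_rosette", seed=31, target_area_cm2=60.0)
        p2 = lc.make_plant("dicot_rosette", seed=32, target_area_cm2=60.0)
        scan, truth = lc.render_scan([p1, p2])
        sils = lc.segment_scan(scan)
        assert len(truth) == 2
        assert truth["pot_center_mm"].diff().iloc[-1] == pytest.approx(300.0)
        assert not (set(sils[0].pixels) & set(sils[1].pixels))

    def test_overlapping_pots_rejected(self):
        p = lc.make_plant("dicot_rosette", seed=1)
        with pytest.raises(LayoutError):
            lc.render_scan([p, p], pot_spacing=100.0)

    def test_ground_truth_carries_model_truth(self, small_dicot):
        _, truth = lc.render_scan([small_dicot])
        assert truth.loc[0, "true_leaf_area_cm2"] == pytest.approx(small_dicot.true_leaf_area)
        assert truth.loc[0, "true_max_height_mm"] == pytest.approx(small_dicot.true_max_height)


class TestViewStack:
    def test_has_exactly_18_views(self, small_dicot_stack):
        assert set(small_dicot_stack.views) == set(lc.VIEW_ANGLES)
        assert len(small_dicot_stack.views) == 18

    def test_stack_is_deterministic(self, small_dicot, small_dicot_stack):
        again = lc.make_view_stack(small_dicot)
        for a in lc.VIEW_ANGLES:
            assert again.views[a].pixels == small_dicot_stack.views[a].pixels

    def test_view_matches_fresh_render(self, small_dicot, small_dicot_stack):
        k = lc.VIEW_ANGLES.index(10)
        phase = ((k * _PHASE_STEP) % 1.0) * small_dicot_stack.views[10].h_pitch
        scan, _ = lc.render_scan([small_dicot], view_angles=[10], phase_mm=phase)
        (sil,) = lc.segment_scan(scan)
        assert sil.pixels == small_dicot_stack.views[10].pixels

    def test_rotationally_symmetric_plant_has_zero_mdm(self):
        cylinder = SyntheticPlant(
            archetype="dicot_rosette",
            leaves=(),
            stem_height=150.0,
            stem_diameter=20.0,
            true_leaf_area=0.0,
            true_max_height=150.0,
        )
        stack = lc.make_view_stack(cylinder, spread_phase=False)
        for n, step in [(1, 10), (2, 90), (4, 50)]:
            assert lc.max_deviation_to_mean(stack, n, step, "area") == pytest.approx(0.0)
            assert lc.max_deviation_to_mean(stack, n, step, "height") == pytest.approx(0.0)
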