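"""Chamber geometry, patch bookkeeping and catheter placement."""

import numpy as np
import pytest

from atriumflow import constants as C
from atriumflow.geometry import (
    BoundaryPatch,
    CatheterConfig,
    ChamberGeometry,
    TipVolume,
    place_catheter,
)


class TestBoundaryPatch:
    def test_slot_facets_sum_to_area(self):
        p = BoundaryPatch.slot("svc", "velocity_inlet", "x-", 0.01, 0.008, 0.002, 0.03)
        assert p.area == pytest.approx(p.n_facets * 0.002 * 0.03)
        assert np.allclose(np.linalg.norm(p.normals, axis=1), 1.0)

    def test_bad_kind_rejected(self):
        with pytest.raises(ValueError):
            BoundaryPatch("x", "mystery", [1.0], [[1.0, 0.0]])

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            BoundaryPatch("x", "wall", [0.0], [[1.0, 0.0]])


class TestChamberGeometry:
    def test_default_ra_patches(self):
        g = ChamberGeometry.default_ra(nx=48, ny=48)
        assert set(g.patches) == {"svc", "ivc", "tv"}
        # as-built slot areas approximate the physiological opening areas
        assert g.patches["tv"].area == pytest.approx(C.TV_AREA, rel=0.07)
        assert g.patches["svc"].diameter == C.SVC_DIAMETER
        assert g.patches["ivc"].diameter == C.IVC_DIAMETER

    def test_overlapping_patches_rejected(self):
        g = ChamberGeometry.default_ra(nx=48, ny=48)
        with pytest.raises(ValueError):
            g.add_slot("svc2", "velocity_inlet", "x-", 0.045, 2e-4)

    def test_anisotropic_grid_rejected(self):
        with pytest.raises(ValueError):
            ChamberGeometry(Lx=0.06, Ly=0.06, nx=48, ny=32)

    def test_3d_not_available(self):
        with pytest.raises(NotImplementedError):
            ChamberGeometry(dimensionality="3D")


class TestCatheterConfig:
    def test_dimensions_table_defaults(self):
        c = CatheterConfig(design="C")
        assert (c.tip_length, c.outer_diameter, c.lumen_area) == (152.0, 15.0, 3.5)

    def test_design_d_jet_speed(self):
        # 400 ml/min through a 7.8 mm^2 lumen
        c = CatheterConfig(design="D")
        assert c.venous_jet_speed == pytest.approx(0.855, rel=2e-3)

    def test_side_holes_only_for_design_a(self):
        assert CatheterConfig(design="A").side_hole_count == 2
        assert CatheterConfig(design="B", side_hole_count=4).side_hole_count == 0

    def test_rotation_undefined_for_symmetric_tip(self):
        with pytest.raises(ValueError):
            CatheterConfig(design="D", tip_position="position3")

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            CatheterConfig(design="E")


class TestPlaceCatheter:
    def test_adds_source_and_sink_patches(self):
        g = ChamberGeometry.default_ra(nx=48, ny=48)
        g2 = place_catheter(g, CatheterConfig(design="B"))
        assert "cath_venous" in g2.patches and "cath_arterial" in g2.patches
        assert "cath_venous" not in g.patches  # original untouched
        # design B has no side-hole sub-patches
        assert not [n for n in g2.patches if n.startswith("cath_side")]

    def test_design_a_side_holes_split_flow(self):
        g = ChamberGeometry.default_ra(nx=48, ny=48)
        g2 = place_catheter(g, CatheterConfig(design="A"))
        sides = [p for n, p in g2.patches.items() if n.startswith("cath_side")]
        assert len(sides) == 2
        q_total = sum(
            p.prescribed_speed * p.area
            for n, p in g2.patches.items()
            if p.kind == "catheter_venous"
        )
        assert q_total == pytest.approx(400.0 * C.ML_MIN_TO_M3_S, rel=1e-9)

    def test_arterial_flow_matches_operating_table(self):
        g = ChamberGeometry.default_ra(nx=48, ny=48)
        g2 = place_catheter(g, CatheterConfig(design="C"))
        p = g2.patches["cath_arterial"]
        assert -p.prescribed_speed * p.area == pytest.approx(
            360.0 * C.ML_MIN_TO_M3_S, rel=1e-9
        )

    def test_positions_differ_only_by_translation(self):
        g = ChamberGeometry.default_ra(nx=48, ny=48)
        g1 = place_catheter(g, CatheterConfig(design="A", tip_position="position1"))
        g2 = place_catheter(g, CatheterConfig(design="A", tip_position="position2"))
        p1, p2 = g1.patches["cath_venous"], g2.patches["cath_venous"]
        assert p1.i0 != p2.i0  # translated toward the wall
        assert p1.n_facets == p2.n_facets
        assert p1.prescribed_speed == pytest.approx(p2.prescribed_speed)

    def test_position3_mirrors_lumen_order(self):
        g = ChamberGeometry.default_ra(nx=48, ny=48)
        g1 = place_catheter(g, CatheterConfig(design="A", tip_position="position1"))
        g3 = place_catheter(g, CatheterConfig(design="A", tip_position="position3"))
        assert (g1.patches["cath_venous"].i0 > g1.patches["cath_arterial"].i0) != (
            g3.patches["cath_venous"].i0 > g3.patches["cath_arterial"].i0
        )

    def test_reverse_mode_swaps_lumen_positions(self):
        from atriumflow.boundary import CatheterOperatingPoint

        g = ChamberGeometry.default_ra(nx=48, ny=48)
        std = place_catheter(g, CatheterConfig(design="B"))
        rev = place_catheter(
            g,
            CatheterConfig(
                design="B", operating=CatheterOperatingPoint.for_design("B", mode="reverse")
            ),
        )
        assert std.patches["cath_venous"].i0 == rev.patches["cath_arterial"].i0

    def test_tip_volume_defaults(self):
        g = place_catheter(ChamberGeometry.default_ra(48, 48), CatheterConfig(design="A"))
        tv = g.catheter.tip_volume
        assert (tv.length, tv.width, tv.height) == (4.5, 25.0, 6.0)


class TestTipVolume:
    @pytest.mark.parametrize("design,dims", list(C.TIP_VOLUME_MM.items()))
    def test_per_design_dimensions(self, design, dims):
        tv = TipVolume.for_design(design)
        assert (tv.length, tv.width, tv.height) == dims

    def test_bounds_2d_use_length_and_height(self):
        tv = TipVolume(length=4.0, width=25.0, height=6.0, anchor=(0.01, 0.02))
        (x0, x1), (y0, y1) = tv.bounds(2)
        assert x1 - x0 == pytest.approx(4e-3)
        assert y1 - y0 == pytest.approx(6e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            TipVolume(length=0.0, width=1.0, height=1.0)
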