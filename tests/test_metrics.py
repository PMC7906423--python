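"""Haemodynamic metric operators against closed-form oracles."""

import numpy as np
import pytest

import atriumflow as af
from atriumflow.fields import FieldSnapshot
from atriumflow.geometry import TipVolume
from atriumflow.metrics import (
    TimeSeries,
    boundary_flow_rate,
    build_report,
    helicity_density,
    pearson,
    percent_change,
    recirculation_fraction,
    render_report_markdown,
    strain_and_stress,
    time_average,
    tip_statistics,
    tip_volume_stats,
    vorticity,
    wall_shear_stress,
)
from atriumflow.synthetic import GeneratorSpec, make_field, make_phase_pattern


def interior(ndim, w=1):
    return tuple([slice(w, -w)] * ndim)


def simple_shear_snapshot(gamma0=100.0, n=16, h=0.01):
    y = (np.arange(n) + 0.5) * h
    vel = np.stack([np.tile(gamma0 * y, (n, 1)), np.zeros((n, n))])
    return FieldSnapshot(0.0, h, vel)


class TestVorticity:
    @pytest.mark.parametrize("ndim", [2, 3])
    def test_rigid_rotation_exact(self, ndim):
        f = make_field(GeneratorSpec("rigid_rotation", {"omega": 5.0, "n": 12, "ndim": ndim}))
        _, mag = vorticity(f)
        assert np.abs(mag[interior(ndim)] - 10.0).max() < 1e-12

    def test_uniform_flow_zero(self):
        f = make_field(GeneratorSpec("uniform_jet", {"u": (0.3, -0.1), "n": 8}))
        _, mag = vorticity(f)
        assert np.abs(mag).max() == 0.0

    def test_taylor_green_second_order(self):
        errs = []
        for n in (32, 64):
            f = make_field(GeneratorSpec("taylor_green", {"n": n}))
            om, _ = vorticity(f)
            errs.append(
                np.abs(om[0] - f.ground_truth["vorticity_z"])[interior(2)].max()
            )
        assert errs[0] / errs[1] > 3.0  # ~4x for a second-order stencil

    def test_curl_divergence_identity(self):
        # div(curl u) vanishes analytically; discretely it is O(h^2)
        for kind, params in [
            ("taylor_green", {"n": 48}),
            ("rigid_rotation", {"omega": 3.0, "n": 24, "ndim": 3}),
            ("beltrami", {"n": 24}),
        ]:
            f = make_field(GeneratorSpec(kind, params))
            om, _ = vorticity(f)
            if om.shape[0] == 1:
                continue  # a scalar in 2-D; identity trivially holds
            div = sum(np.gradient(om[k], f.h, axis=k) for k in range(3))
            scale = max(np.abs(om).max(), 1.0)
            assert np.abs(div[interior(3, 2)]).max() / scale < 5 * f.h**2

    def test_small_grid_rejected(self):
        f = FieldSnapshot(0.0, 0.1, np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            vorticity(f)


class TestHelicity:
    def test_planar_field_zero(self):
        f = make_field(GeneratorSpec("taylor_green", {"n": 16}))
        assert np.abs(helicity_density(f)).max() == 0.0

    def test_rigid_rotation_3d_zero(self):
        f = make_field(GeneratorSpec("rigid_rotation", {"omega": 5.0, "n": 12, "ndim": 3}))
        hel = helicity_density(f)
        assert np.abs(hel[interior(3)]).max() < 1e-10

    def test_beltrami_eigenfield(self):
        f = make_field(GeneratorSpec("beltrami", {"n": 32}))
        hel = helicity_density(f)
        gt = f.ground_truth["helicity"]
        rel = np.abs(hel - gt)[interior(3, 2)].max() / np.abs(gt).max()
        assert rel < 0.01  # O(h^2) at n=32


class TestStrainAndStress:
    def test_simple_shear_closed_form(self, default_props):
        f = simple_shear_snapshot(gamma0=100.0)
        sf = strain_and_stress(f, default_props)
        assert np.abs(sf.magnitude - 100.0).max() < 1e-10
        tau_expected = af.apparent_viscosity(100.0, default_props) * 100.0
        assert np.abs(sf.tau - tau_expected).max() < 1e-10

    def test_rigid_rotation_strain_free(self, default_props):
        f = make_field(GeneratorSpec("rigid_rotation", {"omega": 5.0, "n": 12}))
        sf = strain_and_stress(f, default_props)
        assert np.abs(sf.magnitude[interior(2)]).max() < 1e-12
        assert np.abs(sf.tau[interior(2)]).max() < 1e-12

    def test_random_linear_field_matches_tensor_assembly(self, newtonian_props):
        # brute-force oracle: assemble eps from the exact constant gradients
        rng = np.random.default_rng(7)
        A = rng.normal(size=(2, 2))
        n, h = 10, 0.05
        c = (np.arange(n) + 0.5) * h
        X, Y = np.meshgrid(c, c, indexing="ij")
        vel = np.stack([A[0, 0] * X + A[0, 1] * Y, A[1, 0] * X + A[1, 1] * Y])
        sf = strain_and_stress(FieldSnapshot(0.0, h, vel), newtonian_props)
        eps_exact = 0.5 * (A + A.T)
        mag_exact = np.sqrt(2.0 * (eps_exact**2).sum())
        assert np.abs(sf.magnitude[interior(2)] - mag_exact).max() < 1e-12
        for i in range(2):
            for j in range(2):
                assert np.abs(sf.eps[i, j][interior(2)] - eps_exact[i, j]).max() < 1e-12

    def test_symmetry(self, default_props):
        f = make_field(GeneratorSpec("taylor_green", {"n": 16}))
        sf = strain_and_stress(f, default_props)
        assert np.abs(sf.eps[0, 1] - sf.eps[1, 0]).max() == 0.0


class TestWallShearStress:
    def test_poiseuille_both_walls(self, newtonian_props):
        f = make_field(GeneratorSpec("poiseuille", {"U_max": 0.5, "H": 0.02, "mu": 0.004}))
        gt = f.ground_truth["wss"]
        for side in ("y-", "y+"):
            _, avg = wall_shear_stress(f, side, newtonian_props)
            assert avg == pytest.approx(gt, rel=1e-9)  # formula exact for parabola
        assert gt == pytest.approx(4 * 0.004 * 0.5 / 0.02)

    def test_zero_velocity_zero_wss(self, default_props):
        f = FieldSnapshot(0.0, 0.01, np.zeros((2, 8, 8)))
        _, avg = wall_shear_stress(f, "y-", default_props)
        assert avg == 0.0

    def test_linearity_in_viscosity(self):
        f = make_field(GeneratorSpec("poiseuille", {"U_max": 0.5, "H": 0.02}))
        _, a1 = wall_shear_stress(f, "y-", af.FluidProperties.newtonian(0.004))
        _, a2 = wall_shear_stress(f, "y-", af.FluidProperties.newtonian(0.008))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_bad_wall_label(self, default_props):
        f = simple_shear_snapshot()
        with pytest.raises(ValueError):
            wall_shear_stress(f, "q-", default_props)
        with pytest.raises(ValueError):
            wall_shear_stress(f, "z+", default_props)  # no z axis in 2-D


class TestBoundaryFlowRate:
    def test_hand_value(self):
        # uniform 0.1 m/s across 2 cm^2 -> 20 ml/s
        areas = np.full(4, 0.5e-4)
        assert boundary_flow_rate(np.full(4, 0.1), areas) == pytest.approx(20.0)

    def test_zero_field(self):
        assert boundary_flow_rate(np.zeros(3), np.ones(3)) == 0.0

    def test_series_shape(self):
        q = boundary_flow_rate(np.ones((5, 3)), np.full(3, 1e-6))
        assert q.shape == (5,)

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            boundary_flow_rate(np.zeros(0), np.zeros(0))


class TestRecirculationFraction:
    @pytest.mark.parametrize("rf", [0.0, 25.0, 100.0])
    def test_planted_values(self, rf):
        t, phi, un, areas = make_phase_pattern(rf, seed=11)
        res = recirculation_fraction(t, phi, un, areas)
        assert res.Rf == pytest.approx(rf, abs=1e-9)

    def test_two_facet_hand_example(self):
        # mdot (1, 3) kg/s with phibar (1, 0) -> Rf = 25%
        res = recirculation_fraction(
            [0.0, 1.0], [[1.0, 0.0]] * 2, np.array([[1.0, 3.0]] * 2), np.ones(2), rho=1.0
        )
        assert res.Rf == pytest.approx(25.0, abs=1e-12)

    def test_matches_brute_force_facet_loop(self):
        t, phi, un, areas = make_phase_pattern(37.5, n_facets=6, seed=5)
        res = recirculation_fraction(t, phi, un, areas)
        # independent facet-by-facet trapezoid loop
        T = t[-1] - t[0]
        num, den = 0.0, 0.0
        for k in range(6):
            phib = np.trapezoid(phi[:, k], t) / T
            mdot = np.trapezoid(1060.0 * un[:, k] * areas[k], t) / T
            num += phib * mdot
            den += mdot
        assert res.Rf == pytest.approx(num / den * 100.0, abs=1e-12)

    def test_invariances(self):
        t, phi, un, areas = make_phase_pattern(42.0, seed=2)
        base = recirculation_fraction(t, phi, un, areas, rho=1060.0).Rf
        scaled = recirculation_fraction(t, phi, un, areas, rho=530.0).Rf
        assert scaled == base  # density cancels
        order = np.random.default_rng(0).permutation(phi.shape[1])
        perm = recirculation_fraction(t, phi[:, order], un[:, order], areas[order]).Rf
        assert perm == pytest.approx(base, abs=1e-12)

    def test_zero_mass_flow_rejected(self):
        with pytest.raises(ZeroDivisionError):
            recirculation_fraction([0, 1], [[0.5], [0.5]], np.zeros((2, 1)), np.ones(1))


class TestTipStatistics:
    def test_uniform_and_half_split(self):
        mask = np.ones((4, 4), dtype=bool)
        mean, frac = tip_volume_stats(np.full((4, 4), 5.0), mask, 10.0)
        assert (mean, frac) == (5.0, 0.0)
        tau = np.zeros((4, 4))
        tau[:2] = 20.0
        mean, frac = tip_volume_stats(tau, mask, 10.0)
        assert (mean, frac) == (10.0, 50.0)

    def test_random_field_matches_cell_loop(self):
        rng = np.random.default_rng(3)
        tau = rng.uniform(0, 30, (12, 10))
        mask = rng.uniform(size=(12, 10)) > 0.4
        mean, frac = tip_volume_stats(tau, mask, 10.0)
        vals = [tau[i, j] for i in range(12) for j in range(10) if mask[i, j]]
        assert mean == pytest.approx(sum(vals) / len(vals), rel=1e-12)
        assert frac == pytest.approx(
            100.0 * sum(v >= 10.0 for v in vals) / len(vals), rel=1e-12
        )

    def test_threshold_monotonicity(self, default_props):
        f = simple_shear_snapshot(gamma0=500.0)
        tip = TipVolume(length=50.0, width=50.0, height=50.0, anchor=(0.08, 0.08))
        fracs = [
            tip_statistics([f], tip, default_props, threshold=thr).frac_above_avg
            for thr in (0.5, 1.0, 2.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_outside_grid_rejected(self, default_props):
        f = simple_shear_snapshot()
        tip = TipVolume(length=500.0, width=10.0, height=10.0, anchor=(0.08, 0.08))
        with pytest.raises(ValueError):
            tip_statistics([f], tip, default_props)


class TestAveragesAndCorrelation:
    def test_constant_series_time_average(self):
        ts = TimeSeries("c", np.linspace(0, 0.8, 9), np.full(9, 3.7))
        assert time_average(ts) == pytest.approx(3.7, rel=1e-14)

    def test_time_average_last_cycle(self):
        t = np.linspace(0, 1.6, 33)
        v = np.where(t < 0.8, 1.0, 2.0)
        ts = TimeSeries("x", t, v, cycle_period=0.8)
        assert time_average(ts, over_last_cycle=True) == pytest.approx(2.0)

    def test_pearson_self_and_negated(self):
        x = np.random.default_rng(0).normal(size=50)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 200))
        r = pearson(x, y)
        assert pearson(3.0 * x - 7.0, y) == pytest.approx(r, abs=1e-12)
        assert pearson(x, -2.0 * y + 5.0) == pytest.approx(-r, abs=1e-12)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pearson(np.ones(10), np.arange(10.0))

    @pytest.mark.parametrize(
        "value,ref,expected",
        [(57.20, 44.10, 29.71), (6.45, 9.32, -30.79), (15.50, 12.90, 20.15),
         (33.40, 28.30, 18.02)],
    )
    def test_percent_change_printed_precision(self, value, ref, expected):
        assert percent_change(value, ref) == pytest.approx(expected, abs=0.01)

    def test_percent_change_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(1.0, 0.0)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            TimeSeries("x", [0.0, 0.1, 0.3], [1.0, 2.0, 3.0])


class TestReport:
    def test_absent_metrics_rendered_as_dash(self):
        df = build_report({"RA": {"vorticity_mean": 44.1, "wss_mean": 1.89}})
        assert np.isnan(df.loc["RA", "Rf_pct"])
        md = render_report_markdown(df)
        assert "-" in md and "44.10" in md

    def test_empty_input(self):
        df = build_report({})
        assert len(df) == 0 and list(df.columns)

    def test_pass_through_and_order(self):
        rows = {
            "A1": {"Rf_pct": 9.32, "vorticity_mean": 54.0},
            "D2": {"Rf_pct": 0.21, "vorticity_mean": 54.9},
        }
        df = build_report(rows)
        assert list(df.index) == ["A1", "D2"]
        assert df.loc["A1", "Rf_pct"] == 9.32

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            build_report({"X": {"bogus": 1.0}})
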