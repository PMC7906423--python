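"""Solver verification: analytic oracles, conservation, boundedness,
determinism, and the temporal-convergence harness."""

import numpy as np
import pytest

import atriumflow as af
from atriumflow.geometry import CatheterConfig, ChamberGeometry
from atriumflow.metrics import wall_shear_stress
from atriumflow.solver import (
    SolverSettings,
    check_temporal_convergence,
    cycle_averages,
    solve_transient,
)
from tests.conftest import run_poiseuille


class TestEquilibrium:
    def test_rest_stays_at_rest(self):
        w = af.build_default_waveform(mean_p=0.0, pulse_amplitude=0.0)
        geom = ChamberGeometry.default_ra(nx=24, ny=24)
        res = solve_transient(
            geom, waveform=w, settings=SolverSettings(dt=0.01, n_cycles=1, snapshot_stride=20)
        )
        assert max(np.abs(s.velocity).max() for s in res.snapshots) == 0.0


class TestPoiseuille:
    def test_flow_rate_and_wss(self, poiseuille_fine, newtonian_props):
        res, ref = poiseuille_fine
        s = res.snapshots[-1]
        u = s.velocity[0]
        q_num = u[0].sum() * s.h
        q_exact = 2.0 / 3.0 * ref["U_max"] * ref["H"]
        assert abs(q_num - q_exact) / q_exact < 0.02
        wss_exact = 4 * ref["mu"] * ref["U_max"] / ref["H"]
        _, avg = wall_shear_stress(s, "y-", newtonian_props)
        assert abs(avg - wss_exact) / wss_exact < 0.02

    def test_centerline_profile(self, poiseuille_fine):
        res, ref = poiseuille_fine
        s = res.snapshots[-1]
        y = s.cell_centers()[1]
        u_exact = 4 * ref["U_max"] * y * (ref["H"] - y) / ref["H"] ** 2
        assert np.abs(s.velocity[0][0] - u_exact).max() / ref["U_max"] < 0.02

    def test_grid_convergence_order(self, poiseuille_coarse, poiseuille_fine):
        errs = []
        for res, ref in (poiseuille_coarse, poiseuille_fine):
            s = res.snapshots[-1]
            q_num = s.velocity[0][0].sum() * s.h
            q_exact = 2.0 / 3.0 * ref["U_max"] * ref["H"]
            errs.append(abs(q_num - q_exact) / q_exact)
        assert errs[0] / errs[1] >= 1.7  # second-order interior scheme

    def test_divergence_free(self, poiseuille_fine):
        res, _ = poiseuille_fine
        assert np.abs(res.snapshots[-1].divergence()).max() < 1e-10


class TestModelEquivalence:
    def test_carreau_with_equal_plateaus_matches_newtonian(self):
        geom = ChamberGeometry.default_ra(nx=16, ny=16)
        w = af.build_default_waveform()
        settings = SolverSettings(dt=0.01, n_cycles=1, end_time=0.3, snapshot_stride=10)
        res_a = solve_transient(
            geom, props=af.FluidProperties(mu0=0.004, mu_inf=0.004), waveform=w, settings=settings
        )
        res_b = solve_transient(
            geom, props=af.FluidProperties.newtonian(0.004), waveform=w, settings=settings
        )
        for sa, sb in zip(res_a.snapshots, res_b.snapshots):
            assert np.abs(sa.velocity - sb.velocity).max() < 1e-10
            assert np.abs(sa.pressure - sb.pressure).max() < 1e-10


class TestChamberInvariants:
    def test_mass_conservation_per_step(self, catheter_run):
        qs = {n: ps.flow_rate_series() for n, ps in catheter_run.patch_series.items()}
        net = sum(qs.values())
        q_max = max(np.abs(q).max() for q in qs.values())
        assert np.abs(net).max() / q_max < 0.01  # rigid walls: instantaneous balance

    def test_phase_fraction_bounded(self, catheter_run):
        for s in catheter_run.snapshots:
            if s.phi_r is not None:
                assert s.phi_r.min() >= 0.0
                assert s.phi_r.max() <= 1.0

    def test_divergence_within_tolerance(self, catheter_run):
        for s in catheter_run.snapshots[::5]:
            vmax = max(np.abs(s.velocity).max(), 1e-9)
            assert np.abs(s.divergence()).max() * s.h / vmax < 1e-8

    def test_analysis_cycle_flagged(self, catheter_run):
        snaps = catheter_run.analysis_cycle_snapshots
        assert snaps[-1].time == pytest.approx(1.6, rel=1e-9)
        assert snaps[0].time >= 0.8 - 1e-9

    def test_reynolds_laminar(self, catheter_run):
        recs = catheter_run.reynolds_records()
        assert recs, "boundary records expected"
        for r in recs:
            assert 0 <= r.re_min <= r.re_mean <= r.re_max
        ok, _ = af.laminar_check([r.re_max for r in recs])
        assert ok

    def test_upwind_scheme_also_bounded(self):
        geom = ChamberGeometry.default_ra(nx=16, ny=16)
        res = solve_transient(
            geom,
            waveform=af.build_default_waveform(),
            catheter=CatheterConfig(design="D"),
            settings=SolverSettings(
                dt=0.005, n_cycles=1, end_time=0.4, snapshot_stride=10,
                advection_scheme="upwind",
            ),
        )
        for s in res.snapshots:
            assert s.phi_r.min() >= 0.0 and s.phi_r.max() <= 1.0


class TestDeterminism:
    def test_identical_runs_bit_identical(self):
        def run():
            geom = ChamberGeometry.default_ra(nx=16, ny=16)
            return solve_transient(
                geom,
                waveform=af.build_default_waveform(),
                catheter=CatheterConfig(design="B"),
                settings=SolverSettings(
                    dt=0.005, n_cycles=1, end_time=0.3, snapshot_stride=10,
                    seed=7, init_perturbation=1e-4,
                ),
            )

        r1, r2 = run(), run()
        for s1, s2 in zip(r1.snapshots, r2.snapshots):
            assert np.array_equal(s1.velocity, s2.velocity)
            assert np.array_equal(s1.phi_r, s2.phi_r)


class TestCflHandling:
    def test_abort_without_adaptivity(self):
        geom = ChamberGeometry.default_ra(nx=16, ny=16)
        with pytest.raises(RuntimeError, match="CFL"):
            solve_transient(
                geom,
                waveform=af.build_default_waveform(mean_p=4.5, pulse_amplitude=1.0),
                settings=SolverSettings(
                    dt=0.05, n_cycles=1, end_time=0.3, adaptive_substepping=False,
                    snapshot_stride=100,
                ),
            )


class TestTemporalConvergence:
    def test_zero_error_for_identical_cycles(self):
        df = check_temporal_convergence({"v": np.array([10.0, 10.0, 10.0])})
        assert (df["E_pct"] == 0.0).all()

    def test_hand_value(self):
        df = check_temporal_convergence({"v": np.array([10.0, 10.5])})
        e1 = df[(df["cycle"] == 1)]["E_pct"].iloc[0]
        assert e1 == pytest.approx(abs(10 - 10.5) / 10.5 * 100, rel=1e-12)
        assert e1 == pytest.approx(4.76, abs=0.005)

    def test_scale_invariance(self):
        vals = np.array([3.0, 2.5, 2.2, 2.0])
        e1 = check_temporal_convergence({"v": vals})["E_pct"].to_numpy()
        e2 = check_temporal_convergence({"v": -17.3 * vals})["E_pct"].to_numpy()
        assert np.allclose(e1, e2, rtol=1e-12)

    def test_reference_cycle_selection(self):
        vals = np.array([5.0, 4.0, 3.0])
        df = check_temporal_convergence({"v": vals}, ref_cycle=2)
        assert df[df["cycle"] == 2]["E_pct"].iloc[0] == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            check_temporal_convergence({"v": np.array([1.0, 0.0])})

    def test_threshold_flagging(self):
        df = check_temporal_convergence(
            {"v": np.array([10.5, 10.3, 10.05, 10.0])}, threshold_pct=1.0
        )
        conv = df.groupby("cycle")["converged"].first()
        assert not conv[1] and conv[3]

    def test_cycle_averages_of_solver_series(self, catheter_run):
        ts = catheter_run.volume_average_series("speed")
        ca = cycle_averages(ts)
        assert len(ca) == 2
        df = check_temporal_convergence({"speed": ca})
        # by the second cycle the start-up transient has largely decayed
        assert df[df["cycle"] == 2]["E_pct"].iloc[0] == 0.0
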