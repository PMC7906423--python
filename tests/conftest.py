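import warnings

import numpy as np
import pytest

import atriumflow as af
from atriumflow.geometry import CatheterConfig, ChamberGeometry
from atriumflow.solver import SolverSettings, solve_transient

# slot widths snap to whole grid faces at test resolutions; the area
# warning is informative, not an error
warnings.filterwarnings("ignore", message=r"patch .*as-built area")


@pytest.fixture(scope="session")
def default_props():
    return af.FluidProperties()


@pytest.fixture(scope="session")
def newtonian_props():
    return af.FluidProperties.newtonian(0.004)


def run_poiseuille(n_y: int, props=None, end_time: float = 120.0):
    """Pressure-driven (body-force) periodic channel, run to steady state."""
    if props is None:
        props = af.FluidProperties.newtonian(0.004)
    H = 0.02
    G = 2.0  # Pa/m
    geom = ChamberGeometry(Lx=2 * H, Ly=H, nx=2 * n_y, ny=n_y, depth=0.03)
    res = solve_transient(
        geom,
        props=props,
        settings=SolverSettings(
            dt=1.0,
            n_cycles=1,
            end_time=end_time,
            snapshot_stride=1000,
            body_force=(G / props.rho, 0.0),
        ),
        periodic_x=True,
    )
    U_max = G * H**2 / (8 * props.mu_newt)
    return res, dict(H=H, G=G, U_max=U_max, mu=props.mu_newt)


@pytest.fixture(scope="session")
def poiseuille_coarse():
    return run_poiseuille(8)


@pytest.fixture(scope="session")
def poiseuille_fine():
    return run_poiseuille(16)


@pytest.fixture(scope="session")
def catheter_run():
    """Small catheter-A chamber run shared by the metric/invariant tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        geom = ChamberGeometry.default_ra(nx=32, ny=32)
        res = solve_transient(
            geom,
            waveform=af.build_default_waveform(),
            catheter=CatheterConfig(design="A"),
            settings=SolverSettings(dt=0.004, n_cycles=2, snapshot_stride=10),
        )
    return res
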