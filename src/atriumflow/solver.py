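"""Transient incompressible generalized-Newtonian chamber-flow solver.

A fractional-step (projection) scheme on a uniform staggered (MAC) grid:

1.  momentum is advanced with explicit first-order upwind advection and
    first-order implicit diffusion, the apparent viscosity being evaluated
    cell-wise from the current shear-rate magnitude;
2.  a pressure projection enforces discrete incompressibility exactly
    (direct sparse solve of the Poisson equation);
3.  the recirculation-phase fraction ``phi_r`` is advected in conservative
    flux form with a bounded scheme — donor-cell upwind, or van Leer MUSCL
    fluxes limited by a Zalesak flux-corrected-transport step so the
    fraction provably stays in [0, 1].

All boundary velocities are Dirichlet: waveform-driven caval inflow
(through a linear admittance), constant catheter source/sink speeds, and a
tricuspid outflow balanced each step so the rigid-wall chamber conserves
mass instantaneously.  An optional x-periodic channel mode with a body
force supports verification against plane Poiseuille flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import constants as C
from .boundary import InletWaveform, sample_waveform
from .fields import FieldSnapshot
from .geometry import BoundaryPatch, CatheterConfig, ChamberGeometry, place_catheter
from .rheology import FluidProperties, ReynoldsRecord, apparent_viscosity

__all__ = [
    "SolverSettings",
    "PatchSeries",
    "SolveResult",
    "solve_transient",
    "check_temporal_convergence",
    "cycle_averages",
]


@dataclass
class SolverSettings:
    """Numerical settings of the transient solve.

    ``dt`` defaults to 0.005 s for single-phase runs and 0.001 s when a
    catheter (and hence the phase scalar) is present.  ``n_cycles`` cardiac
    cycles are simulated and the final one is flagged as the analysis
    cycle.  ``seed`` controls the optional random velocity perturbation of
    the initial state (0 amplitude by default: runs are deterministic).
    """

    dt: float | None = None
    n_cycles: int = C.N_CYCLES
    residual_tolerance: float = C.RESIDUAL_TOLERANCE
    cfl_cap: float = 0.9
    adaptive_substepping: bool = True
    advection_scheme: str = "van-leer-limited"
    snapshot_stride: int = 5
    seed: int = 0
    init_perturbation: float = 0.0
    body_force: tuple[float, float] = (0.0, 0.0)
    end_time: float | None = None  # overrides n_cycles * period when set

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.residual_tolerance <= 0:
            raise ValueError("residual tolerance must be positive")
        if self.advection_scheme not in ("upwind", "van-leer-limited"):
            raise ValueError(f"unknown advection scheme {self.advection_scheme!r}")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")


@dataclass
class PatchSeries:
    """Per-facet normal velocity and phase fraction at one boundary patch.

    ``un`` is positive into the domain; rows are snapshot times.
    """

    name: str
    times: np.ndarray
    un: np.ndarray  # (nt, n_facets) [m/s]
    phi: np.ndarray  # (nt, n_facets) [-]
    areas: np.ndarray  # (n_facets,) [m^2]
    diameter: float | None = None

    def flow_rate_series(self) -> np.ndarray:
        """Signed flow rate into the domain [ml/s] at each sample."""
        return self.un @ self.areas * 1e6


@dataclass
class SolveResult:
    """Ordered snapshots plus per-patch boundary series of one run."""

    snapshots: list[FieldSnapshot]
    patch_series: dict[str, PatchSeries]
    geometry: ChamberGeometry
    settings: SolverSettings
    props: FluidProperties
    cycle_period: float

    @property
    def analysis_cycle_snapshots(self) -> list[FieldSnapshot]:
        """Snapshots of the final (analysis) cycle, endpoints included."""
        t_end = self.snapshots[-1].time
        t0 = t_end - self.cycle_period
        return [s for s in self.snapshots if s.time >= t0 - 1e-12]

    def volume_average_series(self, quantity: str = "speed"):
        """Volume-averaged |u| or pressure at each snapshot."""
        from .metrics import TimeSeries

        vals = []
        for s in self.snapshots:
            if quantity == "speed":
                vals.append(float(np.mean(np.sqrt((s.velocity**2).sum(axis=0)))))
            elif quantity == "pressure":
                vals.append(float(np.mean(s.pressure)))
            else:
                raise ValueError(f"unknown quantity {quantity!r}")
        times = np.array([s.time for s in self.snapshots])
        return TimeSeries(quantity, times, np.array(vals), self.cycle_period)

    def reynolds_records(self) -> list[ReynoldsRecord]:
        """Boundary Reynolds summaries over the analysis cycle.

        The characteristic velocity is the patch-averaged normal speed;
        viscosity is the patch- and time-averaged apparent viscosity of
        the wall-adjacent cells.  Min/mean/max are taken over the
        time-varying Reynolds series built with patch-averaged U and mu.
        """
        t_end = self.snapshots[-1].time
        t0 = t_end - self.cycle_period
        mu_patch = _patch_mu_series(self)
        out = []
        for name, ps in self.patch_series.items():
            if ps.diameter is None:
                continue
            mask = ps.times >= t0 - 1e-12
            u_t = np.abs(ps.un[mask]).mean(axis=1)
            mu_t = mu_patch[name][mask]
            re_t = self.props.rho * u_t * ps.diameter / mu_t
            U = float(np.trapezoid(u_t, ps.times[mask]) / self.cycle_period)
            mu_bar = float(np.trapezoid(mu_t, ps.times[mask]) / self.cycle_period)
            out.append(
                ReynoldsRecord(
                    boundary_name=name,
                    U=U,
                    D=ps.diameter,
                    mu_used=mu_bar,
                    re_min=float(re_t.min()),
                    re_mean=self.props.rho * U * ps.diameter / mu_bar,
                    re_max=float(re_t.max()),
                )
            )
        return out


def _patch_mu_series(res: SolveResult) -> dict[str, np.ndarray]:
    """Patch-averaged apparent viscosity per snapshot, per patch."""
    out: dict[str, list[float]] = {n: [] for n in res.patch_series}
    for s in res.snapshots:
        mu = apparent_viscosity(s.shear_rate, res.props)
        for name, ps in res.patch_series.items():
            p = res.geometry.patches[name]
            cells = _adjacent_cells(p, res.geometry)
            out[name].append(float(np.mean(mu[cells])))
    return {n: np.array(v) for n, v in out.items()}


def _adjacent_cells(p: BoundaryPatch, g: ChamberGeometry):
    if p.side == "x-":
        return (0, slice(p.i0, p.i1))
    if p.side == "x+":
        return (g.nx - 1, slice(p.i0, p.i1))
    if p.side == "y-":
        return (slice(p.i0, p.i1), 0)
    return (slice(p.i0, p.i1), g.ny - 1)


# ----------------------------------------------------------------------
# sparse operators


def _assemble_helmholtz(
    m: int,
    k: int,
    lam: float,
    nu_lo0: np.ndarray,
    nu_hi0: np.ndarray,
    nu_lo1: np.ndarray,
    nu_hi1: np.ndarray,
    ax0_periodic: bool,
    ax1_mode: str,  # "ghost" (no-slip reflection) or "periodic"
):
    """Matrix of (I - dt div(nu grad)) for one staggered component.

    Unknowns are laid out on an (m, k) grid; axis 0 is the component's own
    direction (Dirichlet neighbours handled by the caller via the returned
    boundary-coefficient arrays, or periodic), axis 1 is tangential (ghost
    no-slip reflection doubles the wall-side coefficient, or periodic).

    Returns (A_csc, w_lo, w_hi): the matrix and, for non-periodic axis 0,
    the coefficients multiplying the known Dirichlet boundary faces that
    must be added to the right-hand side.
    """
    N = m * k
    I, J = np.meshgrid(np.arange(m), np.arange(k), indexing="ij")
    idx = (I * k + J).ravel()

    diag = 1.0 + lam * (nu_lo0 + nu_hi0 + nu_lo1 + nu_hi1)
    rows = [idx]
    cols = [idx]
    extra_rows, extra_cols, extra_vals = [], [], []
    # axis-1 no-slip ghost: quadratic extrapolation through the wall value,
    # u_ghost = (u_next - 6 u_adj) / 3, which makes the wall flux exact for
    # quadratic profiles (second-order wall shear)
    if ax1_mode == "ghost":
        diag = diag.copy()
        diag[:, 0] += 2.0 * lam * nu_lo1[:, 0]
        diag[:, -1] += 2.0 * lam * nu_hi1[:, -1]
        if k >= 2:
            idx2 = idx.reshape(m, k)
            extra_rows += [idx2[:, 0], idx2[:, -1]]
            extra_cols += [idx2[:, 1], idx2[:, -2]]
            extra_vals += [-lam * nu_lo1[:, 0] / 3.0, -lam * nu_hi1[:, -1] / 3.0]
    vals = [diag.ravel()]

    def add(mask, nbr_idx, coef):
        rows.append(idx.reshape(m, k)[mask].ravel())
        cols.append(nbr_idx[mask].ravel())
        vals.append(-lam * coef[mask].ravel())

    # axis 0 neighbours
    if ax0_periodic:
        lo_nbr = ((I - 1) % m) * k + J
        hi_nbr = ((I + 1) % m) * k + J
        add(np.ones((m, k), bool), lo_nbr, nu_lo0)
        add(np.ones((m, k), bool), hi_nbr, nu_hi0)
        w_lo = w_hi = None
    else:
        lo_nbr = (I - 1) * k + J
        hi_nbr = (I + 1) * k + J
        add(I > 0, lo_nbr, nu_lo0)
        add(I < m - 1, hi_nbr, nu_hi0)
        w_lo = lam * nu_lo0[0, :]  # multiplies Dirichlet face at axis0 low end
        w_hi = lam * nu_hi0[-1, :]
    # axis 1 neighbours
    if ax1_mode == "periodic":
        lo_nbr = I * k + (J - 1) % k
        hi_nbr = I * k + (J + 1) % k
        add(np.ones((m, k), bool), lo_nbr, nu_lo1)
        add(np.ones((m, k), bool), hi_nbr, nu_hi1)
    else:
        lo_nbr = I * k + (J - 1)
        hi_nbr = I * k + (J + 1)
        add(J > 0, lo_nbr, nu_lo1)
        add(J < k - 1, hi_nbr, nu_hi1)

    rows += extra_rows
    cols += extra_cols
    vals += extra_vals
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsc()
    return A, w_lo, w_hi


def _assemble_poisson(nx: int, ny: int, periodic_x: bool):
    """Neumann (compatible) pressure Poisson matrix, cell 0 pinned."""
    N = nx * ny
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    idx = I * ny + J
    rows, cols, vals = [], [], []
    diag = np.zeros((nx, ny))

    def add(mask, nbr):
        rows.append(idx[mask].ravel())
        cols.append(nbr[mask].ravel())
        vals.append(-np.ones(mask.sum()))
        diag[mask] += 1.0

    if periodic_x:
        add(np.ones((nx, ny), bool), ((I - 1) % nx) * ny + J)
        add(np.ones((nx, ny), bool), ((I + 1) % nx) * ny + J)
    else:
        add(I > 0, (I - 1) * ny + J)
        add(I < nx - 1, (I + 1) * ny + J)
    add(J > 0, I * ny + (J - 1))
    add(J < ny - 1, I * ny + (J + 1))
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tolil()
    # pin the gauge: replace the first row by identity
    A.rows[0] = [0]
    A.data[0] = [1.0]
    return A.tocsc()


# ----------------------------------------------------------------------
# boundary handling


def _patch_speed(p: BoundaryPatch, waveform: InletWaveform | None, t: float) -> float:
    """Into-domain normal speed prescribed at a patch at time t."""
    if p.kind == "pressure_outlet":
        return 0.0  # overwritten by the balancing step
    if p.admittance is not None:
        if waveform is None:
            raise ValueError(f"patch {p.name!r} needs an inlet waveform")
        return p.admittance * sample_waveform(waveform, t)
    return p.prescribed_speed or 0.0


def _boundary_values(geom, waveform, t):
    """Dirichlet boundary-face velocities and inflow phase fractions."""
    nx, ny, h = geom.nx, geom.ny, geom.h
    u_lo = np.zeros(ny)  # u at x=0 face, positive = +x (into domain)
    u_hi = np.zeros(ny)  # u at x=Lx face
    v_lo = np.zeros(nx)
    v_hi = np.zeros(nx)
    phi_lo_x = np.zeros(ny)
    phi_hi_x = np.zeros(ny)
    phi_lo_y = np.zeros(nx)
    phi_hi_y = np.zeros(nx)
    outlet = None
    influx = 0.0  # grid flux per unit depth [m^2/s]
    for p in geom.patches.values():
        s = _patch_speed(p, waveform, t)
        if p.kind == "pressure_outlet":
            outlet = p
            continue
        sl = slice(p.i0, p.i1)
        if p.side == "x-":
            u_lo[sl] = s
            phi_lo_x[sl] = p.phi_value
        elif p.side == "x+":
            u_hi[sl] = -s
            phi_hi_x[sl] = p.phi_value
        elif p.side == "y-":
            v_lo[sl] = s
            phi_lo_y[sl] = p.phi_value
        else:
            v_hi[sl] = -s
            phi_hi_y[sl] = p.phi_value
        influx += s * (p.i1 - p.i0) * h
    if outlet is not None:
        # rigid walls: instantaneous balance fixes the outflow speed
        s_out = influx / ((outlet.i1 - outlet.i0) * h)
        sl = slice(outlet.i0, outlet.i1)
        if outlet.side == "x+":
            u_hi[sl] = s_out
        elif outlet.side == "x-":
            u_lo[sl] = -s_out
        elif outlet.side == "y+":
            v_hi[sl] = s_out
        else:
            v_lo[sl] = -s_out
    return (u_lo, u_hi, v_lo, v_hi), (phi_lo_x, phi_hi_x, phi_lo_y, phi_hi_y)


# ----------------------------------------------------------------------
# discrete operators on the MAC grid


def _cell_viscosity(u, v, h, props):
    """Cell-centred shear-rate magnitude and kinematic viscosity."""
    dudx = np.diff(u, axis=0) / h
    dvdy = np.diff(v, axis=1) / h
    # cross derivatives at corners, tangential no-slip ghosts
    u_pad = np.pad(u, ((0, 0), (1, 1)), mode="reflect")
    u_pad[:, 0] = -u[:, 0]
    u_pad[:, -1] = -u[:, -1]
    dudy_c = np.diff(u_pad, axis=1) / h  # (nx+1, ny+1) at corners
    v_pad = np.pad(v, ((1, 1), (0, 0)), mode="reflect")
    v_pad[0, :] = -v[0, :]
    v_pad[-1, :] = -v[-1, :]
    dvdx_c = np.diff(v_pad, axis=0) / h
    cross_c = dudy_c + dvdx_c
    cross = 0.25 * (
        cross_c[:-1, :-1] + cross_c[1:, :-1] + cross_c[:-1, 1:] + cross_c[1:, 1:]
    )
    gamma = np.sqrt(2.0 * dudx**2 + 2.0 * dvdy**2 + cross**2)
    mu = apparent_viscosity(gamma, props)
    return gamma, mu


def _corner_average(nu_cell, periodic_x=False):
    if periodic_x:
        padded = np.pad(nu_cell, ((1, 1), (0, 0)), mode="wrap")
        padded = np.pad(padded, ((0, 0), (1, 1)), mode="edge")
    else:
        padded = np.pad(nu_cell, 1, mode="edge")
    return 0.25 * (
        padded[:-1, :-1] + padded[1:, :-1] + padded[:-1, 1:] + padded[1:, 1:]
    )


def _upwind_advection(u_all, v, h, periodic_x):
    """First-order upwind advection terms at interior u and v faces.

    ``u_all`` is the full face array (nx+1, ny) — in periodic mode the
    last row duplicates the first.  Returns ``adv_u`` at the u unknowns
    ((nx, ny) periodic, (nx-1, ny) otherwise) and ``adv_v`` at (nx, ny-1).
    """
    if periodic_x:
        u = u_all[:-1, :]  # (nx, ny), faces 0..nx-1
        ui, uw, ue = u, np.roll(u, 1, axis=0), np.roll(u, -1, axis=0)
        vw = np.roll(v, 1, axis=0)
        v_at_u = 0.25 * (vw[:, :-1] + v[:, :-1] + vw[:, 1:] + v[:, 1:])
        u_pad = np.pad(u, ((0, 0), (1, 1)), mode="edge")
    else:
        u = u_all
        ui, uw, ue = u[1:-1, :], u[:-2, :], u[2:, :]
        v_at_u = 0.25 * (v[:-1, :-1] + v[1:, :-1] + v[:-1, 1:] + v[1:, 1:])
        u_pad = np.pad(ui, ((0, 0), (1, 1)), mode="edge")
    u_pad[:, 0] = -u_pad[:, 1]  # no-slip ghost below the wall
    u_pad[:, -1] = -u_pad[:, -2]
    dudx = np.where(ui > 0, (ui - uw) / h, (ue - ui) / h)
    dudy = np.where(
        v_at_u > 0,
        (u_pad[:, 1:-1] - u_pad[:, :-2]) / h,
        (u_pad[:, 2:] - u_pad[:, 1:-1]) / h,
    )
    adv_u = ui * dudx + v_at_u * dudy

    vi, vs, vn = v[:, 1:-1], v[:, :-2], v[:, 2:]
    dvdy = np.where(vi > 0, (vi - vs) / h, (vn - vi) / h)
    if periodic_x:
        u_ = u_all[:-1, :]
        ue_ = np.roll(u_, -1, axis=0)
        u_at_v = 0.25 * (u_[:, :-1] + u_[:, 1:] + ue_[:, :-1] + ue_[:, 1:])
        v_pad = np.pad(v[:, 1:-1], ((1, 1), (0, 0)), mode="wrap")
    else:
        u_at_v = 0.25 * (
            u_all[:-1, :-1] + u_all[:-1, 1:] + u_all[1:, :-1] + u_all[1:, 1:]
        )
        v_pad = np.pad(v[:, 1:-1], ((1, 1), (0, 0)), mode="edge")
        v_pad[0, :] = -v_pad[1, :]
        v_pad[-1, :] = -v_pad[-2, :]
    dvdx = np.where(
        u_at_v > 0,
        (v_pad[1:-1, :] - v_pad[:-2, :]) / h,
        (v_pad[2:, :] - v_pad[1:-1, :]) / h,
    )
    adv_v = u_at_v * dvdx + vi * dvdy
    return adv_u, adv_v


def _advect_phi(phi, u, v, dt, h, phi_bc, scheme):
    """Conservative bounded advection of the phase fraction.

    ``u, v`` are the divergence-free face velocities (boundary faces
    included); ``phi_bc`` gives the inflow fractions on the four walls.
    Donor-cell upwind is provably bounded for divergence-free velocities
    at CFL <= 1; the van Leer variant adds limited antidiffusive fluxes
    clipped by a Zalesak FCT step, preserving the bound.
    """
    nx, ny = phi.shape
    phi_lo_x, phi_hi_x, phi_lo_y, phi_hi_y = phi_bc

    # upstream states at x-faces (nx+1, ny) and y-faces (nx, ny+1)
    phix = np.empty((nx + 1, ny))
    phix[1:-1] = np.where(u[1:-1] > 0, phi[:-1], phi[1:])
    phix[0] = np.where(u[0] > 0, phi_lo_x, phi[0])
    phix[-1] = np.where(u[-1] < 0, phi_hi_x, phi[-1])
    phiy = np.empty((nx, ny + 1))
    phiy[:, 1:-1] = np.where(v[:, 1:-1] > 0, phi[:, :-1], phi[:, 1:])
    phiy[:, 0] = np.where(v[:, 0] > 0, phi_lo_y, phi[:, 0])
    phiy[:, -1] = np.where(v[:, -1] < 0, phi_hi_y, phi[:, -1])
    F_L = u * phix
    G_L = v * phiy
    phi_td = phi - dt / h * (np.diff(F_L, axis=0) + np.diff(G_L, axis=1))

    if scheme == "upwind":
        return phi_td

    # van Leer limited slopes (zero-slope ghosts at boundaries)
    def limited_slope(q, axis):
        dq = np.diff(q, axis=axis)
        pad = [(0, 0), (0, 0)]
        pad[axis] = (1, 1)
        dq = np.pad(dq, pad)  # zero-gradient beyond walls
        a = np.take(dq, range(0, q.shape[axis]), axis=axis)
        b = np.take(dq, range(1, q.shape[axis] + 1), axis=axis)
        denom = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(a * b > 0, 2.0 * a * b / np.where(denom == 0, 1.0, denom), 0.0)
        return s

    sx = limited_slope(phi, 0)
    sy = limited_slope(phi, 1)
    cu = np.abs(u[1:-1]) * dt / h
    cv = np.abs(v[:, 1:-1]) * dt / h
    phix_H = phix.copy()
    phix_H[1:-1] = np.where(
        u[1:-1] > 0,
        phi[:-1] + 0.5 * (1 - cu) * sx[:-1],
        phi[1:] - 0.5 * (1 - cu) * sx[1:],
    )
    phiy_H = phiy.copy()
    phiy_H[:, 1:-1] = np.where(
        v[:, 1:-1] > 0,
        phi[:, :-1] + 0.5 * (1 - cv) * sy[:, :-1],
        phi[:, 1:] - 0.5 * (1 - cv) * sy[:, 1:],
    )
    A_x = u * (phix_H - phix)
    A_y = v * (phiy_H - phiy)

    # Zalesak limiter against the local extrema of phi and phi_td
    pad_td = np.pad(phi_td, 1, mode="edge")
    pad_n = np.pad(phi, 1, mode="edge")
    stack = [pad_td, pad_n]
    neigh_max = np.maximum.reduce(
        [np.maximum(s[1:-1, 1:-1], np.maximum.reduce([
            s[:-2, 1:-1], s[2:, 1:-1], s[1:-1, :-2], s[1:-1, 2:]
        ])) for s in stack]
    )
    neigh_min = np.minimum.reduce(
        [np.minimum(s[1:-1, 1:-1], np.minimum.reduce([
            s[:-2, 1:-1], s[2:, 1:-1], s[1:-1, :-2], s[1:-1, 2:]
        ])) for s in stack]
    )
    # antidiffusive flux into each cell
    P_plus = (
        np.maximum(A_x[:-1], 0) - np.minimum(A_x[1:], 0)
        + np.maximum(A_y[:, :-1], 0) - np.minimum(A_y[:, 1:], 0)
    ) * dt / h
    P_minus = (
        np.maximum(A_x[1:], 0) - np.minimum(A_x[:-1], 0)
        + np.maximum(A_y[:, 1:], 0) - np.minimum(A_y[:, :-1], 0)
    ) * dt / h
    Q_plus = neigh_max - phi_td
    Q_minus = phi_td - neigh_min
    with np.errstate(divide="ignore", invalid="ignore"):
        R_plus = np.where(P_plus > 0, np.minimum(1.0, Q_plus / np.where(P_plus == 0, 1, P_plus)), 0.0)
        R_minus = np.where(P_minus > 0, np.minimum(1.0, Q_minus / np.where(P_minus == 0, 1, P_minus)), 0.0)

    Cx = np.ones_like(A_x)
    pos = A_x[1:-1] >= 0
    Cx[1:-1] = np.where(pos, np.minimum(R_plus[1:], R_minus[:-1]), np.minimum(R_plus[:-1], R_minus[1:]))
    Cx[0] = 0.0
    Cx[-1] = 0.0
    Cy = np.ones_like(A_y)
    pos = A_y[:, 1:-1] >= 0
    Cy[:, 1:-1] = np.where(pos, np.minimum(R_plus[:, 1:], R_minus[:, :-1]), np.minimum(R_plus[:, :-1], R_minus[:, 1:]))
    Cy[:, 0] = 0.0
    Cy[:, -1] = 0.0

    return phi_td - dt / h * (np.diff(Cx * A_x, axis=0) + np.diff(Cy * A_y, axis=1))


# ----------------------------------------------------------------------
# main driver


def solve_transient(
    geom: ChamberGeometry,
    props: FluidProperties | None = None,
    waveform: InletWaveform | None = None,
    catheter: CatheterConfig | None = None,
    settings: SolverSettings | None = None,
    periodic_x: bool = False,
) -> SolveResult:
    """Run the transient chamber simulation.

    When ``catheter`` is given it is placed into (a copy of) the geometry
    first and the phase scalar is tracked (sourced at 1 on the venous
    patch, 0 at the caval inlets).  Snapshots are emitted every
    ``settings.snapshot_stride`` steps plus the initial and final states.
    """
    if props is None:
        props = FluidProperties()
    if settings is None:
        settings = SolverSettings()
    if catheter is not None:
        geom = place_catheter(geom, catheter)
    multiphase = geom.catheter is not None
    dt = settings.dt if settings.dt is not None else (
        C.DT_MULTIPHASE if multiphase else C.DT_SINGLE_PHASE
    )
    period = waveform.cycle.period if waveform is not None else C.CYCLE_PERIOD
    t_end = settings.end_time if settings.end_time is not None else settings.n_cycles * period
    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > 1e-9:
        n_steps = int(np.ceil(t_end / dt))
    nx, ny, h = geom.nx, geom.ny, geom.h
    rho = props.rho

    u = np.zeros((nx, ny)) if periodic_x else np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p_cells = np.zeros((nx, ny))
    phi = np.zeros((nx, ny))
    if settings.init_perturbation > 0:
        rng = np.random.default_rng(settings.seed)
        u += settings.init_perturbation * rng.standard_normal(u.shape)
        v += settings.init_perturbation * rng.standard_normal(v.shape)
        if not periodic_x:
            u[0, :] = u[-1, :] = 0.0
        v[:, 0] = v[:, -1] = 0.0

    poisson = splu(_assemble_poisson(nx, ny, periodic_x))
    lam = dt / h**2
    fx, fy = settings.body_force

    snapshots: list[FieldSnapshot] = []
    series_t: list[float] = []
    series_un: dict[str, list[np.ndarray]] = {n: [] for n in geom.patches if geom.patches[n].kind != "wall"}
    series_phi: dict[str, list[np.ndarray]] = {n: [] for n in series_un}

    def record(t):
        gamma, _ = _cell_viscosity(u_full(), v, h, props)
        uc = 0.5 * (u_full()[:-1, :] + u_full()[1:, :])
        vc = 0.5 * (v[:, :-1] + v[:, 1:])
        snapshots.append(
            FieldSnapshot(
                time=t,
                h=h,
                velocity=np.stack([uc, vc]),
                pressure=p_cells.copy(),
                phi_r=phi.copy() if multiphase else None,
                shear_rate=gamma,
                u_face=u_full().copy(),
                v_face=v.copy(),
            )
        )
        series_t.append(t)
        for name in series_un:
            pch = geom.patches[name]
            sl = slice(pch.i0, pch.i1)
            if pch.side == "x-":
                un = u_full()[0, sl]
                ph = phi[0, sl]
            elif pch.side == "x+":
                un = -u_full()[-1, sl]
                ph = phi[-1, sl]
            elif pch.side == "y-":
                un = v[sl, 0]
                ph = phi[sl, 0]
            else:
                un = -v[sl, -1]
                ph = phi[sl, -1]
            # inflow facets carry the prescribed inflow fraction
            ph = np.where(un > 0, pch.phi_value, ph) if multiphase else np.zeros_like(un)
            series_un[name].append(np.asarray(un, dtype=float).copy())
            series_phi[name].append(np.asarray(ph, dtype=float).copy())

    def u_full():
        if periodic_x:
            return np.vstack([u, u[:1, :]])  # face nx duplicates face 0
        return u

    t = 0.0
    record(t)
    for step in range(n_steps):
        t_new = (step + 1) * dt
        if periodic_x:
            bc_u = (None, None, np.zeros(nx), np.zeros(nx))
            phi_bc = (np.zeros(ny), np.zeros(ny), np.zeros(nx), np.zeros(nx))
            u_lo = u_hi = None
            v_lo, v_hi = bc_u[2], bc_u[3]
        else:
            (u_lo, u_hi, v_lo, v_hi), phi_bc = _boundary_values(geom, waveform, t_new)

        # CFL control (|u|+|v| bound keeps donor-cell transport a convex
        # combination); sub-step if the Courant number is too big
        vmax = max(np.abs(u).max() + np.abs(v).max(), 1e-30)
        n_sub = 1
        if vmax * dt / h > settings.cfl_cap:
            if not settings.adaptive_substepping:
                raise RuntimeError(
                    f"CFL violation at t={t_new:.4f}s: C={vmax * dt / h:.2f} "
                    f"> cap {settings.cfl_cap}"
                )
            n_sub = int(np.ceil(vmax * dt / (h * settings.cfl_cap)))
        dts = dt / n_sub

        for _ in range(n_sub):
            gamma, mu = _cell_viscosity(u_full(), v, h, props)
            nu = mu / rho
            nu_c = _corner_average(nu, periodic_x)
            lam_s = dts / h**2

            adv_u, adv_v = _upwind_advection(u_full(), v, h, periodic_x)

            # --- u momentum ---
            if periodic_x:
                m, k = nx, ny
                nu_w = np.roll(nu, 1, axis=0)
                nu_e = nu
                nu_s = nu_c[:nx, :-1]
                nu_n = nu_c[:nx, 1:]
                A, _, _ = _assemble_helmholtz(m, k, lam_s, nu_w, nu_e, nu_s, nu_n, True, "ghost")
                rhs = (u - dts * adv_u + dts * fx).ravel()
                u = splu(A).solve(rhs).reshape(m, k)
            else:
                m, k = nx - 1, ny
                nu_w = nu[:-1, :]
                nu_e = nu[1:, :]
                nu_s = nu_c[1:-1, :-1]
                nu_n = nu_c[1:-1, 1:]
                A, w_lo, w_hi = _assemble_helmholtz(m, k, lam_s, nu_w, nu_e, nu_s, nu_n, False, "ghost")
                rhs = u[1:-1, :] - dts * adv_u + dts * fx
                rhs[0, :] += w_lo * u_lo
                rhs[-1, :] += w_hi * u_hi
                u_int = splu(A).solve(rhs.ravel()).reshape(m, k)
                u = np.vstack([u_lo[np.newaxis, :], u_int, u_hi[np.newaxis, :]])

            # --- v momentum (axis 0 = y) ---
            m, k = ny - 1, nx
            nu_s_ = nu[:, :-1].T
            nu_n_ = nu[:, 1:].T
            nu_w_ = nu_c[:-1, 1:-1].T
            nu_e_ = nu_c[1:, 1:-1].T
            ax1 = "periodic" if periodic_x else "ghost"
            A, w_lo, w_hi = _assemble_helmholtz(m, k, lam_s, nu_s_, nu_n_, nu_w_, nu_e_, False, ax1)
            rhs = (v[:, 1:-1] - dts * adv_v + dts * fy).T
            rhs[0, :] += w_lo * v_lo
            rhs[-1, :] += w_hi * v_hi
            v_int = splu(A).solve(rhs.ravel()).reshape(m, k).T
            v = np.hstack([v_lo[:, np.newaxis], v_int, v_hi[:, np.newaxis]])

            # --- projection ---
            div = (np.diff(u_full(), axis=0) + np.diff(v, axis=1)) / h
            # A represents -h^2 * discrete Laplacian, so A p = -(rho/dt) h^2 div
            rhs_p = -(rho / dts) * div.ravel() * h**2
            rhs_p[0] = 0.0
            p_flat = poisson.solve(rhs_p)
            p_cells = p_flat.reshape(nx, ny)
            p_cells -= p_cells.mean()
            gradx = np.diff(p_cells, axis=0) / h
            if periodic_x:
                gradx_all = (p_cells - np.roll(p_cells, 1, axis=0)) / h
                u = u - dts / rho * gradx_all
            else:
                u[1:-1, :] -= dts / rho * gradx
            v[:, 1:-1] -= dts / rho * np.diff(p_cells, axis=1) / h

            # --- residual check on continuity ---
            div_new = (np.diff(u_full(), axis=0) + np.diff(v, axis=1)) / h
            if not np.all(np.isfinite(div_new)):
                raise RuntimeError(f"pressure solve diverged at t={t_new:.4f}s")
            vel_scale = max(np.abs(u).max(), np.abs(v).max(), 1e-9)
            res = np.abs(div_new).max() * h / vel_scale
            if res > max(settings.residual_tolerance, 1e-8) * 100:
                raise RuntimeError(
                    f"continuity residual {res:.2e} exceeds tolerance at t={t_new:.4f}s"
                )

            # --- phase transport ---
            if multiphase:
                phi = _advect_phi(phi, u_full(), v, dts, h, phi_bc, settings.advection_scheme)
                # the scheme is bounds-preserving in exact arithmetic; only
                # round-off-level excursions are tolerated (and removed)
                viol = max(0.0, float(-phi.min()), float(phi.max() - 1.0))
                if viol > 1e-12:
                    raise RuntimeError(
                        f"phase fraction left [0,1] by {viol:.2e} at t={t_new:.4f}s"
                    )
                np.clip(phi, 0.0, 1.0, out=phi)

        t = t_new
        if (step + 1) % settings.snapshot_stride == 0 or step == n_steps - 1:
            record(t)

    ps = {}
    for name in series_un:
        pch = geom.patches[name]
        ps[name] = PatchSeries(
            name=name,
            times=np.array(series_t),
            un=np.array(series_un[name]),
            phi=np.array(series_phi[name]),
            areas=pch.areas.copy(),
            diameter=pch.diameter,
        )
    return SolveResult(
        snapshots=snapshots,
        patch_series=ps,
        geometry=geom,
        settings=settings,
        props=props,
        cycle_period=period,
    )


# ----------------------------------------------------------------------
# temporal convergence


def cycle_averages(series, period: float | None = None) -> np.ndarray:
    """Trapezoidal mean of a series over each successive full cycle."""
    T = period if period is not None else series.cycle_period
    if T is None:
        raise ValueError("cycle period required")
    t, x = series.times, series.values
    n_cycles = int(round((t[-1] - t[0]) / T))
    if n_cycles < 1:
        raise ValueError("series shorter than one cycle")
    out = []
    for c in range(n_cycles):
        lo = t[0] + c * T
        hi = lo + T
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if mask.sum() < 2:
            raise ValueError(f"cycle {c + 1} has too few samples")
        out.append(np.trapezoid(x[mask], t[mask]) / (t[mask][-1] - t[mask][0]))
    return np.array(out)


def check_temporal_convergence(
    cycle_values: dict[str, np.ndarray],
    ref_cycle: int | None = None,
    threshold_pct: float | None = None,
) -> pd.DataFrame:
    """Cycle-to-cycle relative error E = |v_B - v_L| / |v_L| * 100.

    ``cycle_values`` maps quantity names to per-cycle values (1-based
    cycles in the output).  ``ref_cycle`` is the 1-based reference cycle,
    by default the last one.  With ``threshold_pct`` set, a
    ``converged`` column flags cycles where every quantity's error is at
    or below the threshold.
    """
    lengths = {len(np.atleast_1d(v)) for v in cycle_values.values()}
    if len(lengths) != 1:
        raise ValueError("all quantities must have the same number of cycles")
    n = lengths.pop()
    if n < 2:
        raise ValueError("temporal convergence needs at least 2 cycles")
    ref = n if ref_cycle is None else ref_cycle
    if not (1 <= ref <= n):
        raise ValueError(f"ref_cycle {ref} out of range 1..{n}")
    rows = []
    for name, vals in cycle_values.items():
        vals = np.atleast_1d(np.asarray(vals, dtype=float))
        v_ref = vals[ref - 1]
        if v_ref == 0:
            raise ZeroDivisionError(
                f"reference value for {name!r} is zero; relative error undefined"
            )
        for c in range(n):
            rows.append(
                {
                    "cycle": c + 1,
                    "quantity": name,
                    "value": vals[c],
                    "E_pct": abs((vals[c] - v_ref) / v_ref) * 100.0,
                }
            )
    df = pd.DataFrame(rows)
    if threshold_pct is not None:
        ok = df.groupby("cycle")["E_pct"].max() <= threshold_pct
        df["converged"] = df["cycle"].map(ok)
    return df
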