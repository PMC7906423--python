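"""Seeded generators with analytically known ground truth.

Every input class the pipeline consumes can be synthesised here: analytic
velocity fields with closed-form vorticity/strain/WSS, outlet phase
patterns with an exactly planted recirculation fraction, multi-cycle
pulsatile series with planted cycle-convergence errors and an exactly
planted Pearson correlation, and mock supplementary spreadsheets in the
on-disk schema the validation module reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .fields import FieldSnapshot

__all__ = [
    "GeneratorSpec",
    "make_field",
    "make_phase_pattern",
    "make_pulsatile_series",
    "make_correlated_pair",
    "make_supplementary_mock",
]

FIELD_KINDS = (
    "poiseuille",
    "rigid_rotation",
    "taylor_green",
    "uniform_jet",
    "beltrami",
)


@dataclass
class GeneratorSpec:
    """What to generate and with which parameters; ``seed`` fixes all draws."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _centers(n: int, L: float, origin: float = 0.0) -> np.ndarray:
    h = L / n
    return origin + (np.arange(n) + 0.5) * h


def make_field(spec: GeneratorSpec) -> FieldSnapshot:
    """Sample an analytic velocity field on a uniform grid.

    The snapshot's ``ground_truth`` dict carries the closed-form values
    (vorticity magnitude, strain magnitude, wall shear stress, ...) the
    discrete operators are checked against.

    Kinds and their parameters
    --------------------------
    poiseuille : U_max, H (channel height [m]), mu, n (grid), aspect
        Plane channel flow u(y) = 4 U_max y (H - y) / H^2; walls at
        ``y-`` and ``y+``; WSS = 4 mu U_max / H.
    rigid_rotation : omega (rate Omega [1/s]), L, n, ndim (2 or 3)
        u = Omega x r; vorticity magnitude 2 Omega everywhere.
    taylor_green : A, kx (integer wavenumber), n; domain [0, 2 pi]^2
        u = A cos(kx x) sin(kx y), v = -A sin(kx x) cos(kx y);
        divergence-free, omega_z = -2 A kx cos(kx x) cos(kx y).
    uniform_jet : u (velocity tuple), L, n, ndim
        Constant velocity; zero vorticity and strain.
    beltrami : A, B, Cc, n; ABC flow on [0, 2 pi]^3
        curl u = u, so helicity density equals |u|^2.
    """
    p = dict(spec.params)
    kind = spec.kind
    if kind == "poiseuille":
        U = p.get("U_max", 0.5)
        H = p.get("H", 0.02)
        mu = p.get("mu", C.NEWTONIAN_MU)
        n = p.get("n", 32)
        aspect = p.get("aspect", 2)
        h = H / n
        nx = n * aspect
        y = _centers(n, H)
        u = 4.0 * U * y * (H - y) / H**2
        vel = np.stack([np.tile(u, (nx, 1)), np.zeros((nx, n))])
        return FieldSnapshot(
            time=0.0,
            h=h,
            velocity=vel,
            ground_truth={
                "wss": 4.0 * mu * U / H,
                "mu": mu,
                "U_max": U,
                "H": H,
                "flow_rate_per_depth": 2.0 / 3.0 * U * H,
                "vorticity_mag": np.abs(np.tile(4.0 * U * (H - 2 * y) / H**2, (nx, 1))),
            },
        )
    if kind == "rigid_rotation":
        om = p.get("omega", 5.0)
        L = p.get("L", 1.0)
        n = p.get("n", 32)
        ndim = p.get("ndim", 2)
        h = L / n
        c = _centers(n, L, origin=-L / 2)
        if ndim == 2:
            X, Y = np.meshgrid(c, c, indexing="ij")
            vel = np.stack([-om * Y, om * X])
        else:
            X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
            vel = np.stack([-om * Y, om * X, np.zeros_like(X)])
        return FieldSnapshot(
            time=0.0,
            h=h,
            velocity=vel,
            origin=(-L / 2,) * ndim,
            ground_truth={"vorticity_mag": 2.0 * abs(om), "strain_mag": 0.0},
        )
    if kind == "taylor_green":
        A = p.get("A", 1.0)
        kx = p.get("kx", 1)
        n = p.get("n", 64)
        L = 2.0 * math.pi
        h = L / n
        c = _centers(n, L)
        X, Y = np.meshgrid(c, c, indexing="ij")
        vel = np.stack(
            [A * np.cos(kx * X) * np.sin(kx * Y), -A * np.sin(kx * X) * np.cos(kx * Y)]
        )
        return FieldSnapshot(
            time=0.0,
            h=h,
            velocity=vel,
            ground_truth={
                "vorticity_z": -2.0 * A * kx * np.cos(kx * X) * np.cos(kx * Y),
                "divergence": 0.0,
            },
        )
    if kind == "uniform_jet":
        uvec = tuple(p.get("u", (1.0, 0.0)))
        L = p.get("L", 1.0)
        n = p.get("n", 16)
        ndim = p.get("ndim", len(uvec))
        h = L / n
        shape = (n,) * ndim
        vel = np.stack([np.full(shape, comp) for comp in uvec])
        return FieldSnapshot(
            time=0.0,
            h=h,
            velocity=vel,
            ground_truth={"vorticity_mag": 0.0, "strain_mag": 0.0},
        )
    if kind == "beltrami":
        A = p.get("A", 1.0)
        B = p.get("B", math.sqrt(2.0 / 3.0))
        Cc = p.get("Cc", math.sqrt(1.0 / 3.0))
        n = p.get("n", 32)
        L = 2.0 * math.pi
        h = L / n
        c = _centers(n, L)
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        vel = np.stack(
            [
                A * np.sin(Z) + Cc * np.cos(Y),
                B * np.sin(X) + A * np.cos(Z),
                Cc * np.sin(Y) + B * np.cos(X),
            ]
        )
        return FieldSnapshot(
            time=0.0,
            h=h,
            velocity=vel,
            ground_truth={"helicity": (vel**2).sum(axis=0), "eigenvalue": 1.0},
        )
    raise ValueError(f"unknown field kind {spec.kind!r}; expected one of {FIELD_KINDS}")


def make_phase_pattern(
    rf_target: float,
    n_facets: int = 8,
    n_times: int = 41,
    period: float = C.CYCLE_PERIOD,
    seed: int = 0,
    rho: float = C.BLOOD_DENSITY,
):
    """Outlet-patch phase-fraction series with an exactly planted Rf [%].

    Facet mass flows are heterogeneous random draws; per-facet
    time-averaged fractions are constructed so the mass-weighted average
    equals ``rf_target`` exactly, then turned into time series whose
    trapezoidal mean over the uniform periodic grid reproduces each
    average exactly (a zero-mean sinusoid is added on top).

    Returns ``(times, phi, un, areas)`` ready for
    :func:`atriumflow.metrics.recirculation_fraction`.
    """
    if not (0.0 <= rf_target <= 100.0):
        raise ValueError("planted Rf must lie in [0, 100] %")
    rng = np.random.default_rng(seed)
    areas = rng.uniform(0.5, 2.0, n_facets) * 1e-6  # m^2
    un = rng.uniform(0.1, 1.0, n_facets)  # m/s, uniform in time
    target = rf_target / 100.0
    x = rng.uniform(0.0, 1.0, n_facets)
    mdot = rho * un * areas
    mean_w = float(x @ mdot / mdot.sum())
    if target == 0.0:
        phi_bar = np.zeros(n_facets)
    elif target == 1.0:
        phi_bar = np.ones(n_facets)
    elif target <= mean_w:
        phi_bar = x * (target / mean_w)
    else:
        phi_bar = 1.0 - (1.0 - x) * ((1.0 - target) / (1.0 - mean_w))
    times = np.linspace(0.0, period, n_times)
    amp = np.minimum(phi_bar, 1.0 - phi_bar) * rng.uniform(0.0, 0.9, n_facets)
    # a full-period sinusoid has an exactly zero trapezoidal mean on this grid
    wiggle = np.sin(2.0 * np.pi * times[:, None] / period) * amp[None, :]
    phi = phi_bar[None, :] + wiggle
    return times, phi, np.broadcast_to(un, (n_times, n_facets)).copy(), areas


def make_pulsatile_series(
    planted_errors_pct,
    ref_value: float = 1.0,
    period: float = C.CYCLE_PERIOD,
    samples_per_cycle: int = 40,
    name: str = "velocity",
    seed: int = 0,
    signs=None,
):
    """Multi-cycle series whose per-cycle convergence errors are planted.

    ``planted_errors_pct[c]`` is the relative error (Eq.-style,
    ``|v_c - v_ref| / |v_ref| * 100``) of cycle ``c + 1`` against the last
    cycle; the final entry must be 0.  Within each cycle the series is the
    cycle value plus a zero-mean (trapezoid-exact) sinusoid, so per-cycle
    trapezoidal averages reproduce the planted values exactly.
    """
    from .metrics import TimeSeries

    errs = np.asarray(planted_errors_pct, dtype=float)
    if errs.ndim != 1 or len(errs) < 2:
        raise ValueError("need planted errors for at least 2 cycles")
    if errs[-1] != 0.0:
        raise ValueError("the last (reference) cycle must have error 0")
    if np.any(errs < 0):
        raise ValueError("relative errors must be non-negative")
    if ref_value == 0:
        raise ValueError("reference value must be non-zero")
    rng = np.random.default_rng(seed)
    if signs is None:
        signs = rng.choice([-1.0, 1.0], size=len(errs))
    cycle_vals = ref_value * (1.0 + np.asarray(signs) * errs / 100.0)
    n_c = len(errs)
    spc = samples_per_cycle
    times = np.linspace(0.0, n_c * period, n_c * spc + 1)
    values = np.empty_like(times)
    amp = 0.05 * abs(ref_value)
    # cycle-boundary samples are shared by two trapezoids; choose them so
    # each cycle's half-weighted ends average to that cycle's value, making
    # every per-cycle trapezoidal mean exact: (b_c + b_{c+1})/2 = V_c
    b = np.empty(n_c + 1)
    b[0] = cycle_vals[0]
    for c in range(n_c):
        b[c + 1] = 2.0 * cycle_vals[c] - b[c]
    for c in range(n_c):
        sl = slice(c * spc, (c + 1) * spc + 1)
        tt = times[sl]
        values[sl] = cycle_vals[c] + amp * np.sin(2.0 * np.pi * (tt - c * period) / period)
        values[c * spc] = b[c]
        values[(c + 1) * spc] = b[c + 1]
    return TimeSeries(name, times, values, cycle_period=period), cycle_vals


def make_correlated_pair(
    target_r: float,
    n: int = 1000,
    seed: int = 0,
    mean_x: float = 0.0,
    std_x: float = 1.0,
    mean_y: float = 0.0,
    std_y: float = 1.0,
):
    """Two series whose *sample* Pearson correlation equals ``target_r``
    exactly.

    The second series is built from the first by Gram-Schmidt: an
    independent Gaussian draw is orthogonalised against the first and the
    two are mixed as ``r x + sqrt(1 - r^2) z``, which fixes the sample
    statistic (not just its expectation).  Affine transforms then set the
    requested means and standard deviations without changing r.
    """
    if not (-1.0 < target_r < 1.0):
        raise ValueError("target correlation must lie in (-1, 1)")
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    xc = (x - x.mean()) / x.std()
    zc = z - z.mean()
    zc -= (zc @ xc) / (xc @ xc) * xc
    zc /= zc.std()
    y = target_r * xc + math.sqrt(1.0 - target_r**2) * zc
    y = (y - y.mean()) / y.std()
    return mean_x + std_x * xc, mean_y + std_y * y


def make_supplementary_mock(
    out_dir,
    seed: int = 0,
    fmt: str = "xlsx",
    period: float = C.CYCLE_PERIOD,
    n_cycles: int = 7,
    samples_per_cycle: int = 40,
):
    """Write mock supplementary time-series files with planted statistics.

    Emulates the content classes of the study's supplementary spreadsheets
    in the exact on-disk schema :func:`atriumflow.validation.recompute_supplementary`
    reads:

    * ``cycle_convergence`` — volume-averaged velocity/pressure per cycle,
      planted so the analysis cycle (4) has errors 1.28% / 4.12% against
      the reference cycle (7);
    * ``boundary_flows`` — per-boundary velocity and area series whose
      systolic flow-rate peaks are 106 (IVC), 120 (SVC) and 225 (TV) ml/s;
    * ``wss_vorticity`` — spatially averaged WSS and volume-averaged
      vorticity series with sample correlation exactly 0.87 and a
      cycle-averaged vorticity of exactly 44.1 1/s;
    * ``tip_shear`` — per-design tip shear series whose time averages are
      the per-design values (A1 12.90 Pa, ...).

    Returns the mapping of logical name to written path.  These are
    synthetic stand-ins generated with planted ground truth, not the
    study's data.
    """
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ext = {"xlsx": ".xlsx", "csv": ".csv"}[fmt]

    def write(df, name):
        path = out / f"{name}{ext}"
        if fmt == "xlsx":
            df.to_excel(path, index=False)
        else:
            df.to_csv(path, index=False)
        return path

    paths = {}

    # --- per-cycle velocity / pressure convergence ---
    vel_err = np.array([6.0, 3.5, 2.0, 1.28, 0.8, 0.4, 0.0])[:n_cycles]
    prs_err = np.array([9.0, 6.5, 5.0, 4.12, 2.5, 1.2, 0.0])[:n_cycles]
    v_ref, p_ref = 0.192, 1.18
    df = pd.DataFrame(
        {
            "cycle": np.arange(1, n_cycles + 1),
            "velocity": v_ref * (1.0 - vel_err / 100.0),
            "pressure": p_ref * (1.0 + prs_err / 100.0),
        }
    )
    paths["cycle_convergence"] = write(df, "cycle_convergence")

    # --- boundary velocity * area series with planted peak flows ---
    t = np.linspace(0.0, period, samples_per_cycle + 1)
    systole_frac = 0.45
    bump = np.exp(-0.5 * ((t / period - systole_frac) / 0.08) ** 2)
    bump2 = np.exp(-0.5 * ((t / period - 0.9) / 0.08) ** 2)
    shape = bump + 0.5 * bump2
    shape /= shape.max()
    rows = {"time": t}
    areas = {
        "svc": math.pi * C.SVC_DIAMETER**2 / 4,
        "ivc": math.pi * C.IVC_DIAMETER**2 / 4,
        "tv": C.TV_AREA,
    }
    peaks_ml_s = {"svc": 120.0, "ivc": 106.0, "tv": 225.0}
    for b, area in areas.items():
        u_peak = peaks_ml_s[b] * 1e-6 / area
        rows[f"{b}_velocity"] = u_peak * (0.25 + 0.75 * shape)
        rows[f"{b}_area"] = np.full_like(t, area)
    paths["boundary_flows"] = write(pd.DataFrame(rows), "boundary_flows")

    # --- WSS / vorticity pair with exact correlation and vorticity mean ---
    n = samples_per_cycle + 1
    wss, vort = make_correlated_pair(
        0.87, n=n, seed=seed + 1, mean_x=1.89, std_x=0.15, mean_y=44.1, std_y=8.0
    )
    # constant shift (affine, r-preserving) so the *trapezoidal* cycle mean
    # of vorticity is exactly 44.1
    vort = vort + (44.1 - np.trapezoid(vort, t) / period)
    paths["wss_vorticity"] = write(
        pd.DataFrame({"time": t, "wss": wss, "vorticity": vort}), "wss_vorticity"
    )

    # --- per-design tip shear with planted time averages ---
    tip_means = {"A1": 12.90, "A2": 15.50, "A3": 13.70, "B": 13.80,
                 "C": 11.20, "D1": 11.60, "D2": 10.20}
    rows = {"time": t}
    for model, m in tip_means.items():
        wiggle = 0.1 * m * np.sin(2.0 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
        rows[model] = m + wiggle  # full-period sinusoid: trapezoid mean exact
    paths["tip_shear"] = write(pd.DataFrame(rows), "tip_shear")
    return paths
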