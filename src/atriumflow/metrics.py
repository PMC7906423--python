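"""Derived haemodynamic quantities.

Vorticity, helicity density, strain rate and shear stress, wall shear
stress, boundary flow rates, the recirculation fraction of the filtered
phase, tip-volume shear statistics, and the time/volume averaging and
correlation utilities used to compare catheter designs.

Conventions
-----------
* Vorticity is the curl of the velocity field, by central differences.
* The strain-rate magnitude is ``|eps| = sqrt(2 eps_ij eps_ij)`` with
  ``eps_ij = (d u_j / d x_i + d u_i / d x_j) / 2``; for simple shear with
  rate ``g`` this reduces to ``|eps| = g``, so the shear rate fed to the
  generalized-Newtonian viscosity is identified with ``|eps|`` and the
  stress is ``tau = mu(|eps|) |eps|``.
* The recirculation fraction is the mass-weighted, time-averaged fraction
  of filtered blood crossing the arterial intake:
  ``Rf = (1/mdot_T) sum_k phibar_k mdot_k`` with
  ``phibar_k = (1/T) int phi_r dt`` and ``mdot_k = rho (u_k . A_k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .fields import FieldSnapshot
from .geometry import TipVolume
from .rheology import FluidProperties, apparent_viscosity

__all__ = [
    "TimeSeries",
    "RecirculationResult",
    "ShearFields",
    "TipShearResult",
    "vorticity",
    "helicity_density",
    "strain_and_stress",
    "wall_shear_stress",
    "boundary_flow_rate",
    "recirculation_fraction",
    "tip_statistics",
    "tip_volume_stats",
    "time_average",
    "volume_average",
    "pearson",
    "percent_change",
    "build_report",
    "render_report_markdown",
]

REPORT_COLUMNS = [
    "Rf_pct",
    "vorticity_mean",
    "wss_mean",
    "tip_tau_mean",
    "tip_frac_above_pct",
]


@dataclass
class TimeSeries:
    """A named scalar sampled on a uniform time grid [s]."""

    name: str
    times: np.ndarray
    values: np.ndarray
    cycle_period: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("time series needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("time grid must be uniform (relative tolerance 1e-9)")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def last_cycle(self) -> "TimeSeries":
        """Restrict to the final full cycle (requires ``cycle_period``)."""
        if self.cycle_period is None:
            raise ValueError("cycle_period not set")
        t_end = self.times[-1]
        mask = self.times >= t_end - self.cycle_period - 1e-9 * self.cycle_period
        return TimeSeries(self.name, self.times[mask], self.values[mask], self.cycle_period)


@dataclass
class RecirculationResult:
    """Mass-weighted recirculation fraction and its per-facet ingredients."""

    Rf: float  # [%]
    phi_bar_k: np.ndarray  # time-averaged phase fraction per facet [-]
    mdot_k: np.ndarray  # time-averaged facet mass flow [kg/s]

    @property
    def mdot_T(self) -> float:
        return float(self.mdot_k.sum())


@dataclass
class ShearFields:
    """Strain-rate tensor, its magnitude, and the shear stress field."""

    eps: np.ndarray  # (ndim, ndim, *grid) [1/s]
    magnitude: np.ndarray  # sqrt(2 eps:eps) [1/s]
    tau: np.ndarray  # mu(|eps|) * |eps| [Pa]


@dataclass
class TipShearResult:
    """Shear-stress burden inside the tip sampling prism."""

    times: np.ndarray
    tau_mean: np.ndarray  # volume-averaged tau per snapshot [Pa]
    frac_above: np.ndarray  # % of prism volume with tau >= threshold
    tau_mean_avg: float
    frac_above_avg: float
    threshold: float
    n_cells: int


def _check_stencil(field: FieldSnapshot) -> None:
    if min(field.grid_shape) < 3:
        raise ValueError("grid too small for a central-difference stencil (need >= 3)")


def _grad(comp: np.ndarray, h: float, axis: int) -> np.ndarray:
    return np.gradient(comp, h, axis=axis)


def vorticity(field: FieldSnapshot) -> tuple[np.ndarray, np.ndarray]:
    """Curl of the velocity field by central differences.

    Returns ``(omega, magnitude)``.  In 2-D ``omega`` has one component
    (the out-of-plane z-component); in 3-D it has three.
    """
    _check_stencil(field)
    u, h = field.velocity, field.h
    if field.ndim == 2:
        wz = _grad(u[1], h, 0) - _grad(u[0], h, 1)
        omega = wz[np.newaxis]
    else:
        wx = _grad(u[2], h, 1) - _grad(u[1], h, 2)
        wy = _grad(u[0], h, 2) - _grad(u[2], h, 0)
        wz = _grad(u[1], h, 0) - _grad(u[0], h, 1)
        omega = np.stack([wx, wy, wz])
    return omega, np.sqrt((omega**2).sum(axis=0))


def helicity_density(field: FieldSnapshot) -> np.ndarray:
    """Kinetic helicity density u . omega [m/s^2].

    Identically zero for any planar 2-D field (the vorticity is then
    perpendicular to the plane of motion).
    """
    _check_stencil(field)
    if field.ndim == 2:
        return np.zeros(field.grid_shape)
    omega, _ = vorticity(field)
    return np.einsum("c...,c...->...", field.velocity, omega)


def strain_and_stress(field: FieldSnapshot, props: FluidProperties | None = None) -> ShearFields:
    """Strain-rate tensor, magnitude and generalized-Newtonian shear stress."""
    _check_stencil(field)
    if props is None:
        props = FluidProperties()
    u, h, nd = field.velocity, field.h, field.ndim
    grads = [[_grad(u[i], h, j) for j in range(nd)] for i in range(nd)]
    eps = np.empty((nd, nd) + field.grid_shape)
    for i in range(nd):
        for j in range(nd):
            eps[i, j] = 0.5 * (grads[j][i] + grads[i][j])
    mag = np.sqrt(2.0 * np.einsum("ij...,ij...->...", eps, eps))
    tau = apparent_viscosity(mag, props) * mag
    return ShearFields(eps=eps, magnitude=mag, tau=tau)


_SIDE_AXIS = {"x": 0, "y": 1, "z": 2}


def wall_shear_stress(
    field: FieldSnapshot,
    wall: str,
    props: FluidProperties | None = None,
    facet_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float]:
    """Wall shear stress on one no-slip wall of the grid.

    ``wall`` is a side label such as ``"y-"`` (low-y wall) or ``"x+"``.
    The tangential-velocity normal gradient is evaluated with a one-sided
    second-order formula using the no-slip wall value and the first two
    cell centres at h/2 and 3h/2 from the wall; the stress is
    ``mu(gamma_w) * gamma_w`` with the wall shear rate
    ``gamma_w = |d u_t / d n|``.

    Returns ``(tau_wall, spatial_average)``; ``facet_range`` optionally
    restricts the average to a slice of the wall (a boundary patch).
    """
    _check_stencil(field)
    if props is None:
        props = FluidProperties()
    if len(wall) != 2 or wall[0] not in _SIDE_AXIS or wall[1] not in "+-":
        raise ValueError(f"wall must look like 'y-' or 'x+', got {wall!r}")
    axis = _SIDE_AXIS[wall[0]]
    if axis >= field.ndim:
        raise ValueError(f"wall {wall!r} not present on a {field.ndim}-D grid")
    if field.grid_shape[axis] < 2:
        raise ValueError("need at least 2 interior cells normal to the wall")
    low = wall[1] == "-"
    h = field.h

    def take(arr, idx):
        sl = [slice(None)] * field.ndim
        sl[axis] = idx if low else arr.shape[axis] - 1 - idx
        return arr[tuple(sl)]

    # d u_t / d n via quadratic through (0, u_wall=0), (h/2, u1), (3h/2, u2)
    grads = []
    for comp in range(field.ncomp):
        if comp == axis:
            continue  # normal component carries no wall shear under no-slip
        u1 = take(field.velocity[comp], 0)
        u2 = take(field.velocity[comp], 1)
        grads.append((9.0 * u1 - u2) / (3.0 * h))
    gamma_w = np.sqrt(sum(g**2 for g in grads))
    tau = apparent_viscosity(gamma_w, props) * gamma_w
    if facet_range is not None:
        i0, i1 = facet_range
        tau_sel = tau[i0:i1] if field.ndim == 2 else tau[i0:i1, ...]
    else:
        tau_sel = tau
    return tau, float(np.mean(tau_sel))


def boundary_flow_rate(un, areas) -> np.ndarray | float:
    """Flow rate Q = sum_k u_k . A_k through a patch, in ml/s.

    ``un`` holds facet normal velocities [m/s] (signed by the chosen normal
    convention), shape ``(n_facets,)`` for one instant or
    ``(n_times, n_facets)`` for a series; ``areas`` are facet areas [m^2].
    """
    un = np.asarray(un, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if areas.ndim != 1 or len(areas) == 0:
        raise ValueError("patch has no facets")
    q = un @ areas * 1e6  # m^3/s -> ml/s
    return float(q) if np.ndim(q) == 0 else q


def recirculation_fraction(
    times,
    phi,
    un,
    areas,
    rho: float = C.BLOOD_DENSITY,
) -> RecirculationResult:
    """Mass-weighted recirculation fraction over one cycle at a patch.

    Parameters
    ----------
    times : (nt,) uniform sample times spanning the analysis cycle [s]
    phi : (nt, nk) recirculation-phase fraction per facet
    un : (nt, nk) or (nk,) facet normal velocity [m/s]
    areas : (nk,) facet areas [m^2]
    rho : fluid density [kg/m^3]
    """
    times = np.asarray(times, dtype=float)
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    areas = np.asarray(areas, dtype=float)
    un = np.asarray(un, dtype=float)
    if un.ndim == 1:
        un = np.broadcast_to(un, phi.shape)
    if phi.shape != un.shape or phi.shape[0] != len(times):
        raise ValueError("times, phi and un shapes are inconsistent")
    T = times[-1] - times[0]
    if T <= 0:
        raise ValueError("times must span a positive interval")
    phi_bar = np.trapezoid(phi, times, axis=0) / T
    mdot_kt = rho * un * areas[np.newaxis, :]
    mdot_k = np.trapezoid(mdot_kt, times, axis=0) / T
    mdot_T = mdot_k.sum()
    if mdot_T == 0:
        raise ZeroDivisionError("total patch mass flow is zero; Rf undefined")
    rf = float(phi_bar @ mdot_k / mdot_T * 100.0)
    return RecirculationResult(Rf=rf, phi_bar_k=phi_bar, mdot_k=mdot_k)


def tip_volume_stats(tau: np.ndarray, mask: np.ndarray, threshold: float) -> tuple[float, float]:
    """Volume-weighted mean tau and % of masked volume with tau >= threshold.

    Cells are uniform, so volume weighting reduces to arithmetic means
    over the masked cells.
    """
    n = int(mask.sum())
    if n == 0:
        raise ValueError("tip volume contains no grid cells")
    vals = tau[mask]
    return float(vals.mean()), float((vals >= threshold).mean() * 100.0)


def tip_statistics(
    fields,
    tip: TipVolume,
    props: FluidProperties | None = None,
    threshold: float = C.PLATELET_TAU_THRESHOLD,
) -> TipShearResult:
    """Shear-stress burden inside the tip prism over a sequence of snapshots.

    For each snapshot the stress field is computed, the cells whose centres
    fall inside the prism are selected, and the volume-averaged stress and
    the volume percentage with ``tau >= threshold`` are recorded; both are
    then time-averaged (trapezoid) over the snapshot span.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("no snapshots supplied")
    f0 = fields[0]
    bounds = tip.bounds(f0.ndim)
    centers = f0.cell_centers()
    masks_1d = []
    for (lo, hi), c in zip(bounds, centers):
        if lo < c[0] - f0.h or hi > c[-1] + f0.h:
            raise ValueError("tip volume extends outside the grid")
        masks_1d.append((c >= lo) & (c <= hi))
    mask = np.ones(f0.grid_shape, dtype=bool)
    for ax, m1 in enumerate(masks_1d):
        shape = [1] * f0.ndim
        shape[ax] = -1
        mask &= m1.reshape(shape)
    if not mask.any():
        raise ValueError("tip volume contains no grid cells")

    times, tau_means, fracs = [], [], []
    for f in fields:
        sf = strain_and_stress(f, props)
        m, fr = tip_volume_stats(sf.tau, mask, threshold)
        times.append(f.time)
        tau_means.append(m)
        fracs.append(fr)
    times = np.asarray(times)
    tau_means = np.asarray(tau_means)
    fracs = np.asarray(fracs)
    if len(times) > 1:
        span = times[-1] - times[0]
        tau_avg = float(np.trapezoid(tau_means, times) / span)
        frac_avg = float(np.trapezoid(fracs, times) / span)
    else:
        tau_avg, frac_avg = float(tau_means[0]), float(fracs[0])
    return TipShearResult(
        times=times,
        tau_mean=tau_means,
        frac_above=fracs,
        tau_mean_avg=tau_avg,
        frac_above_avg=frac_avg,
        threshold=threshold,
        n_cells=int(mask.sum()),
    )


def time_average(series: TimeSeries, over_last_cycle: bool = False) -> float:
    """Trapezoidal time mean of a series.

    With ``over_last_cycle`` the mean is taken over exactly the final full
    cycle (``series.cycle_period`` must be set).
    """
    s = series.last_cycle() if over_last_cycle else series
    span = s.times[-1] - s.times[0]
    return float(np.trapezoid(s.values, s.times) / span)


def volume_average(field_values: np.ndarray) -> float:
    """Volume average of a cell field on a uniform grid."""
    return float(np.mean(np.asarray(field_values, dtype=float)))


def pearson(a, b) -> float:
    """Sample Pearson correlation coefficient of two aligned series."""
    x = np.asarray(getattr(a, "values", a), dtype=float)
    y = np.asarray(getattr(b, "values", b), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and aligned on a common grid")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ZeroDivisionError("pearson undefined for a zero-variance series")
    return float(xc @ yc / (sx * sy))


def percent_change(value: float, reference: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return (value - reference) / abs(reference) * 100.0


def build_report(results: dict[str, dict]) -> pd.DataFrame:
    """Assemble the per-model haemodynamic summary table.

    ``results`` maps a model label (e.g. "RA", "A1", "D2") to a dict with
    any of the keys in :data:`REPORT_COLUMNS`; missing metrics are kept as
    NaN and rendered as "-", never silently zero.  Rows follow the input
    order.
    """
    rows = {}
    for model, rec in results.items():
        unknown = set(rec) - set(REPORT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown metric keys for {model!r}: {sorted(unknown)}")
        rows[model] = {c: rec.get(c, np.nan) for c in REPORT_COLUMNS}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=REPORT_COLUMNS)
    df.index.name = "model"
    return df


def render_report_markdown(df: pd.DataFrame) -> str:
    """Human-readable markdown rendering, absent metrics shown as '-'."""
    shown = df.copy()
    for c in shown.columns:
        shown[c] = shown[c].map(lambda v: "-" if pd.isna(v) else f"{v:.2f}")
    try:
        return shown.to_markdown(disable_numparse=True)
    except ImportError:  # tabulate not installed
        header = "| " + " | ".join(["model", *shown.columns]) + " |"
        sep = "|" + "---|" * (len(shown.columns) + 1)
        rows = [
            "| " + " | ".join([str(ix), *map(str, r)]) + " |"
            for ix, r in zip(shown.index, shown.to_numpy())
        ]
        return "\n".join([header, sep, *rows])
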