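"""Idealised atrial chamber geometry and catheter placement.

The chamber is a 2-D rectangle with an assumed uniform out-of-plane depth.
Physiological openings (the two caval inlets and the tricuspid-valve
outlet) and catheter lumen openings are represented as slots on the
boundary; each slot is a :class:`BoundaryPatch` made of grid-face facets
with area vectors, through which flow rates, Reynolds numbers and the
recirculation fraction are computed.

The catheter solid is not resolved: each lumen is a boundary source/sink
patch delivering the operating-point flow rate.  This keeps every modelled
mechanism (pulsatile caval inflow, return-jet/chamber interaction,
filtered-phase tracking) at a scale where the solver can be verified
against analytic solutions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .boundary import CatheterOperatingPoint

__all__ = [
    "BoundaryPatch",
    "ChamberGeometry",
    "CatheterConfig",
    "TipVolume",
    "place_catheter",
]

PATCH_KINDS = (
    "pressure_inlet",
    "velocity_inlet",
    "pressure_outlet",
    "catheter_venous",
    "catheter_arterial",
    "wall",
)

_SIDES = ("x-", "x+", "y-", "y+")


@dataclass
class BoundaryPatch:
    """A named opening on the chamber boundary.

    ``areas`` are facet area magnitudes [m^2] and ``normals`` the outward
    unit normals.  Grid-attached patches also carry the wall side, the face
    index range along that wall, and the prescribed normal speed (positive
    = into the domain) or waveform admittance used by the solver.
    """

    name: str
    kind: str
    areas: np.ndarray
    normals: np.ndarray
    side: str | None = None
    i0: int = 0
    i1: int = 0
    diameter: float | None = None
    prescribed_speed: float | None = None  # m/s, inflow positive
    admittance: float | None = None  # (m/s)/Pa mapping waveform pressure to inflow
    phi_value: float = 0.0  # recirculation-phase fraction carried by inflow

    def __post_init__(self) -> None:
        if self.kind not in PATCH_KINDS:
            raise ValueError(f"unknown patch kind {self.kind!r}")
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if np.any(self.areas <= 0):
            raise ValueError(f"patch {self.name!r}: facet areas must be positive")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"patch {self.name!r}: normals must be unit length")
        if self.side is not None and self.side not in _SIDES:
            raise ValueError(f"unknown wall side {self.side!r}")

    @property
    def area(self) -> float:
        """Total patch area, the sum of facet areas [m^2]."""
        return float(self.areas.sum())

    @property
    def n_facets(self) -> int:
        return len(self.areas)

    @classmethod
    def slot(
        cls,
        name: str,
        kind: str,
        side: str,
        start: float,
        width: float,
        h: float,
        depth: float,
        **kw,
    ) -> "BoundaryPatch":
        """Build a slot patch on a wall, snapped to the grid of spacing h."""
        i0 = int(round(start / h))
        i1 = max(i0 + 1, int(round((start + width) / h)))
        n = i1 - i0
        outward = {
            "x-": (-1.0, 0.0),
            "x+": (1.0, 0.0),
            "y-": (0.0, -1.0),
            "y+": (0.0, 1.0),
        }[side]
        return cls(
            name=name,
            kind=kind,
            areas=np.full(n, h * depth),
            normals=np.tile(outward, (n, 1)),
            side=side,
            i0=i0,
            i1=i1,
            **kw,
        )


@dataclass(frozen=True)
class TipVolume:
    """Rectangular sampling prism around the venous tip [mm dims].

    The shear-stress burden of each design (volume-averaged tau and the
    volume percentage with tau at or above the platelet-activation
    threshold) is evaluated inside this prism.
    """

    length: float
    width: float
    height: float
    anchor: tuple[float, ...] = (0.0, 0.0)  # prism centre [m], chamber frame

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("tip volume dimensions must be positive")

    @classmethod
    def for_design(cls, design: str, anchor=(0.0, 0.0)) -> "TipVolume":
        l, w, hgt = C.TIP_VOLUME_MM[design[0].upper()]
        return cls(length=l, width=w, height=hgt, anchor=tuple(anchor))

    def bounds(self, ndim: int) -> list[tuple[float, float]]:
        """Axis-aligned bounds [m] in the chamber frame.

        In 2-D the in-plane extents are (length, height); in 3-D
        (length, width, height).
        """
        dims_mm = (
            (self.length, self.height)
            if ndim == 2
            else (self.length, self.width, self.height)
        )
        if len(self.anchor) < ndim:
            raise ValueError("anchor dimensionality does not match grid")
        return [
            (a - 0.5e-3 * d, a + 0.5e-3 * d)
            for a, d in zip(self.anchor[:ndim], dims_mm)
        ]


# Default effective venous-arterial separation [mm] per tip morphology:
# the step designs (A, B) stagger the lumens by the step, the split tip (C)
# separates them further, and the symmetric design (D) keeps the intake
# farthest from the return jet.  Exact tip coordinates are not published,
# so these encode only the designs' qualitative separation ordering.
_DEFAULT_TIP_GAP = {"A": 10.0, "B": 10.0, "C": 15.0, "D": 20.0}


@dataclass
class CatheterConfig:
    """One catheter design at one operating point and tip position.

    Designs: A = step tip with side holes, B = step tip without, C = split
    tip, D = symmetric tip.  Tip positions: 1 mid-chamber, 2 near the
    atrial wall, 3 rotated about the catheter axis (asymmetric tips only).
    """

    design: str = "A"
    operating: CatheterOperatingPoint | None = None
    tip_position: str = "position1"
    tip_gap: float | None = None  # mm
    side_hole_count: int = 2
    side_hole_flow_fraction: float = 0.5
    tip_volume: TipVolume | None = None
    tip_length: float | None = None  # mm
    outer_diameter: float | None = None  # Fr
    lumen_area: float | None = None  # mm^2

    def __post_init__(self) -> None:
        d = self.design[0].upper()
        if d not in "ABCD":
            raise ValueError(f"unknown catheter design {self.design!r}")
        self.design = d
        dims = C.CATHETER_DIMENSIONS[d]
        if self.tip_length is None:
            self.tip_length = dims["tip_length_mm"]
        if self.outer_diameter is None:
            self.outer_diameter = dims["outer_diameter_fr"]
        if self.lumen_area is None:
            self.lumen_area = dims["lumen_area_mm2"]
        if self.lumen_area <= 0:
            raise ValueError("lumen area must be positive")
        if self.operating is None:
            self.operating = CatheterOperatingPoint.for_design(d)
        if self.tip_gap is None:
            self.tip_gap = _DEFAULT_TIP_GAP[d]
        if self.tip_position not in ("position1", "position2", "position3"):
            raise ValueError(f"unknown tip position {self.tip_position!r}")
        if self.tip_position == "position3" and d == "D":
            raise ValueError("position3 (rotation) is undefined for the symmetric tip D")
        if d != "A":
            self.side_hole_count = 0
        elif self.side_hole_count < 0:
            raise ValueError("side hole count must be non-negative")
        if not (0.0 <= self.side_hole_flow_fraction < 1.0):
            raise ValueError("side-hole flow fraction must lie in [0, 1)")

    @property
    def venous_jet_speed(self) -> float:
        """Mean jet speed through the true lumen area, Q / A [m/s]."""
        q = self.operating.venous_flow * C.ML_MIN_TO_M3_S
        return q / (self.lumen_area * 1e-6)


@dataclass
class ChamberGeometry:
    """2-D rectangular chamber with boundary patches on a uniform grid.

    ``depth`` is the uniform out-of-plane extent: using a single depth for
    every patch makes the in-plane (grid) mass balance and the physical
    flow-rate balance identical, so rigid-wall continuity holds exactly in
    both.
    """

    Lx: float = 0.06
    Ly: float = 0.06
    nx: int = 48
    ny: int = 48
    depth: float = 0.03
    patches: dict[str, BoundaryPatch] = field(default_factory=dict)
    dimensionality: str = "2D"
    catheter: CatheterConfig | None = None

    def __post_init__(self) -> None:
        if self.dimensionality != "2D":
            raise NotImplementedError(
                "only the 2-D chamber is implemented; metric operators accept 3-D fields"
            )
        hx, hy = self.Lx / self.nx, self.Ly / self.ny
        if not math.isclose(hx, hy, rel_tol=1e-12):
            raise ValueError("grid must be isotropic (Lx/nx == Ly/ny)")
        self._validate_patches()

    @property
    def h(self) -> float:
        return self.Lx / self.nx

    def _wall_faces(self, side: str) -> int:
        return self.ny if side in ("x-", "x+") else self.nx

    def _validate_patches(self) -> None:
        occupied: dict[str, set[int]] = {s: set() for s in _SIDES}
        for p in self.patches.values():
            if p.side is None:
                raise ValueError(f"patch {p.name!r} is not attached to a wall")
            nfaces = self._wall_faces(p.side)
            if p.i0 < 0 or p.i1 > nfaces:
                raise ValueError(f"patch {p.name!r} extends outside wall {p.side}")
            span = set(range(p.i0, p.i1))
            if occupied[p.side] & span:
                raise ValueError(f"patch {p.name!r} overlaps another patch on {p.side}")
            occupied[p.side] |= span

    def add_slot(
        self,
        name: str,
        kind: str,
        side: str,
        center: float,
        target_area: float,
        diameter: float | None = None,
        **kw,
    ) -> BoundaryPatch:
        """Add a slot whose as-built area approximates ``target_area`` [m^2].

        The slot width is ``target_area / depth`` snapped to whole grid
        faces; a warning is issued if snapping changes the area by more
        than 1%.
        """
        width = target_area / self.depth
        p = BoundaryPatch.slot(
            name, kind, side, center - width / 2, width, self.h, self.depth,
            diameter=diameter, **kw,
        )
        rel = abs(p.area - target_area) / target_area
        if rel > 0.01:
            warnings.warn(
                f"patch {name!r}: as-built area {p.area:.3e} m^2 differs from "
                f"target {target_area:.3e} m^2 by {100 * rel:.1f}% (grid snapping)",
                stacklevel=2,
            )
        self.patches[name] = p
        self._validate_patches()
        return p

    @classmethod
    def default_ra(
        cls,
        nx: int = 48,
        ny: int = 48,
        Lx: float = 0.06,
        Ly: float = 0.06,
        depth: float = 0.03,
        admittance: float = 5e-4,
    ) -> "ChamberGeometry":
        """Idealised right atrium: caval inlets on the left wall, the
        tricuspid outlet on the right wall.

        ``admittance`` [(m/s)/Pa] linearly maps the inlet pressure waveform
        to a spatially uniform inflow speed; the default puts the mean
        caval velocity near the clinically reported 0.17 m/s for a 3 mmHg
        mean pressure.
        """
        geom = cls(Lx=Lx, Ly=Ly, nx=nx, ny=ny, depth=depth)
        svc_area = math.pi * C.SVC_DIAMETER**2 / 4
        ivc_area = math.pi * C.IVC_DIAMETER**2 / 4
        geom.add_slot(
            "svc", "velocity_inlet", "x-", 0.75 * Ly, svc_area,
            diameter=C.SVC_DIAMETER, admittance=admittance, phi_value=0.0,
        )
        geom.add_slot(
            "ivc", "velocity_inlet", "x-", 0.25 * Ly, ivc_area,
            diameter=C.IVC_DIAMETER, admittance=admittance, phi_value=0.0,
        )
        tv_d = math.sqrt(4 * C.TV_AREA / math.pi)
        geom.add_slot(
            "tv", "pressure_outlet", "x+", 0.5 * Ly, C.TV_AREA, diameter=tv_d,
        )
        return geom


def place_catheter(geom: ChamberGeometry, catheter: CatheterConfig) -> ChamberGeometry:
    """Insert a catheter as venous (source) and arterial (sink) slots on the
    top wall, returning a new geometry.

    The venous slot injects the operating-point flow (recirculation-phase
    fraction 1), the arterial slot withdraws the design's achieved flow.
    For design A a fraction of the venous flow is split over side-hole
    sub-slots flanking the end hole.  Position 2 translates the tip toward
    the outlet-side wall; position 3 mirrors the venous/arterial order
    (the 2-D analogue of rotating an asymmetric tip about its axis).
    ``reverse`` mode swaps the venous and arterial lumen roles.
    """
    import copy

    g = copy.deepcopy(geom)
    cath = copy.deepcopy(catheter)
    if cath.tip_volume is None:
        cath.tip_volume = TipVolume.for_design(cath.design)
    op = cath.operating
    h, depth = g.h, g.depth
    q_ven = op.venous_flow * C.ML_MIN_TO_M3_S
    q_art = op.arterial_flow * C.ML_MIN_TO_M3_S

    gap = cath.tip_gap * 1e-3
    # slot centres on the top wall, venous downstream (toward the outlet)
    if cath.tip_position == "position2":
        center = 0.78 * g.Lx
    else:
        center = 0.5 * g.Lx
    ven_x = center + gap / 2
    art_x = center - gap / 2
    if cath.tip_position == "position3":
        ven_x, art_x = art_x, ven_x

    ven_kind, art_kind = "catheter_venous", "catheter_arterial"
    if op.mode == "reverse":
        # swap lumen roles: the arterial tip returns filtered blood
        ven_x, art_x = art_x, ven_x

    # slot widths: at least one grid face, nominally two
    slot_w = 2 * h

    n_side = cath.side_hole_count
    side_frac = cath.side_hole_flow_fraction if n_side > 0 else 0.0
    q_end = q_ven * (1.0 - side_frac)

    def add(name, kind, x0, width, q, phi):
        p = BoundaryPatch.slot(
            name, kind, "y+", x0, width, h, depth,
            prescribed_speed=q / (max(1, round(width / h)) * h * depth),
            phi_value=phi,
        )
        # sign convention: prescribed_speed positive = into the domain
        if kind == "catheter_arterial":
            p.prescribed_speed = -abs(p.prescribed_speed)
        g.patches[name] = p

    add("cath_venous", ven_kind, ven_x - slot_w / 2, slot_w, q_end, 1.0)
    add("cath_arterial", art_kind, art_x - slot_w / 2, slot_w, q_art, 0.0)
    if n_side > 0:
        q_side = q_ven * side_frac / n_side
        offsets = np.linspace(2.5 * h, 2.5 * h + (n_side - 1) * 2 * h, n_side)
        for k, off in enumerate(offsets):
            sgn = 1.0 if k % 2 == 0 else -1.0
            add(f"cath_side_{k}", ven_kind, ven_x + sgn * off - h / 2, h,
                q_side, 1.0)
    g._validate_patches()

    # anchor the tip prism just inside the wall, under the venous exit
    tip_depth_m = cath.tip_volume.height * 1e-3
    cath.tip_volume = replace(
        cath.tip_volume, anchor=(ven_x, g.Ly - tip_depth_m / 2 - h)
    )
    g.catheter = cath
    return g
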