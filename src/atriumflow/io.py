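"""File formats and pipeline configuration.

All internal quantities are SI; clinical units (mmHg, ml/min, Fr) appear
only in the config file and in reports.  Supported formats: YAML config,
CSV time series, legacy-ASCII VTK structured-points snapshots (readable
by standard viewers), XLSX series (read), and STL surface meshes (read,
inspection only).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .boundary import CardiacCycle, CatheterOperatingPoint, InletWaveform, build_default_waveform
from .fields import FieldSnapshot
from .geometry import CatheterConfig, ChamberGeometry
from .metrics import TimeSeries
from .rheology import FluidProperties
from .solver import SolverSettings

__all__ = [
    "PipelineConfig",
    "read_config",
    "write_config",
    "read_series",
    "write_series",
    "read_waveform_csv",
    "write_fields",
    "read_stl",
]

# Schema: section -> key -> default.  Units are clinical at this boundary.
_SCHEMA: dict[str, dict[str, object]] = {
    "fluid": {
        "model": "bird_carreau",
        "rho": C.BLOOD_DENSITY,
        "mu0": C.CARREAU_MU0,
        "mu_inf": C.CARREAU_MU_INF,
        "lambda_t": C.CARREAU_LAMBDA,
        "n_index": C.CARREAU_N,
        "mu_newtonian": C.NEWTONIAN_MU,
    },
    "cycle": {
        "diastole_s": C.DIASTOLE,
        "systole_s": C.SYSTOLE,
    },
    "waveform": {
        "mean_mmhg": C.MEAN_RA_PRESSURE_MMHG,
        "amplitude_mmhg": 2.0,
        "interpolation": "linear",
        "csv_path": None,
    },
    "geometry": {
        "nx": 48,
        "ny": 48,
        "Lx_m": 0.06,
        "Ly_m": 0.06,
        "depth_m": 0.03,
        "admittance": 5e-4,
    },
    "catheter": {
        "enabled": False,
        "design": "A",
        "tip_position": "position1",
        "mode": "standard",
        "venous_flow_ml_min": C.VENOUS_FLOW_ML_MIN,
        "venous_gauge_mmhg": C.VENOUS_GAUGE_MMHG,
        "arterial_gauge_mmhg": None,  # per-design default from the operating table
        "arterial_flow_ml_min": None,
        "side_hole_count": 2,
        "side_hole_flow_fraction": 0.5,
    },
    "solver": {
        "dt_s": None,
        "n_cycles": C.N_CYCLES,
        "residual_tolerance": C.RESIDUAL_TOLERANCE,
        "cfl_cap": 0.9,
        "advection_scheme": "van-leer-limited",
        "snapshot_stride": 5,
    },
    "metrics": {
        "tau_threshold_pa": C.PLATELET_TAU_THRESHOLD,
        "analysis_cycle": C.ANALYSIS_CYCLE,
    },
    "output": {
        "directory": "out",
        "write_vtk": True,
    },
    "run": {
        "seed": 0,
        "log_level": "INFO",
    },
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults filled in.

    ``provenance`` records, per dotted key, whether the value came from
    the user file or is a package default.
    """

    sections: dict[str, dict[str, object]]
    provenance: dict[str, str] = dc_field(default_factory=dict)

    def __getitem__(self, section: str) -> dict[str, object]:
        return self.sections[section]

    # --- builders -----------------------------------------------------
    def fluid_properties(self) -> FluidProperties:
        f = self.sections["fluid"]
        return FluidProperties(
            rho=f["rho"], mu0=f["mu0"], mu_inf=f["mu_inf"],
            lambda_t=f["lambda_t"], n_index=f["n_index"],
            model=f["model"], mu_newt=f["mu_newtonian"],
        )

    def cardiac_cycle(self) -> CardiacCycle:
        c = self.sections["cycle"]
        return CardiacCycle(diastole=c["diastole_s"], systole=c["systole_s"])

    def waveform(self) -> InletWaveform:
        w = self.sections["waveform"]
        if w["csv_path"]:
            return read_waveform_csv(w["csv_path"], self.cardiac_cycle(), w["interpolation"])
        return build_default_waveform(
            cycle=self.cardiac_cycle(),
            mean_p=w["mean_mmhg"],
            pulse_amplitude=w["amplitude_mmhg"],
            interpolation=w["interpolation"],
        )

    def geometry(self) -> ChamberGeometry:
        g = self.sections["geometry"]
        return ChamberGeometry.default_ra(
            nx=g["nx"], ny=g["ny"], Lx=g["Lx_m"], Ly=g["Ly_m"],
            depth=g["depth_m"], admittance=g["admittance"],
        )

    def catheter(self) -> CatheterConfig | None:
        c = self.sections["catheter"]
        if not c["enabled"]:
            return None
        design = str(c["design"])[0].upper()
        op = CatheterOperatingPoint(
            venous_flow=c["venous_flow_ml_min"],
            venous_gauge_pressure=c["venous_gauge_mmhg"],
            arterial_gauge_pressure=(
                c["arterial_gauge_mmhg"]
                if c["arterial_gauge_mmhg"] is not None
                else C.ARTERIAL_GAUGE_MMHG[design]
            ),
            arterial_flow=(
                c["arterial_flow_ml_min"]
                if c["arterial_flow_ml_min"] is not None
                else C.ARTERIAL_FLOW_ML_MIN[design]
            ),
            mode=c["mode"],
        )
        return CatheterConfig(
            design=design,
            operating=op,
            tip_position=c["tip_position"],
            side_hole_count=c["side_hole_count"],
            side_hole_flow_fraction=c["side_hole_flow_fraction"],
        )

    def solver_settings(self) -> SolverSettings:
        s = self.sections["solver"]
        return SolverSettings(
            dt=s["dt_s"],
            n_cycles=s["n_cycles"],
            residual_tolerance=s["residual_tolerance"],
            cfl_cap=s["cfl_cap"],
            advection_scheme=s["advection_scheme"],
            snapshot_stride=s["snapshot_stride"],
            seed=self.sections["run"]["seed"],
        )


def _default_config() -> dict[str, dict[str, object]]:
    return {s: dict(kv) for s, kv in _SCHEMA.items()}


def read_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected by name.

    ``None`` (or an empty file) yields the all-defaults configuration.
    """
    sections = _default_config()
    provenance = {
        f"{s}.{k}": "default" for s, kv in sections.items() for k in kv
    }
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        for section, kv in raw.items():
            if section not in _SCHEMA:
                raise ValueError(
                    f"{path}: unknown config section {section!r}; "
                    f"expected one of {sorted(_SCHEMA)}"
                )
            if not isinstance(kv, dict):
                raise ValueError(f"{path}: section {section!r} must be a mapping")
            for key, value in kv.items():
                if key not in _SCHEMA[section]:
                    raise ValueError(
                        f"{path}: unknown key {section}.{key}; "
                        f"expected one of {sorted(_SCHEMA[section])}"
                    )
                sections[section][key] = value
                provenance[f"{section}.{key}"] = "user"
    cfg = PipelineConfig(sections=sections, provenance=provenance)
    # construct the typed objects once so invalid values fail at load time
    cfg.fluid_properties()
    cfg.cardiac_cycle()
    cfg.solver_settings()
    cfg.catheter()
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.sections, sort_keys=True))


# ----------------------------------------------------------------------
# time series


def write_series(series: TimeSeries, path: str | Path) -> None:
    pd.DataFrame({"time": series.times, series.name: series.values}).to_csv(
        path, index=False
    )


def read_series(
    path: str | Path,
    name: str | None = None,
    cycle_period: float | None = None,
    time_column: str = "time",
) -> TimeSeries:
    """Read one named series from a two-or-more-column CSV.

    The time grid must be uniform; a non-uniform grid is rejected with an
    explicit message (the :class:`TimeSeries` invariant).
    """
    df = pd.read_csv(path)
    if time_column not in df.columns:
        raise ValueError(f"{path}: missing time column {time_column!r}")
    value_cols = [c for c in df.columns if c != time_column]
    if not value_cols:
        raise ValueError(f"{path}: no value columns")
    col = name if name is not None else value_cols[0]
    if col not in df.columns:
        raise ValueError(f"{path}: no column {col!r}; available: {value_cols}")
    return TimeSeries(
        col,
        df[time_column].to_numpy(dtype=float),
        df[col].to_numpy(dtype=float),
        cycle_period,
    )


def read_waveform_csv(
    path: str | Path,
    cycle: CardiacCycle | None = None,
    interpolation: str = "linear",
) -> InletWaveform:
    """Read an inlet waveform from CSV.

    Columns: ``time`` [s] and one of ``pressure_pa`` or ``pressure_mmhg``.
    """
    if cycle is None:
        cycle = CardiacCycle()
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    if "pressure_pa" in df.columns:
        p = df["pressure_pa"].to_numpy(dtype=float)
    elif "pressure_mmhg" in df.columns:
        p = df["pressure_mmhg"].to_numpy(dtype=float) * C.MMHG_TO_PA
    else:
        raise ValueError(f"{path}: need a 'pressure_pa' or 'pressure_mmhg' column")
    return InletWaveform(
        cycle=cycle,
        times=df["time"].to_numpy(dtype=float),
        pressures=p,
        interpolation=interpolation,
    )


# ----------------------------------------------------------------------
# VTK snapshots


def _write_vtk(snapshot: FieldSnapshot, path: Path) -> None:
    """Legacy-ASCII VTK STRUCTURED_POINTS file with cell-centred fields
    stored as point data on the cell-centre lattice."""
    shape = snapshot.grid_shape
    dims = tuple(shape) + (1,) * (3 - len(shape))
    n = int(np.prod(shape))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"atriumflow snapshot t={snapshot.time:.6f}\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        org = tuple(snapshot.origin) + (0.0,) * (3 - len(shape))
        f.write(
            f"ORIGIN {org[0] + snapshot.h / 2} {org[1] + snapshot.h / 2} "
            f"{(org[2] + snapshot.h / 2) if len(shape) == 3 else 0.0}\n"
        )
        f.write(f"SPACING {snapshot.h} {snapshot.h} {snapshot.h}\n")
        f.write(f"POINT_DATA {n}\n")

        def flat(arr):
            # VTK varies x fastest; our axis 0 is x
            return np.asarray(arr).ravel(order="F")

        f.write("VECTORS velocity double\n")
        comps = [flat(snapshot.velocity[k]) for k in range(snapshot.ncomp)]
        while len(comps) < 3:
            comps.append(np.zeros(n))
        np.savetxt(f, np.column_stack(comps), fmt="%.9e")
        for fname, arr in (
            ("pressure", snapshot.pressure),
            ("phi_r", snapshot.phi_r),
            ("shear_rate", snapshot.shear_rate),
        ):
            if arr is None:
                continue
            f.write(f"SCALARS {fname} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, flat(arr)[:, np.newaxis], fmt="%.9e")


def write_fields(snapshots, out_dir: str | Path) -> Path:
    """Write snapshots as VTK files plus a CSV manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(snapshots):
        fname = f"snapshot_{i:04d}.vtk"
        _write_vtk(s, out / fname)
        rows.append({"index": i, "time": s.time, "file": fname})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ----------------------------------------------------------------------
# STL inspection


def read_stl(path: str | Path) -> dict:
    """Summarise an STL surface: triangle count and bounding box.

    Inspection only — surface meshes are never used by the solver.
    """
    import trimesh

    mesh = trimesh.load(str(path), file_type="stl", force="mesh", process=False)
    return {
        "n_triangles": int(len(mesh.faces)),
        "bbox_min": tuple(float(x) for x in mesh.bounds[0]),
        "bbox_max": tuple(float(x) for x in mesh.bounds[1]),
    }
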