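"""Mesh/temporal convergence harness and validation against literature bands.

``recompute_supplementary`` re-derives the study-level statistics
(WSS-vorticity correlation, per-cycle convergence errors, cycle-averaged
vorticity, boundary flow-rate maxima, time-averaged tip shear) from
time-series files in the supplementary-spreadsheet schemas written by
:func:`atriumflow.synthetic.make_supplementary_mock` or supplied by the
user after CSV/XLSX conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from .metrics import pearson
from .solver import check_temporal_convergence

__all__ = [
    "ConvergenceRecord",
    "ValidationBand",
    "mesh_convergence",
    "validate_bands",
    "recompute_supplementary",
    "default_bands",
]


@dataclass
class ConvergenceRecord:
    """Relative error of one refinement level against the reference."""

    level: str
    quantity: str
    value: float
    E_pct: float

    def __post_init__(self) -> None:
        if self.E_pct < 0:
            raise ValueError("relative error must be non-negative")


@dataclass
class ValidationBand:
    """Closed interval of literature-reported values for one quantity."""

    quantity: str
    low: float
    high: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"band for {self.quantity!r} has low > high")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


def default_bands() -> list[ValidationBand]:
    """Literature bands used to sanity-check the chamber haemodynamics."""
    return [
        ValidationBand("vorticity_mean", *C.VORTICITY_BAND, "in-vivo volume-averaged vorticity"),
        ValidationBand("velocity_mean", *C.VELOCITY_BAND, "clinical mean +/- sd"),
        ValidationBand("pressure_mean_mmHg", *C.PRESSURE_BAND_MMHG, "right-heart guidelines"),
    ]


def mesh_convergence(
    levels: dict[str, dict[str, float]],
    wss_threshold_pct: float = C.MESH_WSS_ERROR_PCT,
    probe_threshold_pct: float = C.MESH_PROBE_ERROR_PCT,
    reference: str | None = None,
) -> tuple[list[ConvergenceRecord], dict[str, bool]]:
    """Relative errors of per-mesh probe velocity and average WSS.

    ``levels`` maps a level id (e.g. element count) to
    ``{"probe_velocity": ..., "avg_wss": ...}``; the reference is the last
    (finest) level unless named.  A level passes when its WSS error is
    below ``wss_threshold_pct`` and its probe-velocity error below
    ``probe_threshold_pct``.

    Returns ``(records, pass_by_level)``.
    """
    if len(levels) < 2:
        raise ValueError("mesh convergence needs at least 2 levels")
    names = list(levels)
    ref_name = reference if reference is not None else names[-1]
    ref = levels[ref_name]
    records: list[ConvergenceRecord] = []
    passes: dict[str, bool] = {}
    for name in names:
        errs = {}
        for q, thr in (("avg_wss", wss_threshold_pct), ("probe_velocity", probe_threshold_pct)):
            v_ref = ref[q]
            if v_ref == 0:
                raise ZeroDivisionError(f"reference {q!r} is zero; error undefined")
            e = abs((levels[name][q] - v_ref) / v_ref) * 100.0
            records.append(ConvergenceRecord(level=name, quantity=q, value=levels[name][q], E_pct=e))
            errs[q] = e <= thr
        passes[name] = all(errs.values())
    return records, passes


def validate_bands(
    metrics: dict[str, float],
    bands: list[ValidationBand] | None = None,
) -> pd.DataFrame:
    """Flag each metric inside/outside its literature band.

    Reporting only: out-of-band values never raise.  Metrics with no
    matching band, or non-finite values, are listed as unchecked.
    """
    if bands is None:
        bands = default_bands()
    by_name = {b.quantity: b for b in bands}
    rows = []
    for name, value in metrics.items():
        band = by_name.get(name)
        if band is None:
            rows.append({"quantity": name, "value": value, "status": "unchecked",
                         "low": np.nan, "high": np.nan})
            continue
        if value is None or not math.isfinite(value):
            rows.append({"quantity": name, "value": value, "status": "unchecked",
                         "low": band.low, "high": band.high})
            continue
        rows.append(
            {
                "quantity": name,
                "value": value,
                "status": "inside" if band.contains(value) else "outside",
                "low": band.low,
                "high": band.high,
            }
        )
    return pd.DataFrame(rows)


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; expected layout with {list(cols)}"
        )


def recompute_supplementary(
    files: dict[str, str | Path],
    ref_cycle: int | None = None,
    analysis_cycle: int = C.ANALYSIS_CYCLE,
    period: float = C.CYCLE_PERIOD,
) -> dict[str, float]:
    """Recompute study-level statistics from supplementary-schema files.

    ``files`` maps logical names to paths; all are optional and only the
    statistics whose inputs are present are emitted:

    * ``cycle_convergence`` (columns cycle, velocity, pressure) ->
      ``velocity_error_pct`` / ``pressure_error_pct`` at the analysis
      cycle against ``ref_cycle`` (default: last cycle);
    * ``wss_vorticity`` (time, wss, vorticity) ->
      ``wss_vorticity_pearson`` and ``vorticity_cycle_mean``;
    * ``boundary_flows`` (time, <b>_velocity, <b>_area) ->
      ``<b>_peak_flow_ml_s`` per boundary;
    * ``tip_shear`` (time, one column per model) ->
      ``tip_shear_mean_<model>``.
    """
    out: dict[str, float] = {}
    files = {k: Path(v) for k, v in files.items()}

    if "cycle_convergence" in files:
        df = _read_table(files["cycle_convergence"])
        _require(df, ("cycle", "velocity", "pressure"), files["cycle_convergence"])
        df = df.sort_values("cycle")
        table = check_temporal_convergence(
            {"velocity": df["velocity"].to_numpy(), "pressure": df["pressure"].to_numpy()},
            ref_cycle=ref_cycle,
        )
        sel = table[table["cycle"] == analysis_cycle]
        for _, row in sel.iterrows():
            out[f"{row['quantity']}_error_pct"] = float(row["E_pct"])

    if "wss_vorticity" in files:
        df = _read_table(files["wss_vorticity"])
        _require(df, ("time", "wss", "vorticity"), files["wss_vorticity"])
        t = df["time"].to_numpy(dtype=float)
        out["wss_vorticity_pearson"] = pearson(
            df["wss"].to_numpy(dtype=float), df["vorticity"].to_numpy(dtype=float)
        )
        out["vorticity_cycle_mean"] = float(
            np.trapezoid(df["vorticity"].to_numpy(dtype=float), t) / (t[-1] - t[0])
        )

    if "boundary_flows" in files:
        df = _read_table(files["boundary_flows"])
        if "time" not in df.columns:
            raise ValueError(f"{files['boundary_flows']}: missing 'time' column")
        boundaries = sorted(
            {c[: -len("_velocity")] for c in df.columns if c.endswith("_velocity")}
        )
        if not boundaries:
            raise ValueError(
                f"{files['boundary_flows']}: expected '<boundary>_velocity' and "
                f"'<boundary>_area' column pairs"
            )
        for b in boundaries:
            _require(df, (f"{b}_velocity", f"{b}_area"), files["boundary_flows"])
            q = df[f"{b}_velocity"].to_numpy(dtype=float) * df[f"{b}_area"].to_numpy(dtype=float)
            out[f"{b}_peak_flow_ml_s"] = float(np.max(q) * 1e6)

    if "tip_shear" in files:
        df = _read_table(files["tip_shear"])
        if "time" not in df.columns:
            raise ValueError(f"{files['tip_shear']}: missing 'time' column")
        t = df["time"].to_numpy(dtype=float)
        for model in [c for c in df.columns if c != "time"]:
            out[f"tip_shear_mean_{model}"] = float(
                np.trapezoid(df[model].to_numpy(dtype=float), t) / (t[-1] - t[0])
            )
    return out
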