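"""End-to-end run: simulate, post-process, and summarise one model.

Glues the solver to the metric operators the way the CLI and the examples
use them: run the transient chamber (with or without a catheter), restrict
to the final (analysis) cycle, and produce the per-model summary row —
recirculation fraction, time/volume-averaged vorticity, time-averaged
wall shear stress, and tip shear-stress burden.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import constants as C
from .metrics import (
    TimeSeries,
    recirculation_fraction,
    time_average,
    tip_statistics,
    vorticity,
    wall_shear_stress,
)
from .solver import SolveResult, solve_transient

__all__ = ["run_pipeline", "summarise"]

_WALL_SIDES_2D = ("x-", "x+", "y-", "y+")


def summarise(result: SolveResult, tau_threshold: float = C.PLATELET_TAU_THRESHOLD) -> dict:
    """Per-model metric row from the analysis cycle of a run.

    Wall shear stress is averaged over all four chamber walls and over
    the cycle; vorticity is the time average of the volume-averaged
    magnitude; Rf and tip statistics are present only for catheter runs.
    """
    snaps = result.analysis_cycle_snapshots
    times = np.array([s.time for s in snaps])
    props = result.props

    vort_means = [float(np.mean(vorticity(s)[1])) for s in snaps]
    wss_means = [
        float(np.mean([wall_shear_stress(s, side, props)[1] for side in _WALL_SIDES_2D]))
        for s in snaps
    ]
    row = {
        "vorticity_mean": time_average(TimeSeries("vort", times, np.array(vort_means))),
        "wss_mean": time_average(TimeSeries("wss", times, np.array(wss_means))),
    }

    cath = result.geometry.catheter
    if cath is not None:
        ps = result.patch_series["cath_arterial"]
        mask = ps.times >= times[0] - 1e-12
        rf = recirculation_fraction(
            ps.times[mask], ps.phi[mask], np.abs(ps.un[mask]), ps.areas, props.rho
        )
        tip = tip_statistics(snaps, cath.tip_volume, props, tau_threshold)
        row.update(
            {
                "Rf_pct": rf.Rf,
                "tip_tau_mean": tip.tau_mean_avg,
                "tip_frac_above_pct": tip.frac_above_avg,
            }
        )
    return row


def run_pipeline(cfg, out_dir: str | Path | None = None):
    """Run one configured model; optionally write snapshots; return
    ``(SolveResult, metric_row)``."""
    from . import io as afio

    geom = cfg.geometry()
    result = solve_transient(
        geom,
        props=cfg.fluid_properties(),
        waveform=cfg.waveform(),
        catheter=cfg.catheter(),
        settings=cfg.solver_settings(),
    )
    row = summarise(result, tau_threshold=cfg["metrics"]["tau_threshold_pa"])
    if out_dir is not None and cfg["output"]["write_vtk"]:
        afio.write_fields(result.analysis_cycle_snapshots, Path(out_dir) / "fields")
    return result, row
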