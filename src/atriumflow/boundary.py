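"""Cardiac-cycle timing, inlet pressure waveforms, catheter operating points
and clinical unit conversions.

The venous inlet pressure is a periodic, two-peaked waveform (the atrial
a-wave during late diastole and the venous-filling v-wave during systole)
imposed identically and spatially uniformly at both caval inlets.  Because
the exact sampled pressures of the reference waveform are not tabulated
anywhere machine-readable, the default generator is parametric: mean gauge
pressure, pulse amplitude, and peak-timing fractions.  A sampled waveform
can instead be loaded from CSV (see :mod:`atriumflow.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import constants as C

__all__ = [
    "CardiacCycle",
    "InletWaveform",
    "CatheterOperatingPoint",
    "sample_waveform",
    "build_default_waveform",
    "convert_units",
]


@dataclass(frozen=True)
class CardiacCycle:
    """Cardiac-cycle timing: ``period = diastole + systole`` [s]."""

    diastole: float = C.DIASTOLE
    systole: float = C.SYSTOLE

    def __post_init__(self) -> None:
        if self.diastole <= 0 or self.systole <= 0:
            raise ValueError("diastole and systole must be positive")

    @property
    def period(self) -> float:
        return self.diastole + self.systole


@dataclass
class InletWaveform:
    """Pressure samples [Pa] on a uniform time grid covering one period.

    The grid includes both endpoints (t = 0 and t = period) and the waveform
    must be periodic: first and last samples agree to a small tolerance.
    """

    cycle: CardiacCycle
    times: np.ndarray
    pressures: np.ndarray
    interpolation: str = "linear"
    mean_band_mmhg: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.shape != self.pressures.shape or self.times.ndim != 1:
            raise ValueError("times and pressures must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise ValueError("waveform needs at least 3 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("time grid must be uniform")
        if abs(self.times[0]) > 1e-12 or abs(self.times[-1] - self.cycle.period) > 1e-9:
            raise ValueError("time grid must cover exactly [0, period]")
        scale = max(1.0, float(np.max(np.abs(self.pressures))))
        if abs(self.pressures[0] - self.pressures[-1]) > 1e-9 * scale:
            raise ValueError("waveform must be periodic (first sample == last sample)")
        if self.interpolation not in ("linear", "periodic-spline"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        mean_mmhg = self.mean_pressure() / C.MMHG_TO_PA
        lo, hi = self.mean_band_mmhg
        if not (lo - 1e-9 <= mean_mmhg <= hi + 1e-9):
            raise ValueError(
                f"mean gauge pressure {mean_mmhg:.3f} mmHg outside "
                f"physiological band [{lo}, {hi}] mmHg"
            )
        if self.interpolation == "periodic-spline":
            self._spline = CubicSpline(self.times, self.pressures, bc_type="periodic")
        else:
            self._spline = None

    def mean_pressure(self) -> float:
        """Trapezoidal time-average over one period [Pa]."""
        return float(np.trapezoid(self.pressures, self.times) / self.cycle.period)

    def __call__(self, t) -> float:
        return sample_waveform(self, t)


def sample_waveform(w: InletWaveform, t):
    """Pressure [Pa] at time ``t`` [s], periodic in the cycle period.

    Exact at grid points; between them the configured interpolation is used.
    Scalar or array ``t`` accepted; negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    tau = np.mod(t_arr, w.cycle.period)
    if w._spline is not None:
        out = w._spline(tau)
    else:
        out = np.interp(tau, w.times, w.pressures)
    if np.ndim(t) == 0:
        return float(out)
    return out


def build_default_waveform(
    cycle: CardiacCycle | None = None,
    mean_p: float = C.MEAN_RA_PRESSURE_MMHG,
    pulse_amplitude: float = 2.0,
    n_samples: int = 161,
    a_peak_fraction: float = 0.85,
    v_peak_fraction: float = 0.45,
    v_peak_ratio: float = 0.75,
    interpolation: str = "linear",
    mean_band_mmhg: tuple[float, float] = (0.0, 5.0),
) -> InletWaveform:
    """Parametric two-peaked venous pressure waveform.

    Parameters
    ----------
    cycle : CardiacCycle
        Timing; default 0.8 s = 0.5 s diastole + 0.3 s systole.
    mean_p : float
        Target time-averaged gauge pressure [mmHg]; the output's trapezoidal
        mean matches it exactly by construction.
    pulse_amplitude : float
        Peak-to-trough pressure excursion [mmHg].
    a_peak_fraction, v_peak_fraction : float
        Locations of the dominant a-wave (atrial contraction, late diastole)
        and of the secondary v-wave (systolic venous filling) as fractions of
        the period.
    v_peak_ratio : float
        Height of the v-wave relative to the a-wave.
    """
    if cycle is None:
        cycle = CardiacCycle()
    if pulse_amplitude < 0:
        raise ValueError("pulse amplitude must be non-negative")
    T = cycle.period
    t = np.linspace(0.0, T, n_samples)

    def periodic_bump(center: float, width: float) -> np.ndarray:
        # wrapped Gaussian so the shape is exactly periodic
        d = np.angle(np.exp(2j * np.pi * (t - center) / T)) * T / (2 * np.pi)
        return np.exp(-0.5 * (d / width) ** 2)

    shape = periodic_bump(a_peak_fraction * T, 0.06 * T) + v_peak_ratio * periodic_bump(
        v_peak_fraction * T, 0.08 * T
    )
    # remove the periodic trapezoidal mean, then scale to the requested amplitude
    shape = shape - np.trapezoid(shape, t) / T
    span = shape.max() - shape.min()
    if span > 0 and pulse_amplitude > 0:
        shape = shape * (pulse_amplitude / span)
    else:
        shape = np.zeros_like(shape)
    p_mmhg = mean_p + shape
    if np.any(p_mmhg * C.MMHG_TO_PA < -101325.0):
        raise ValueError("amplitude produces negative absolute pressure")
    return InletWaveform(
        cycle=cycle,
        times=t,
        pressures=p_mmhg * C.MMHG_TO_PA,
        interpolation=interpolation,
        mean_band_mmhg=mean_band_mmhg,
    )


@dataclass(frozen=True)
class CatheterOperatingPoint:
    """Dialysis-machine operating point of one catheter.

    ``venous_flow`` is the constant return flow through the venous lumen
    [ml/min]; gauge pressures are in mmHg.  ``mode="reverse"`` swaps the
    venous and arterial lumen roles of the catheter tips.
    """

    venous_flow: float = C.VENOUS_FLOW_ML_MIN
    venous_gauge_pressure: float = C.VENOUS_GAUGE_MMHG
    arterial_gauge_pressure: float = C.ARTERIAL_GAUGE_MMHG["A"]
    arterial_flow: float = C.ARTERIAL_FLOW_ML_MIN["A"]
    mode: str = "standard"

    def __post_init__(self) -> None:
        if self.venous_flow <= 0:
            raise ValueError("venous flow must be positive")
        if self.arterial_flow <= 0:
            raise ValueError("arterial flow must be positive")
        if self.arterial_gauge_pressure >= self.venous_gauge_pressure:
            raise ValueError("arterial gauge pressure must be below venous")
        if self.mode not in ("standard", "reverse"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def for_design(cls, design: str, mode: str = "standard") -> "CatheterOperatingPoint":
        d = design[0].upper()
        return cls(
            arterial_gauge_pressure=C.ARTERIAL_GAUGE_MMHG[d],
            arterial_flow=C.ARTERIAL_FLOW_ML_MIN[d],
            mode=mode,
        )


_CONVERSIONS = {
    "mmHg_to_Pa": C.MMHG_TO_PA,
    "Pa_to_mmHg": 1.0 / C.MMHG_TO_PA,
    "ml_min_to_m3_s": C.ML_MIN_TO_M3_S,
    "m3_s_to_ml_min": 1.0 / C.ML_MIN_TO_M3_S,
    "Fr_to_mm": C.FR_TO_MM,
    "mm_to_Fr": 1.0 / C.FR_TO_MM,
}


def convert_units(value, kind: str):
    """Exact linear unit conversion.

    ``kind`` is one of ``mmHg_to_Pa``, ``Pa_to_mmHg``, ``ml_min_to_m3_s``,
    ``m3_s_to_ml_min``, ``Fr_to_mm``, ``mm_to_Fr``.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("value must be finite")
    if kind not in _CONVERSIONS:
        raise ValueError(
            f"unknown conversion {kind!r}; expected one of {sorted(_CONVERSIONS)}"
        )
    out = arr * _CONVERSIONS[kind]
    if np.ndim(value) == 0:
        return float(out)
    return out
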