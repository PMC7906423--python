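"""Pulsatile venous inlet pressure waveform.

A two-peaked (a-wave / v-wave) periodic gauge-pressure waveform over the
0.8 s cardiac cycle (0.5 s diastole + 0.3 s systole), with its
time-average pinned to the normal mean right-atrial pressure of 3 mmHg.
"""

import numpy as np

import atriumflow as af
from atriumflow import constants as C

w = af.build_default_waveform(mean_p=3.0, pulse_amplitude=2.0)
print(f"period   : {w.cycle.period} s  (diastole {w.cycle.diastole}, systole {w.cycle.systole})")
print(f"mean     : {w.mean_pressure() / C.MMHG_TO_PA:.3f} mmHg")
t = np.linspace(0.0, w.cycle.period, 9)
p = af.sample_waveform(w, t) / C.MMHG_TO_PA
print("samples  :", "  ".join(f"{ti:.1f}s:{pi:.2f}" for ti, pi in zip(t, p)))
print(f"periodic : p(0) == p(T) -> {af.sample_waveform(w, 0.0) == af.sample_waveform(w, 0.8)}")
# The sampled pressures stay inside the 0-5 mmHg physiological band and
# repeat exactly every cycle; this series drives both caval inlets.
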