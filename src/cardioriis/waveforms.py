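"""Outlet pressure waveforms (mmHg sample tables, converted at the config
boundary).

The aortic outlet carries a physiological systolic pressure trace in all
scenarios (with compensated regurgitation the afterload stays
physiological).  The atrial outlet is a constant 10 mmHg for the healthy
scenario (Wiggers-diagram level); the regurgitant scenarios use an
elevated-V-wave shape peaking in late systole.  The regurgitant table is a
documented stand-in with the literature's qualitative shape (the source
waveform is not tabulated anywhere reusable); both tables are expressed on
the normalized time base t / T_S so each scenario's heart rate rescales
them.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

MMHG = 133.322

__all__ = ["aortic_pressure", "atrial_pressure", "load_waveform_csv"]

# normalized time, mmHg
_AORTIC_TABLE = (
    np.array([0.0, 0.10, 0.25, 0.40, 0.55, 0.70, 0.85, 1.0]),
    np.array([80.0, 95.0, 112.0, 120.0, 118.0, 112.0, 105.0, 100.0]),
)
_ATRIAL_VWAVE_TABLE = (
    np.array([0.0, 0.20, 0.40, 0.60, 0.80, 0.90, 1.0]),
    np.array([10.0, 13.0, 18.0, 26.0, 34.0, 35.0, 30.0]),
)

HEALTHY_ATRIAL_MMHG = 10.0


def _interp(table, t_s: float):
    s, p = table
    f = PchipInterpolator(s * t_s, p * MMHG)

    def waveform(t: float) -> float:
        return float(f(np.clip(t, 0.0, t_s)))

    return waveform


def aortic_pressure(t_s: float):
    """Aortic outlet pressure (Pa) as a function of time, on [0, t_s]."""
    return _interp(_AORTIC_TABLE, t_s)


def atrial_pressure(t_s: float, regurgitant: bool):
    """Atrial outlet pressure (Pa): constant 10 mmHg when healthy,
    elevated V wave otherwise."""
    if not regurgitant:
        const = HEALTHY_ATRIAL_MMHG * MMHG

        def waveform(t: float) -> float:
            return const

        return waveform
    return _interp(_ATRIAL_VWAVE_TABLE, t_s)


def load_waveform_csv(path: str, t_s: float):
    """Custom waveform from a two-column CSV (t_s, p_mmHg); the time column
    may be normalized (max <= 1) or absolute seconds."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, p = data[:, 0], data[:, 1]
    if t.max() <= 1.0 + 1e-9:
        t = t * t_s
    return _interp((t / t_s, p), t_s)
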