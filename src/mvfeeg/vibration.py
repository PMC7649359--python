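"""Vibrotactile stimulus waveform used by the synthetic experiment.

The actuator signal is a 27 Hz sine amplitude-modulated by a 175 Hz sine
carrier; intermittent stimulation gates it with a 1 s-on / 1 s-off square
envelope. The waveform is generated for logging and for the simulated
stimulus channel only — it never enters the EEG model.
"""

from __future__ import annotations

import numpy as np

MODULATION_HZ = 27.0
CARRIER_HZ = 175.0
MAX_AMPLITUDE_UM = 11.3
GATE_PERIOD_S = 1.0  # intermittent mode: 1 s on, 1 s off


def vibration_waveform(
    kind: str, dur_s: float, amplitude_um: float = MAX_AMPLITUDE_UM, fs: float = 2000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Return (t, v) for a vibration burst of the given condition.

    Parameters
    ----------
    kind : {"CV", "IV"}
        Continuous or intermittent (1 s on / 1 s off) stimulation.
    dur_s : float
        Burst duration in seconds; must be positive.
    amplitude_um : float
        Peak displacement in micrometers; capped at the actuator maximum
        (11.3 um at resonance).
    fs : float
        Sampling rate of the returned waveform.
    """
    if kind not in ("CV", "IV"):
        raise ValueError(f"kind must be 'CV' or 'IV', got {kind!r}")
    if dur_s <= 0:
        raise ValueError("duration must be positive")
    if amplitude_um > MAX_AMPLITUDE_UM:
        raise ValueError(f"amplitude exceeds actuator maximum {MAX_AMPLITUDE_UM} um")
    t = np.arange(int(round(dur_s * fs))) / fs
    v = amplitude_um * np.sin(2 * np.pi * MODULATION_HZ * t) * np.sin(2 * np.pi * CARRIER_HZ * t)
    if kind == "IV":
        v = v * intermittent_gate(t)
    return t, v


def intermittent_gate(t: np.ndarray) -> np.ndarray:
    """1 during odd seconds [0,1), [2,3), ...; 0 during the interleaved rests."""
    return (np.floor(t / GATE_PERIOD_S).astype(int) % 2 == 0).astype(float)
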