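"""Shared fixtures.

The full-pipeline fixture runs every experimental condition through the
periphery and both pitch models once per session; the model-structure and
asymmetry tests all read from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import tempasym as ta
from tempasym import aim, gpm, periphery

HALF_LIVES = (0.5, 1.0, 4.0, 16.0, 32.0)
CONDITIONS = [(e, h) for e in ("ramped", "damped") for h in HALF_LIVES]


@dataclass
class ConditionResult:
    nap: periphery.NeuralActivityPattern
    cascade: gpm.CascadeResult
    sai: aim.StabilisedAuditoryImage
    strobes: aim.StrobeTrain
    sai_salience: float
    nap_energy: float


@pytest.fixture(scope="session")
def pipeline():
    """Periphery + adaptive GPM + SAI for all 10 conditions, plus the
    static-window control for the critical 4 ms pair."""
    results: dict[tuple[str, float], ConditionResult] = {}
    static_4ms: dict[str, gpm.CascadeResult] = {}
    for etype, hl in CONDITIONS:
        w = ta.make_stimulus(hl, etype)
        nap = periphery.waveform_to_nap(w)
        cascade = gpm.run_cascade(nap)
        strobes = aim.detect_strobes(nap)
        sai = aim.build_sai(nap, strobes)
        results[(etype, hl)] = ConditionResult(
            nap=nap,
            cascade=cascade,
            sai=sai,
            strobes=strobes,
            sai_salience=aim.carrier_salience(sai, 1000.0),
            nap_energy=aim.nap_energy(nap),
        )
        if hl == 4.0:
            static_4ms[etype] = gpm.static_window_control(nap)
    return results, static_4ms


@pytest.fixture(scope="session")
def tone_nap():
    """NAP of a plain 1 kHz tone at the stimulus level (periphery checks)."""
    fs = 48000.0
    t = np.arange(int(fs)) / fs
    w = ta.Waveform(0.1 * np.sqrt(2.0) * np.sin(2 * np.pi * 1000.0 * t), fs)
    return periphery.waveform_to_nap(w)


def periodic_test_nap(
    freq_hz: float = 1000.0,
    duration_ms: float = 400.0,
    rate_hz: float = 8000.0,
    n_channels: int = 3,
) -> periphery.NeuralActivityPattern:
    """Tiny synthetic NAP: half-rectified sinusoids, no periphery."""
    n = int(round(duration_ms * rate_hz / 1000.0))
    t = np.arange(n) / rate_hz
    p = np.maximum(np.sin(2 * np.pi * freq_hz * t), 0.0)
    pattern = np.stack([p * (1.0 + 0.1 * k) for k in range(n_channels)], axis=1)
    cfs = 800.0 + 200.0 * np.arange(n_channels)
    return periphery.NeuralActivityPattern(pattern, cfs, rate_hz)
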