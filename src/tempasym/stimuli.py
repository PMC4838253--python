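"""Ramped and damped sinusoid trains.

A ramped/damped sinusoid is a pure-tone carrier multiplied by a periodic
exponential envelope that either decays (damped) or rises (ramped) within
each modulation cycle.  The two members of a pair are within-cycle mirror
images of each other and share an identical long-term magnitude spectrum,
which makes them the canonical probe for temporal-asymmetry processing in
the auditory system.

The envelope is parameterised by its half-life ``T_1/2`` (ms)::

    E(t) = (1 / T_half) * exp(-t * ln2 / T_half)        (damped)
    E_r(t) = E(cycle_ms - t)                            (ramped)

with ``t`` in ``[0, cycle_ms)``.  The cycle length is chosen so that it
holds an integer number of carrier periods; the envelope discontinuity at
each cycle boundary then falls on an upward-going zero crossing of the
carrier and every cycle starts in the same phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "EnvelopeType",
    "StimulusSpec",
    "Waveform",
    "AsymmetryResult",
    "HALF_LIVES_MS",
    "envelope",
    "synthesize_train",
    "normalize_level",
    "default_level_ref",
    "asymmetry_index",
    "write_wav",
    "read_wav",
]

#: Half-life times used throughout the study (ms).
HALF_LIVES_MS = (0.5, 1.0, 4.0, 16.0, 32.0)

_LN2 = math.log(2.0)


class EnvelopeType(str, Enum):
    RAMPED = "ramped"
    DAMPED = "damped"


@dataclass(frozen=True)
class StimulusSpec:
    """Full parameterisation of one ramped/damped train.

    The defaults reproduce the experimental conditions: 1 kHz carrier,
    twenty 50 ms cycles (1 s total) sampled at 48 kHz.
    """

    carrier_hz: float = 1000.0
    half_life_ms: float = 4.0
    envelope_type: EnvelopeType = EnvelopeType.DAMPED
    n_cycles: int = 20
    cycle_ms: float = 50.0
    sample_rate_hz: float = 48000.0
    level_ref: float | None = None

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise ValueError("carrier_hz must be positive")
        if self.half_life_ms <= 0:
            raise ValueError("half_life_ms must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        periods = self.cycle_ms * self.carrier_hz / 1000.0
        if abs(periods - round(periods)) > 1e-9:
            raise ValueError(
                "cycle_ms must hold an integer number of carrier periods "
                f"(got {periods}); phase alignment at cycle boundaries is "
                "impossible otherwise"
            )

    @property
    def duration_ms(self) -> float:
        return self.n_cycles * self.cycle_ms

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate_hz / 1000.0))

    @property
    def label(self) -> str:
        hl = self.half_life_ms
        hl_str = f"{hl:g}"
        return f"{self.envelope_type.value}_{hl_str}ms"


@dataclass
class Waveform:
    """Sampled audio plus optional stimulus metadata."""

    samples: np.ndarray
    sample_rate_hz: float
    spec: StimulusSpec | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * 1000.0 / self.sample_rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class AsymmetryResult:
    """Ramped/damped contrast of some magnitude x at one half-life."""

    half_life_ms: float
    x_ramped: float
    x_damped: float
    ai: float


def envelope(
    t_ms: np.ndarray | float,
    half_life_ms: float,
    envelope_type: EnvelopeType | str = EnvelopeType.DAMPED,
    cycle_ms: float = 50.0,
) -> np.ndarray | float:
    """Periodic exponential envelope, evaluated within one cycle.

    Returns the envelope value (units 1/ms) at time ``t_ms`` in
    ``[0, cycle_ms)``.  The damped branch is
    ``(1/T_half) * exp(-t ln2 / T_half)``; the ramped branch is its
    within-cycle time reverse, ``E_damped(cycle_ms - t)``.
    """
    if half_life_ms <= 0:
        raise ValueError("half_life_ms must be positive")
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0) or np.any(t >= cycle_ms):
        raise ValueError("t must lie in the half-open cycle [0, cycle_ms)")
    etype = EnvelopeType(envelope_type)
    if etype is EnvelopeType.RAMPED:
        t = cycle_ms - t
    out = (1.0 / half_life_ms) * np.exp(-t * _LN2 / half_life_ms)
    if np.isscalar(t_ms):
        return float(out)
    return out


def synthesize_train(spec: StimulusSpec) -> Waveform:
    """Carrier sinusoid times the periodic envelope, ``n_cycles`` cycles.

    The carrier is a global ``sin(2*pi*f*t)``; because each cycle holds an
    integer number of carrier periods the waveform is zero with positive
    slope at every cycle boundary.
    """
    fs = spec.sample_rate_hz
    t_ms = np.arange(spec.n_samples) * 1000.0 / fs
    phase_in_cycle = np.mod(t_ms, spec.cycle_ms)
    env = envelope(phase_in_cycle, spec.half_life_ms, spec.envelope_type, spec.cycle_ms)
    carrier = np.sin(2.0 * np.pi * spec.carrier_hz * t_ms / 1000.0)
    return Waveform(env * carrier, fs, spec)


_LEVEL_REF_CACHE: dict[tuple, float] = {}


def default_level_ref(
    carrier_hz: float = 1000.0,
    cycle_ms: float = 50.0,
    sample_rate_hz: float = 48000.0,
    target_rms: float = 0.1,
) -> float:
    """Normalisation constant such that the T_half = 4 ms train has the
    target RMS (0.1 full scale) after sqrt(T_half) level scaling.

    Only proportionality to sqrt(T_half) is physically meaningful (absolute
    level is a playback property); this fixes the remaining free constant.
    """
    key = (carrier_hz, cycle_ms, sample_rate_hz, target_rms)
    if key not in _LEVEL_REF_CACHE:
        spec = StimulusSpec(
            carrier_hz=carrier_hz,
            half_life_ms=4.0,
            envelope_type=EnvelopeType.DAMPED,
            cycle_ms=cycle_ms,
            sample_rate_hz=sample_rate_hz,
        )
        raw = synthesize_train(spec)
        _LEVEL_REF_CACHE[key] = target_rms / (raw.rms() * math.sqrt(4.0))
    return _LEVEL_REF_CACHE[key]


def normalize_level(
    w: Waveform, half_life_ms: float, level_ref: float | None = None
) -> Waveform:
    """Scale a waveform by ``level_ref * sqrt(half_life_ms)``.

    The exponential envelope carries a ``1/T_half`` amplitude factor, so its
    RMS goes as ``1/sqrt(T_half)``; scaling by ``sqrt(T_half)`` therefore
    approximately equalises loudness across half-life conditions.
    """
    if half_life_ms <= 0:
        raise ValueError("half_life_ms must be positive")
    if level_ref is None:
        if w.spec is not None and w.spec.level_ref is not None:
            level_ref = w.spec.level_ref
        else:
            level_ref = default_level_ref(
                sample_rate_hz=w.sample_rate_hz,
                cycle_ms=w.spec.cycle_ms if w.spec is not None else 50.0,
                carrier_hz=w.spec.carrier_hz if w.spec is not None else 1000.0,
            )
    scaled = w.samples * (level_ref * math.sqrt(half_life_ms))
    spec = replace(w.spec, level_ref=level_ref) if w.spec is not None else None
    return Waveform(scaled, w.sample_rate_hz, spec)


def make_stimulus(
    half_life_ms: float,
    envelope_type: EnvelopeType | str,
    **kwargs,
) -> Waveform:
    """Synthesize one level-normalised experimental stimulus."""
    spec = StimulusSpec(
        half_life_ms=half_life_ms,
        envelope_type=EnvelopeType(envelope_type),
        **kwargs,
    )
    return normalize_level(synthesize_train(spec), half_life_ms)


def stimulus_set(**kwargs) -> dict[tuple[str, float], Waveform]:
    """All 10 experimental conditions: {ramped, damped} x 5 half-lives."""
    out: dict[tuple[str, float], Waveform] = {}
    for etype in (EnvelopeType.RAMPED, EnvelopeType.DAMPED):
        for hl in HALF_LIVES_MS:
            out[(etype.value, hl)] = make_stimulus(hl, etype, **kwargs)
    return out


def asymmetry_index(x_ramped: float, x_damped: float) -> float:
    """Temporal asymmetry index AI = (x_r - x_d) / (x_r + x_d).

    Bounded in [-1, 1] for non-negative magnitudes; undefined when the
    denominator vanishes (the index is not well defined near zero).
    """
    denom = x_ramped + x_damped
    if denom == 0:
        raise ZeroDivisionError(
            "asymmetry index undefined: x_ramped + x_damped is zero"
        )
    return (x_ramped - x_damped) / denom


def write_wav(w: Waveform, path: str | Path) -> Path:
    """Write a waveform as 32-bit float WAV."""
    path = Path(path)
    wavfile.write(path, int(round(w.sample_rate_hz)), w.samples.astype(np.float32))
    return path


def read_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":  # pragma: no cover - depends on input file
        data = data / float(np.iinfo(data.dtype).max)
    data = np.asarray(data, dtype=float)
    if data.ndim > 1:
        data = data.mean(axis=1)
    return Waveform(data, float(rate))
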