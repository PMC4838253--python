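"""Auditory periphery: gammatone filterbank and hair-cell transduction.

This is the shared front end of both pitch models.  A waveform is passed
through a bank of gammatone filters with characteristic frequencies (CFs)
spaced on the ERB-rate scale across 100-10000 Hz (100 channels by
default), and each channel is then converted into an auditory-nerve
spike-probability trace by a functional hair-cell stage:

  half-wave rectification -> power-law compression (exponent 0.6 above a
  low-level knee, linear below it) -> low-pass smoothing at the
  phase-locking limit (3 kHz) -> divisive short-term adaptation.

The knee keeps near-silent channels near-silent (a pure power law would
expand them), and the low-pass cutoff preserves the phase-locked fine
structure of a 1 kHz carrier on which the lag analysis depends.

The divisive adaptation normalises each channel by a slowly-varying
(~30 ms) trace of its own recent activity, producing the onset emphasis
and sustained-response build-up characteristic of auditory-nerve firing.
The result is the neural activity pattern (NAP) ``p(t, k) >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .stimuli import Waveform

__all__ = [
    "NeuralActivityPattern",
    "erb_space",
    "filterbank",
    "transduce",
    "decimate_nap",
    "waveform_to_nap",
    "nap_cycle_centroid",
    "write_nap",
    "read_nap",
]


@dataclass
class NeuralActivityPattern:
    """Time x channel matrix of auditory-nerve spike probabilities."""

    p: np.ndarray  # (n_frames, n_channels), >= 0
    channel_cfs: np.ndarray  # strictly increasing CFs in Hz
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.channel_cfs = np.asarray(self.channel_cfs, dtype=float)
        if self.p.ndim != 2:
            raise ValueError("p must be a (time, channel) matrix")
        if self.p.shape[1] != self.channel_cfs.size:
            raise ValueError("channel count mismatch between p and channel_cfs")
        if np.any(self.p < 0):
            raise ValueError("spike probabilities must be non-negative")
        if np.any(np.diff(self.channel_cfs) <= 0):
            raise ValueError("channel_cfs must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.p.shape[0]

    @property
    def n_channels(self) -> int:
        return self.p.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms


def _hz_to_erb_rate(f_hz: np.ndarray | float) -> np.ndarray | float:
    # Glasberg & Moore ERB-rate scale
    return 21.4 * np.log10(4.37e-3 * np.asarray(f_hz, dtype=float) + 1.0)


def _erb_rate_to_hz(e: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 4.37e-3


def erb_space(fmin_hz: float, fmax_hz: float, n: int) -> np.ndarray:
    """``n`` frequencies equally spaced on the ERB-rate scale, ascending."""
    if not fmin_hz < fmax_hz:
        raise ValueError("fmin must be < fmax")
    if n < 2:
        raise ValueError("need at least 2 channels")
    pts = np.linspace(_hz_to_erb_rate(fmin_hz), _hz_to_erb_rate(fmax_hz), n)
    return np.asarray(_erb_rate_to_hz(pts))


def _erb_bandwidth(cf_hz: float) -> float:
    return 24.7 * (4.37e-3 * cf_hz + 1.0)


def _gammatone_channel(x: np.ndarray, cf_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Fourth-order gammatone filter as a cascade of complex one-pole
    resonators (numerically stable at any CF, unlike a single
    high-order section)."""
    bw = 1.019 * _erb_bandwidth(cf_hz)
    lam = np.exp(-2.0 * np.pi * bw / fs)
    beta = 2.0 * np.pi * cf_hz / fs
    pole = lam * np.exp(1j * beta)
    # unit gain at the characteristic frequency
    gain = abs(1.0 - pole * np.exp(-1j * beta)) ** order
    y = x.astype(complex)
    for _ in range(order):
        y = signal.lfilter([1.0], [1.0, -pole], y)
    return gain * np.real(y)


def filterbank(
    w: Waveform,
    n_channels: int = 100,
    fmin_hz: float = 100.0,
    fmax_hz: float = 10000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gammatone basilar-membrane decomposition.

    Returns ``(bm, cfs)`` where ``bm`` is (n_samples, n_channels) and
    ``cfs`` the ERB-spaced characteristic frequencies.
    """
    x = np.asarray(w.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    cfs = erb_space(fmin_hz, fmax_hz, n_channels)
    fs = w.sample_rate_hz
    bm = np.empty((x.size, n_channels))
    for k, cf in enumerate(cfs):
        bm[:, k] = _gammatone_channel(x, cf, fs)
    return bm, cfs


def transduce(
    bm: np.ndarray,
    cfs: np.ndarray,
    sample_rate_hz: float,
    compression_exponent: float = 0.6,
    compression_knee: float = 0.03,
    saturation: float = 0.3,
    lowpass_hz: float = 3000.0,
    adapt_tau_ms: float = 30.0,
    adapt_strength: float = 0.5,
) -> NeuralActivityPattern:
    """Functional hair-cell stage: basilar membrane motion -> NAP.

    Compression is a continuous broken-stick law: linear below
    ``compression_knee``, ``x**exponent`` (rescaled for continuity)
    above it, followed by a saturating stage ``p / (p + saturation)``
    (firing-rate ceiling: sharp onset peaks are clipped, gradual rises
    are not).  ``adapt_strength`` scales the divisive feedback: each
    channel is divided by ``1 + strength * s(t)`` where ``s`` is an
    exponential average of that channel's own output with time constant
    ``adapt_tau_ms``.
    """
    bm = np.asarray(bm, dtype=float)
    if not np.all(np.isfinite(bm)):
        raise ValueError("non-finite basilar-membrane input")
    fs = sample_rate_hz
    # half-wave rectification and instantaneous compression
    x = np.maximum(bm, 0.0)
    knee = compression_knee
    p = np.where(
        x <= knee,
        x * knee ** (compression_exponent - 1.0),
        x**compression_exponent,
    )
    if saturation > 0:
        p = p / (p + saturation)
    # receptor low-pass (phase-locking roll-off)
    b, a = signal.butter(2, lowpass_hz / (fs / 2.0), btype="low")
    p = np.maximum(signal.lfilter(b, a, p, axis=0), 0.0)
    # divisive short-term adaptation; the smoother is a one-pole filter
    alpha = float(np.exp(-1000.0 / (fs * adapt_tau_ms)))
    s = signal.lfilter([1.0 - alpha], [1.0, -alpha], p, axis=0)
    p = p / (1.0 + adapt_strength * s)
    return NeuralActivityPattern(p, cfs, fs)


def decimate_nap(nap: NeuralActivityPattern, factor: int) -> NeuralActivityPattern:
    """Anti-aliased downsampling of the NAP along time."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return NeuralActivityPattern(
            nap.p.copy(), nap.channel_cfs.copy(), nap.sample_rate_hz
        )
    p = signal.decimate(nap.p, factor, axis=0, zero_phase=True)
    p = np.maximum(p, 0.0)  # anti-alias ringing can dip slightly below zero
    return NeuralActivityPattern(p, nap.channel_cfs.copy(), nap.sample_rate_hz / factor)


def waveform_to_nap(
    w: Waveform,
    n_channels: int = 100,
    fmin_hz: float = 100.0,
    fmax_hz: float = 10000.0,
    target_rate_hz: float = 8000.0,
    **transduce_kwargs,
) -> NeuralActivityPattern:
    """Full periphery: filterbank, transduction and decimation.

    By default the NAP is decimated to 8 kHz (0.125 ms frames), which
    resolves the 1 ms carrier lag while keeping the lag analysis cheap.
    """
    bm, cfs = filterbank(w, n_channels, fmin_hz, fmax_hz)
    nap = transduce(bm, cfs, w.sample_rate_hz, **transduce_kwargs)
    factor = int(round(w.sample_rate_hz / target_rate_hz))
    return decimate_nap(nap, max(factor, 1))


def nap_cycle_centroid(
    nap: NeuralActivityPattern, cycle_ms: float, channel: int
) -> float:
    """Energy centroid (ms) of one channel's activity within the cycle,
    averaged over cycles.  Early-concentrated activity gives a small
    centroid, late-concentrated a large one."""
    phase = np.mod(nap.times_ms, cycle_ms)
    p = nap.p[:, channel]
    if p.sum() == 0:
        raise ValueError("channel is silent")
    return float(np.sum(phase * p) / np.sum(p))


def write_nap(nap: NeuralActivityPattern, path: str | Path) -> Path:
    """Delimited text: one header line, then the (time, channel) matrix."""
    path = Path(path)
    header = (
        f"sample_rate_hz={nap.sample_rate_hz:g} "
        "cfs_hz=" + ",".join(f"{cf:.6g}" for cf in nap.channel_cfs)
    )
    np.savetxt(path, nap.p, header=header, fmt="%.8g")
    return path


def read_nap(path: str | Path) -> NeuralActivityPattern:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(item.split("=", 1) for item in header.split(" "))
    rate = float(fields["sample_rate_hz"])
    cfs = np.array([float(x) for x in fields["cfs_hz"].split(",")])
    p = np.loadtxt(path)
    if p.ndim == 1:
        p = p[:, None]
    return NeuralActivityPattern(p, cfs, rate)
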