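"""Seeded synthetic MEG / psychophysics data with the study's structure.

Real recordings for this paradigm are in-lab only, so every analysis
stage is exercised on generated data whose ground truth encodes the
qualitative experimental pattern:

* grand-truth N100m magnitudes ``M0`` grow with half-life within each
  envelope type, ramped >= damped everywhere, with the ramped/damped gap
  (and hence the asymmetry index) maximal at T1/2 = 4 ms;
* the extra right-hemisphere ramped response at 4 ms makes the
  ramped-damped contrast right-lateralised at that half-life only;
* ramped N100m latencies are delayed relative to damped (energy arrives
  late in each cycle);
* a sustained-field plateau spans ~300-1000 ms at a fixed fraction of M0;
* epochs carry linear drift and additive white noise (evoked averages,
  so the noise floor is sub-nAm);
* paired-comparison choices are Bernoulli draws from BTL win
  probabilities whose strengths are proportional to the
  hemisphere-averaged M0 — perception and fields are co-monotone by
  construction.

All randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aef import SourceWaveform
from .psychophysics import PairedComparisonTable, pair_schedule
from .stimuli import HALF_LIVES_MS

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "condition_labels",
    "synth_subject_waveforms",
    "synth_paired_comparisons",
]

CONDITIONS: tuple[tuple[str, float], ...] = tuple(
    (etype, hl) for etype in ("ramped", "damped") for hl in HALF_LIVES_MS
)


def condition_labels() -> list[str]:
    return [f"{etype}_{hl:g}ms" for etype, hl in CONDITIONS]


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters; defaults reproduce the target pattern."""

    # N100m magnitudes (positive; deflections are negative-going), nAm-like
    m0_ramped: dict = field(
        default_factory=lambda: {0.5: 11.0, 1.0: 14.0, 4.0: 22.0, 16.0: 25.0, 32.0: 28.0}
    )
    m0_damped: dict = field(
        default_factory=lambda: {0.5: 10.0, 1.0: 12.0, 4.0: 14.0, 16.0: 22.0, 32.0: 26.0}
    )
    # right-hemisphere boost of the ramped 4 ms response (nAm)
    right_ramped_4ms_boost: float = 5.0
    base_latency_ms: float = 100.0
    ramped_latency_delay_ms: float = 15.0
    n100m_sigma_ms: float = 15.0
    sf_fraction: float = 0.6  # sustained-field depth as a fraction of M0
    sf_onset_ms: float = 300.0
    # the plateau releases shortly after tone offset (1 s), so the
    # 800-1000 ms measurement window sits on the flat part
    sf_offset_ms: float = 1050.0
    sf_edge_ms: float = 50.0  # smoothing of the plateau edges
    noise_sd: float = 0.8
    drift_slope_range: float = 0.004  # |slope| upper bound, units per ms
    subject_jitter_sd: float = 0.2  # lognormal sigma on per-subject scale
    n_subjects: int = 27
    trials_per_ordered_pair: int = 20
    epoch_start_ms: float = -500.0
    epoch_end_ms: float = 1400.0
    sample_rate_hz: float = 1000.0

    def validate(self) -> None:
        for m0 in (self.m0_ramped, self.m0_damped):
            hls = sorted(m0)
            vals = [m0[h] for h in hls]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("M0 must be non-decreasing in half-life")
        for hl in self.m0_ramped:
            if self.m0_ramped[hl] < self.m0_damped[hl]:
                raise ValueError("M0(ramped) must be >= M0(damped)")
        if self.right_ramped_4ms_boost < 0:
            raise ValueError("right-hemisphere boost must be non-negative")
        if any(s <= 0 for s in self.btl_strengths().values()):
            raise ValueError("BTL strengths must be positive")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    def m0(self, etype: str, hl: float, hemisphere: str) -> float:
        base = self.m0_ramped[hl] if etype == "ramped" else self.m0_damped[hl]
        if hemisphere == "right" and etype == "ramped" and hl == 4.0:
            base += self.right_ramped_4ms_boost
        return base

    def btl_strengths(self) -> dict[str, float]:
        """Salience strengths proportional to hemisphere-averaged M0."""
        raw = {}
        for etype, hl in CONDITIONS:
            raw[f"{etype}_{hl:g}ms"] = 0.5 * (
                self.m0(etype, hl, "left") + self.m0(etype, hl, "right")
            )
        total = sum(raw.values())
        return {k: v / total for k, v in raw.items()}


def default_ground_truth() -> GroundTruth:
    gt = GroundTruth()
    gt.validate()
    return gt


def _smooth_edge(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Sigmoid rising from 0 to 1 around t0 over ~width ms."""
    return 1.0 / (1.0 + np.exp(-(t - t0) / (width / 4.0)))


def synth_subject_waveforms(
    gt: GroundTruth, seed: int | np.random.Generator
) -> list[SourceWaveform]:
    """Generate all subject x hemisphere x condition source epochs."""
    gt.validate()
    rng = np.random.default_rng(seed)
    n_samples = (
        int(round((gt.epoch_end_ms - gt.epoch_start_ms) * gt.sample_rate_hz / 1000.0))
        + 1
    )
    t = gt.epoch_start_ms + np.arange(n_samples) * 1000.0 / gt.sample_rate_hz
    out: list[SourceWaveform] = []
    for si in range(gt.n_subjects):
        subject = f"S{si + 1:02d}"
        # one multiplicative response scale per subject
        scale = float(np.exp(rng.normal(0.0, gt.subject_jitter_sd)))
        for hemisphere in ("left", "right"):
            for etype, hl in CONDITIONS:
                m0 = gt.m0(etype, hl, hemisphere) * scale
                latency = gt.base_latency_ms + (
                    gt.ramped_latency_delay_ms if etype == "ramped" else 0.0
                )
                deflection = -m0 * np.exp(
                    -0.5 * ((t - latency) / gt.n100m_sigma_ms) ** 2
                )
                sf = (
                    -gt.sf_fraction
                    * m0
                    * _smooth_edge(t, gt.sf_onset_ms, gt.sf_edge_ms)
                    * (1.0 - _smooth_edge(t, gt.sf_offset_ms, gt.sf_edge_ms))
                )
                drift = rng.uniform(-gt.drift_slope_range, gt.drift_slope_range) * (
                    t - t[0]
                )
                noise = rng.normal(0.0, gt.noise_sd, n_samples)
                out.append(
                    SourceWaveform(
                        subject=subject,
                        hemisphere=hemisphere,
                        envelope_type=etype,
                        half_life_ms=hl,
                        samples=deflection + sf + drift + noise,
                        sample_rate_hz=gt.sample_rate_hz,
                        epoch_start_ms=gt.epoch_start_ms,
                    )
                )
    return out


def synth_paired_comparisons(
    gt: GroundTruth, seed: int | np.random.Generator
) -> PairedComparisonTable:
    """Stochastic two-alternative 'more tonal' judgements.

    For each ordered pair (i, j) of the 10 conditions,
    ``trials_per_ordered_pair`` Bernoulli draws with
    P(i beats j) = S_i / (S_i + S_j).
    """
    gt.validate()
    rng = np.random.default_rng(seed)
    items = condition_labels()
    strengths = gt.btl_strengths()
    n = len(items)
    wins = np.zeros((n, n))
    for i, j in pair_schedule(n):
        p = strengths[items[i]] / (strengths[items[i]] + strengths[items[j]])
        k = rng.binomial(gt.trials_per_ordered_pair, p)
        wins[i, j] += k
        wins[j, i] += gt.trials_per_ordered_pair - k
    return PairedComparisonTable(items, wins)
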