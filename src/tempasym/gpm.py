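"""Hierarchical generative pitch model (GPM) with adaptive integration windows.

The model is a cascade of three layers operating on the neural activity
pattern p(t, k):

* stage 1 — coincidence detection across cochlear delay lines::

      A1(t, l) = sum_k p(t, k) * p(t - l, k)

* stages 2 and 3 — leaky integrators of the stage below, implemented as
  time-varying exponential averages with effective windows ``E_n(t)``::

      A_n(t, l) = A_n(t - dt, l) * exp(-dt / E_n(t))
                  + (1 - exp(-dt / E_n(t))) * A_{n-1}(t, l)

  The drive normalisation is chosen so that the steady-state response to a
  unit constant input is one, which makes plateau values independent of
  the integration step dt.

* a top-down controller modulating the window of each stage via the gain
  g(t) = omega_n(t) * lambda_n(t)::

      E_n(t) = tau_n / (1 + g(t))

  The controller shortens the windows (gain jump) when the lag prediction
  ``L3(t) = argmax_l A3(t, l)`` disagrees with its expectation
  ``L3(t - dt)`` by more than one lag bin, or when no such discrepancy has
  occurred for longer than a stability horizon; otherwise the gain relaxes
  exponentially back towards zero (static windows).

Stage 2 uses a lag-dependent time constant ``tau_2(l) = clip(2l, 2, 100)``
ms (periodicity extraction at sub-thalamic time scales); stage 3 uses a
single long central time constant (default 250 ms).  The read-out is the
activity at the predicted lag, ``A3(t, L3(t))``; its time derivative is
the model's predictor for the N100m transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LagGrid",
    "LagActivity",
    "IntegratorState",
    "PitchTrack",
    "TopDownParams",
    "TopDownController",
    "CascadeResult",
    "coincidence",
    "sacf",
    "effective_window",
    "integrate_stage",
    "topdown_gain_trace",
    "run_cascade",
    "static_window_control",
    "n100m_predictor",
    "model_n100m_amplitude",
    "default_lag_grid",
    "tau2_profile",
]


@dataclass(frozen=True)
class LagGrid:
    """Delay-line grid: lags l (ms) and integration step dt (ms)."""

    lags: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")

    @property
    def n_lags(self) -> int:
        return self.lags.size

    def nearest(self, lag_ms: float) -> int:
        return int(np.argmin(np.abs(self.lags - lag_ms)))


def default_lag_grid(
    dt_ms: float = 0.125,
    min_lag_ms: float = 0.5,
    max_lag_ms: float = 40.0,
) -> LagGrid:
    """Delay lines at NAP resolution over the existence region of
    periodicity pitch.

    The lower edge (0.5 ms, i.e. 2 kHz) excludes delays above the upper
    frequency limit of periodicity pitch, which also sit on the trivial
    zero-lag correlation ridge of any smoothed non-negative activity
    pattern; the upper edge keeps the 50 ms envelope lag outside the
    grid.  The 1 ms carrier lag and sub-envelope lags are covered.
    """
    n0 = int(round(min_lag_ms / dt_ms))
    n1 = int(round(max_lag_ms / dt_ms))
    return LagGrid(np.arange(n0, n1 + 1) * dt_ms, dt_ms)


@dataclass
class LagActivity:
    """Time x lag activity matrix for one cascade stage."""

    stage: int
    a: np.ndarray  # (n_frames, n_lags)
    grid: LagGrid

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        if self.a.ndim != 2 or self.a.shape[1] != self.grid.n_lags:
            raise ValueError("activity shape does not match lag grid")

    @property
    def final_profile(self) -> np.ndarray:
        return self.a[-1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.a.shape[0]) * self.grid.dt


@dataclass
class IntegratorState:
    """Traces of one integration stage: nominal and effective windows."""

    tau_n: np.ndarray  # per-lag (stage 2) or scalar-broadcast (stage 3), ms
    e_n: np.ndarray  # (n_frames,) effective-window trace E_n(t) in ms
    gain: np.ndarray  # (n_frames,) omega_n * lambda_n trace, >= 0
    g_n: np.ndarray = field(default=None)  # normalisation trace (informational)


@dataclass
class PitchTrack:
    """Lag prediction and read-out of the top stage."""

    times_ms: np.ndarray
    l3: np.ndarray  # predicted lag L3(t), ms
    salience: np.ndarray  # A3(t, L3(t))
    deriv: np.ndarray  # d/dt A3(t, L3(t)), per ms

    @property
    def pitch(self) -> np.ndarray:
        """Predicted pitch 1/L3(t) in kHz (equivalently 1/ms)."""
        return 1.0 / self.l3

    @property
    def expected(self) -> np.ndarray:
        """Expectation: the prediction at the previous time step."""
        out = np.empty_like(self.pitch)
        out[0] = self.pitch[0]
        out[1:] = self.pitch[:-1]
        return out

    def peak_salience(self) -> float:
        return float(np.max(self.salience))

    def settled_salience(self, settle_ms: float = 500.0) -> float:
        """Mean read-out over the settled portion of the response (after
        the onset transient, default the second half of a 1 s stimulus).
        This is the model's pitch-salience prediction."""
        mask = self.times_ms >= settle_ms
        if not np.any(mask):
            raise ValueError("settle time exceeds the track duration")
        return float(np.mean(self.salience[mask]))

    def smoothed_deriv(self, window_ms: float = 25.0) -> np.ndarray:
        """Time derivative of the read-out after a moving-average smooth.

        The evoked-field comparison lives below the 20 Hz envelope rate,
        so the read-out is smoothed over ``window_ms`` before
        differentiating; the raw per-frame derivative is dominated by
        within-cycle ripple.
        """
        dt = float(self.times_ms[1] - self.times_ms[0])
        k = max(int(round(window_ms / dt)), 1)
        kernel = np.ones(k) / k
        sm = np.convolve(self.salience, kernel, mode="same")
        return np.gradient(sm, dt)


def coincidence(nap, grid: LagGrid) -> LagActivity:
    """Stage 1: spike-coincidence probability across all channels.

    ``A1(t, l) = sum_k p(t, k) p(t - l, k)`` with ``p(t - l, .) = 0``
    before stimulus onset.  Lags must be (multiples of) the NAP frame
    period.
    """
    p = nap.p
    dt = nap.dt_ms
    shifts = grid.lags / dt
    if np.any(np.abs(shifts - np.round(shifts)) > 1e-6):
        raise ValueError(
            "lag grid is finer than (or incommensurate with) the NAP sampling"
        )
    shifts = np.round(shifts).astype(int)
    n = p.shape[0]
    if shifts.max() >= n:
        raise ValueError("max lag must be shorter than the NAP duration")
    a1 = np.zeros((n, grid.n_lags))
    for j, s in enumerate(shifts):
        a1[s:, j] = np.einsum("tk,tk->t", p[s:], p[: n - s])
    return LagActivity(1, a1, grid)


def sacf(a1: LagActivity, decay_ms: float = 2.5) -> np.ndarray:
    """Summary autocorrelation function: exponentially weighted running sum
    of A1 over time; the final-time lag profile is returned."""
    if decay_ms <= 0:
        raise ValueError("decay must be positive")
    if a1.stage != 1:
        raise ValueError("sacf expects stage-1 activity")
    dt = a1.grid.dt
    w = float(np.exp(-dt / decay_ms))
    s = np.zeros(a1.grid.n_lags)
    for row in a1.a:
        s = s * w + row * dt
    return s


def effective_window(gain: np.ndarray | float, tau_n: np.ndarray | float):
    """E_n = tau_n / (1 + gain): top-down gains shrink the window."""
    gain = np.asarray(gain, dtype=float)
    tau = np.asarray(tau_n, dtype=float)
    if np.any(gain < 0):
        raise ValueError("gain must be non-negative")
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    out = tau / (1.0 + gain)
    if out.ndim == 0:
        return float(out)
    return out


def tau2_profile(grid: LagGrid, lo_ms: float = 2.0, hi_ms: float = 100.0) -> np.ndarray:
    """Lag-dependent stage-2 time constant, clip(2*l, 2, 100) ms."""
    return np.clip(2.0 * grid.lags, lo_ms, hi_ms)


def _smoother_step(a_prev, drive, e_ms, dt):
    """One step of the normalised exponential average."""
    decay = np.exp(-dt / e_ms)
    return a_prev * decay + (1.0 - decay) * drive


def integrate_stage(
    prev: LagActivity,
    tau_n: np.ndarray | float,
    gain_trace: np.ndarray | float = 0.0,
    stage: int | None = None,
) -> tuple[LagActivity, IntegratorState]:
    """Run one leaky-integration stage over a full stage-(n-1) activity.

    ``gain_trace`` may be a scalar (static windows) or a per-frame trace.
    The state records tau_n, the E_n(t) trace and the gain trace.
    """
    grid = prev.grid
    dt = grid.dt
    n_frames = prev.a.shape[0]
    tau = np.broadcast_to(np.asarray(tau_n, dtype=float), (grid.n_lags,)).copy()
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    gains = np.broadcast_to(
        np.asarray(gain_trace, dtype=float), (n_frames,)
    ).copy()
    if np.any(gains < 0):
        raise ValueError("gain trace must be non-negative")
    out = np.zeros_like(prev.a)
    e_trace = np.empty(n_frames)
    a = np.zeros(grid.n_lags)
    for i in range(n_frames):
        e = tau / (1.0 + gains[i])
        a = _smoother_step(a, prev.a[i], e, dt)
        out[i] = a
        e_trace[i] = float(np.mean(e))
    stage_n = stage if stage is not None else prev.stage + 1
    # g_n such that the printed recursion's (dt^2 / (g tau)) drive matches
    # the normalised (1 - exp(-dt/E)) factor used here
    g_n = (dt**2 / (np.mean(tau))) / (1.0 - np.exp(-dt / e_trace))
    state = IntegratorState(tau_n=tau, e_n=e_trace, gain=gains, g_n=g_n)
    return LagActivity(stage_n, out, grid), state


@dataclass(frozen=True)
class TopDownParams:
    """Controller configuration (approximate re-implementation; the exact
    dynamics are model-internal choices, all exposed here).

    The expectation against which the current lag prediction is compared
    is a short exponential average of recent predictions
    (``expectation_tau_ms``): an instantaneous one-frame expectation
    would let a slowly drifting prediction — one-bin steps, each inside
    the tolerance — pass as 'stable' even though the pitch is changing.
    """

    mismatch_tol_bins: float = 1.0
    stability_horizon_ms: float = 250.0
    g_max: float = 9.0  # gain jump: E_n -> tau_n / 10
    relax_ms: float = 50.0
    expectation_tau_ms: float = 20.0


class TopDownController:
    """Causal gain controller driven by pitch prediction/expectation
    mismatch at the integration stages.  Call :meth:`step` once per frame
    with the current lag-bin predictions; read :attr:`gain` before
    updating the integrators at the next frame."""

    def __init__(self, params: TopDownParams, dt_ms: float, n_streams: int = 2):
        self.params = params
        self.dt = dt_ms
        self.gain = 0.0
        self._since_event_ms = 0.0
        self._relax = float(np.exp(-dt_ms / params.relax_ms))
        self._alpha = float(np.exp(-dt_ms / params.expectation_tau_ms))
        self._expect: list[float | None] = [None] * n_streams

    def mismatch(self, lag_bin: int, expectation: float | None) -> bool:
        """Prediction/expectation discrepancy beyond the tolerance."""
        return (
            expectation is not None
            and abs(lag_bin - expectation) > self.params.mismatch_tol_bins
        )

    def update(self, mismatch: bool) -> float:
        """Advance the gain one frame given the mismatch flag: jump to
        g_max on mismatch or after a long stable period, relax towards
        zero otherwise."""
        p = self.params
        self._since_event_ms += self.dt
        if mismatch or self._since_event_ms >= p.stability_horizon_ms:
            self.gain = p.g_max
            self._since_event_ms = 0.0
        else:
            self.gain *= self._relax
        return self.gain

    def step(self, *lag_bins: int) -> float:
        """Observe the current per-stage lag-bin predictions; a
        discrepancy at any stage activates the top-down mechanism."""
        mm = False
        for j, b in enumerate(lag_bins):
            mm = mm or self.mismatch(b, self._expect[j])
            e = self._expect[j]
            self._expect[j] = float(b) if e is None else (
                self._alpha * e + (1.0 - self._alpha) * b
            )
        return self.update(mm)


def topdown_gain_trace(
    l3_bins: np.ndarray, dt_ms: float, params: TopDownParams | None = None
) -> np.ndarray:
    """Offline gain trace for a given lag-bin prediction history."""
    params = params or TopDownParams()
    ctrl = TopDownController(params, dt_ms, n_streams=1)
    bins = np.asarray(l3_bins)
    out = np.empty(bins.size)
    for i, b in enumerate(bins):
        out[i] = ctrl.gain
        ctrl.step(int(b))
    return out


@dataclass
class CascadeResult:
    a1: LagActivity
    a2: LagActivity
    a3: LagActivity
    state2: IntegratorState
    state3: IntegratorState
    track: PitchTrack

    @property
    def grid(self) -> LagGrid:
        return self.a1.grid

    def settled_profile(self, window_ms: float = 250.0) -> np.ndarray:
        """Final A3 lag profile: time average over the last ``window_ms``
        (a single-frame snapshot at the stimulus offset would alias the
        phase of the last modulation cycle into the profile)."""
        t = self.a3.times_ms
        return self.a3.a[t >= t[-1] - window_ms].mean(axis=0)

    def peak_lag_ms(self, window_ms: float = 250.0) -> float:
        """Lag (ms) of the maximum of the final (settled) A3 profile."""
        prof = self.settled_profile(window_ms)
        return float(self.grid.lags[_argmax_shortest(prof)])


def _argmax_shortest(profile: np.ndarray) -> int:
    """Argmax with ties broken towards the shortest lag."""
    return int(np.argmax(profile))


def run_cascade(
    nap,
    grid: LagGrid | None = None,
    tau3_ms: float = 250.0,
    tau2_bounds_ms: tuple[float, float] = (2.0, 100.0),
    params: TopDownParams | None = None,
    adaptive: bool = True,
) -> CascadeResult:
    """Full GPM run: coincidence -> stage 2 -> stage 3 with the top-down
    controller in the loop.

    With ``adaptive=False`` the gain is clamped to zero, so
    ``E_n(t) = tau_n`` throughout — the static-window autocorrelation
    control.
    """
    if grid is None:
        grid = default_lag_grid(nap.dt_ms)
    params = params or TopDownParams()
    a1 = coincidence(nap, grid)
    dt = grid.dt
    n_frames = a1.a.shape[0]
    tau2 = tau2_profile(grid, *tau2_bounds_ms)
    if tau3_ms <= 0:
        raise ValueError("tau3 must be positive")

    ctrl = TopDownController(params, dt)
    a2 = np.zeros_like(a1.a)
    a3 = np.zeros_like(a1.a)
    e2_trace = np.empty(n_frames)
    e3_trace = np.empty(n_frames)
    gain_trace = np.empty(n_frames)
    l3_bins = np.empty(n_frames, dtype=int)
    salience = np.empty(n_frames)

    v2 = np.zeros(grid.n_lags)
    v3 = np.zeros(grid.n_lags)
    for i in range(n_frames):
        g = ctrl.gain if adaptive else 0.0
        gain_trace[i] = g
        e2 = tau2 / (1.0 + g)
        e3 = tau3_ms / (1.0 + g)
        v2 = _smoother_step(v2, a1.a[i], e2, dt)
        v3 = _smoother_step(v3, v2, e3, dt)
        a2[i] = v2
        a3[i] = v3
        e2_trace[i] = float(np.mean(e2))
        e3_trace[i] = e3
        b2 = _argmax_shortest(v2)
        b = _argmax_shortest(v3)
        l3_bins[i] = b
        salience[i] = v3[b]
        if adaptive:
            ctrl.step(b2, b)

    times = np.arange(n_frames) * dt
    deriv = np.gradient(salience, dt)
    track = PitchTrack(times, grid.lags[l3_bins], salience, deriv)
    state2 = IntegratorState(tau_n=tau2, e_n=e2_trace, gain=gain_trace)
    state3 = IntegratorState(
        tau_n=np.full(grid.n_lags, tau3_ms), e_n=e3_trace, gain=gain_trace
    )
    return CascadeResult(
        a1,
        LagActivity(2, a2, grid),
        LagActivity(3, a3, grid),
        state2,
        state3,
        track,
    )


def static_window_control(nap, **kwargs) -> CascadeResult:
    """Autocorrelation control: the same cascade with gains forced to zero
    (static integration windows E_n = tau_n)."""
    kwargs.pop("adaptive", None)
    return run_cascade(nap, adaptive=False, **kwargs)


def n100m_predictor(
    track: PitchTrack,
    slope: float,
    intercept: float,
    window_ms: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linear map from the model read-out derivative to a predicted
    evoked-field series: slope * deriv + intercept (over a window)."""
    deriv = track.deriv
    if window_ms is None:
        return slope * deriv + intercept
    t0, t1 = window_ms
    if t0 < track.times_ms[0] or t1 > track.times_ms[-1]:
        raise ValueError("requested window lies outside the track")
    mask = (track.times_ms >= t0) & (track.times_ms <= t1)
    return slope * deriv[mask] + intercept


def model_n100m_amplitude(
    track: PitchTrack,
    window_ms: tuple[float, float] = (25.0, 125.0),
    smooth_ms: float = 50.0,
) -> float:
    """Model-side N100m amplitude proxy: peak (smoothed) rise rate of
    A3(t, L3(t)) over the build-up to the N100m latency (~100 ms).

    The first frames are excluded because the evoked deflection this
    quantity models emerges tens of milliseconds after sound onset; the
    smoothing suppresses within-cycle ripple (see smoothed_deriv).
    """
    deriv = track.smoothed_deriv(smooth_ms)
    mask = (track.times_ms >= window_ms[0]) & (track.times_ms <= window_ms[1])
    return float(np.max(deriv[mask]))
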