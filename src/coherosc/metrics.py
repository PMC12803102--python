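"""Oscillation metrics: autocorrelation, damped-sinusoid fits, coherence.

Loss of ensemble coherence shows up as decay of the ensemble-averaged signal
and of its autocorrelation, even when individual trajectories keep
oscillating at full amplitude (dephasing).  The reports here separate the
two: a damped-cosine fit quantifies the ensemble decay rate and frequency,
while per-trajectory amplitude ratios distinguish dephasing (ratio near 1)
from genuine per-trajectory loss of oscillation (ratio near 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .ssa import TrajectoryEnsemble

__all__ = [
    "AutocorrelationCurve",
    "OscillationFit",
    "CoherenceReport",
    "autocorrelation",
    "fit_damped_oscillation",
    "coherence_report",
]


class DegenerateSignalError(ValueError):
    """Raised for zero-variance input where an ACF is undefined."""


@dataclass(frozen=True)
class AutocorrelationCurve:
    """Normalized autocorrelation: value 1 at lag 0, all values in [-1, 1]."""

    lags: np.ndarray  # lag times, nonnegative
    values: np.ndarray
    mode: str  # "per-trajectory" | "ensemble"
    n_signals: int


def _acf_biased(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/L) mean-subtracted estimator; bounded in [-1, 1]."""
    xc = x - x.mean()
    var = np.dot(xc, xc)
    if var == 0.0:
        raise DegenerateSignalError("zero-variance signal")
    return np.array([np.dot(xc[: len(x) - k], xc[k:]) / var
                     for k in range(max_lag + 1)])


def autocorrelation(signals, max_lag: int, mode: str = "per-trajectory",
                    dt: float = 1.0) -> AutocorrelationCurve:
    """ACF of uniformly sampled signal(s).

    ``signals`` is 1-D or (n_signals, length).  mode="per-trajectory"
    averages the individual-signal ACFs (zero-variance signals are skipped);
    mode="ensemble" takes the ACF of the across-signal mean.
    """
    arr = np.atleast_2d(np.asarray(signals, float))
    if max_lag >= arr.shape[1]:
        raise ValueError("max_lag must be smaller than the series length")
    lags = np.arange(max_lag + 1) * dt
    if mode == "ensemble":
        return AutocorrelationCurve(lags, _acf_biased(arr.mean(axis=0), max_lag),
                                    mode, arr.shape[0])
    if mode != "per-trajectory":
        raise ValueError(f"unknown ACF mode {mode!r}")
    curves = []
    for row in arr:
        try:
            curves.append(_acf_biased(row, max_lag))
        except DegenerateSignalError:
            continue
    if not curves:
        raise DegenerateSignalError("all signals have zero variance")
    return AutocorrelationCurve(lags, np.mean(curves, axis=0), mode, len(curves))


@dataclass(frozen=True)
class OscillationFit:
    """Least-squares fit of ``A0 * exp(-gamma t) * cos(omega t + phi) + c``."""

    amplitude: float
    gamma: float  # decay rate; negative means growth (never clamped)
    omega: float  # angular frequency, >= 0
    phase: float
    offset: float
    residual_norm: float
    converged: bool

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return (self.amplitude * np.exp(-self.gamma * t)
                * np.cos(self.omega * t + self.phase) + self.offset)


def _initial_guess(series, t):
    dt = t[1] - t[0]
    y = series - series.mean()
    spec = np.abs(np.fft.rfft(y))
    freqs = 2.0 * np.pi * np.fft.rfftfreq(len(y), dt)
    k = 1 + int(np.argmax(spec[1:])) if len(spec) > 1 else 0
    omega0 = freqs[k] if freqs[k] > 0 else np.pi / (t[-1] - t[0])
    # crude envelope: log of |y| block maxima over ~one period
    block = max(4, int(round(2 * np.pi / omega0 / dt)) or 4)
    n_blocks = max(2, len(y) // block)
    tops, mids = [], []
    for b in range(n_blocks):
        seg = np.abs(y[b * block:(b + 1) * block])
        if seg.size and seg.max() > 0:
            tops.append(seg.max())
            mids.append(t[b * block + int(np.argmax(seg))])
    gamma0 = 0.0
    if len(tops) >= 2:
        slope = np.polyfit(mids, np.log(tops), 1)[0]
        gamma0 = -slope
    return np.max(np.abs(y)), gamma0, omega0


def fit_damped_oscillation(series, t_grid) -> OscillationFit:
    """Fit a damped cosine to a uniformly sampled series.

    Initial frequency comes from the dominant nonzero FFT peak and the
    initial decay rate from the log-envelope slope.  Non-convergence is
    reported through the ``converged`` flag, never raised.
    """
    y = np.asarray(series, float)
    t = np.asarray(t_grid, float)
    if y.size < 8:
        raise ValueError("series must have at least 8 samples")
    if not np.isfinite(y).all():
        raise ValueError("series contains non-finite values")
    a0, g0, w0 = _initial_guess(y, t)
    c0 = y.mean()

    def model(p):
        a, g, w, phi, c = p
        return a * np.exp(-g * t) * np.cos(w * t + phi) + c

    def resid(p):
        return model(p) - y

    best = None
    for phi0 in (0.0, np.pi / 2, np.pi, -np.pi / 2):
        try:
            sol = scipy.optimize.least_squares(
                resid, [a0, g0, w0, phi0, c0], method="lm", max_nfev=4000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return OscillationFit(a0, g0, w0, 0.0, c0, float(np.linalg.norm(resid([a0, g0, w0, 0.0, c0]))), False)
    a, g, w, phi, c = best.x
    if a < 0:  # canonical sign: positive amplitude, shift phase
        a, phi = -a, phi + np.pi
    if w < 0:
        w, phi = -w, -phi
    phi = np.angle(np.exp(1j * phi))
    return OscillationFit(float(a), float(g), float(w), float(phi), float(c),
                          float(np.linalg.norm(best.fun)), bool(best.success))


def _window_amplitude(y: np.ndarray) -> float:
    return 0.5 * (y.max() - y.min())


@dataclass(frozen=True)
class CoherenceReport:
    """Ensemble-level vs trajectory-level oscillation statistics."""

    mean_fit: OscillationFit
    acf_trajectories: AutocorrelationCurve
    acf_ensemble: AutocorrelationCurve
    amplitude_ratios: np.ndarray  # per-trajectory late/early window amplitude

    @property
    def omega(self) -> float:
        return self.mean_fit.omega

    @property
    def gamma(self) -> float:
        return self.mean_fit.gamma

    @property
    def amplitude_ratio(self) -> float:
        return float(np.median(self.amplitude_ratios))


def coherence_report(ens, t_grid=None, species: int = 0,
                     max_lag: int | None = None,
                     window: float = 0.25) -> CoherenceReport:
    """Bundle the coherence diagnostics for an ensemble of trajectories.

    ``ens`` is a :class:`~coherosc.ssa.TrajectoryEnsemble` or an
    (n_traj, T) array with an explicit ``t_grid``.  The per-trajectory
    amplitude ratio compares the peak-to-peak amplitude in the last
    ``window`` fraction of the horizon against the first: phase diffusion
    leaves it near 1 while absorption drives it to 0.  For per-trajectory
    ACFs only the pre-constant (pre-absorption) segment of each trajectory
    is used, since a constant tail has no autocorrelation signal.
    """
    if isinstance(ens, TrajectoryEnsemble):
        signals = ens.counts[:, :, species].astype(float)
        t = ens.time_grid
    else:
        signals = np.asarray(ens, float)
        if t_grid is None:
            raise ValueError("t_grid required for raw-array input")
        t = np.asarray(t_grid, float)
    if signals.shape[0] < 10:
        raise ValueError("coherence report requires >= 10 trajectories")
    n_t = signals.shape[1]
    if max_lag is None:
        max_lag = n_t // 2
    dt = t[1] - t[0]
    mean_fit = fit_damped_oscillation(signals.mean(axis=0), t)
    # per-trajectory ACF on the segment before the signal goes constant
    segments = []
    for row in signals:
        changes = np.flatnonzero(np.diff(row) != 0)
        end = changes[-1] + 2 if changes.size else 0
        if end > 2 * max(8, max_lag // 4):
            segments.append(row[:end])
    if segments:
        min_len = min(len(s) for s in segments)
        lag = min(max_lag, min_len - 1)
        acf_traj = autocorrelation(
            np.array([s[:min_len] for s in segments]), lag,
            mode="per-trajectory", dt=dt)
    else:
        acf_traj = autocorrelation(signals, max_lag, "per-trajectory", dt=dt)
    acf_ens = autocorrelation(signals, max_lag, "ensemble", dt=dt)
    w = max(2, int(round(window * n_t)))
    ratios = np.array([
        _window_amplitude(row[-w:]) / max(_window_amplitude(row[:w]), 1e-12)
        for row in signals
    ])
    return CoherenceReport(mean_fit, acf_traj, acf_ens, ratios)
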