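"""Excited-state decay kinetics and oscillation fits.

The S1 population curve (fraction of trajectories still on the excited
state) is fitted with a lag + double-term model

    f(t) = a1 * exp(-((t - t1) / t2)^2) + y0
         + (1 - a1 - y0) * exp(-(t - t1) / t2)

where t1 is a lag time and t2 a decay constant shared by the Gaussian and
exponential terms; for t < t1 the exponential factor is clamped to 1 so the
curve cannot grow before the lag.  The characteristic fitted lifetime is
reported as t1 + t2, and the mean hop time is reported independently as the
average decay time.  An optional third time constant t3 decouples the
exponential term for sensitivity checks.

Oscillatory (promoter-mode) series are fitted with A*sin(2*pi*t/T + phi) + c,
the period seeded from the dominant discrete-spectrum frequency; an average
twist series can be decomposed into a monotonic drift (robust linear fit,
Theil-Sen) plus an oscillatory residual of the wag period.  Spectral peaks of
velocity series are converted to vibrational wavenumbers in 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .errors import EmptyPopulationError, FitFailureError

#: speed of light in cm/fs
C_CM_PER_FS = 2.99792458e-5


@dataclass
class PopulationCurve:
    times: np.ndarray
    s1_fraction: np.ndarray


@dataclass
class LifetimeFit:
    a1: float
    t1: float
    t2: float
    y0: float
    t3: float | None
    fitted: np.ndarray
    rms_residual: float
    lifetime: float          # t1 + t2, the characteristic fitted lifetime
    mean_decay_time: float   # average hop time, reported independently


@dataclass
class SinusoidFit:
    amplitude: float
    period: float
    phase: float
    offset: float
    rms_residual: float
    flat: bool = False

    def value_at(self, t):
        return self.amplitude * np.sin(2 * np.pi * np.asarray(t) / self.period + self.phase) + self.offset

    def phase_at(self, t) -> float:
        return float((2 * np.pi * t / self.period + self.phase) % (2 * np.pi))


@dataclass
class AlphaDecomposition:
    intercept: float
    slope: float
    oscillation: SinusoidFit
    rms_residual: float
    poor: bool = False
    meta: dict = field(default_factory=dict)

    def reconstruct(self, t):
        t = np.asarray(t)
        return self.intercept + self.slope * t + self.oscillation.value_at(t)

    def sync_phase_at(self, t) -> float:
        return self.oscillation.phase_at(t)


def s1_population(ensemble) -> PopulationCurve:
    """Fraction of trajectories on the excited state (S1 or S2) per time bin.

    Trajectories without any decay count as excited throughout; after a
    trajectory's last frame its final state persists.
    """
    n_max = max(t.n_frames for t in ensemble)
    ref = max(ensemble, key=lambda t: t.n_frames)
    excited = np.zeros(n_max)
    for traj in ensemble:
        on = (traj.states >= 1).astype(float)
        if traj.n_frames < n_max:
            on = np.concatenate([on, np.full(n_max - traj.n_frames, on[-1])])
        excited += on
    return PopulationCurve(times=ref.times[:n_max], s1_fraction=excited / len(ensemble))


def lifetime_model(t, a1, t1, t2, y0, t3=None):
    """Lag + Gaussian + exponential population model (exponential clamped before the lag)."""
    t = np.asarray(t, dtype=float)
    tau_exp = t2 if t3 is None else t3
    gauss = np.exp(-(((t - t1) / t2) ** 2))
    # exponent clamped at 0 so the factor is exactly 1 before the lag
    expo = np.exp(np.minimum(0.0, -(t - t1) / tau_exp))
    return a1 * gauss + y0 + (1.0 - a1 - y0) * expo


def fit_lifetime(
    curve: PopulationCurve,
    mean_decay_time: float = float("nan"),
    free_t3: bool = False,
) -> LifetimeFit:
    """Nonlinear least-squares fit of the population model with multi-start.

    t1 is initialized from the decay onset (first drop below 0.99) and t2
    from the 1/e crossing; several (a1, y0) starts guard against local
    minima.  Raises :class:`FitFailureError` when no start converges or the
    curve never decays (t2 diverges).
    """
    t, y = curve.times, curve.s1_fraction
    if len(t) < 10:
        raise FitFailureError("need at least 10 points to fit the population model")
    if y.min() > 0.95:
        raise FitFailureError("population never decays; t2 unbounded")
    onset = t[np.argmax(y < 0.99)] if np.any(y < 0.99) else t[len(t) // 4]
    below = np.flatnonzero(y < 1 / np.e)
    t2_guess = max((t[below[0]] - onset) if below.size else (t[-1] - onset) / 2, 1.0)

    span = t[-1] - t[0]

    def residual(p):
        if free_t3:
            a1, t1, t2, y0, t3 = p
            return lifetime_model(t, a1, t1, t2, y0, t3) - y
        a1, t1, t2, y0 = p
        return lifetime_model(t, a1, t1, t2, y0) - y

    best = None
    lo = [0.0, 0.0, 1e-6, 0.0] + ([1e-6] if free_t3 else [])
    hi = [1.0, t[-1], 10 * span, 1.0] + ([10 * span] if free_t3 else [])
    for a1_0 in (0.1, 0.3, 0.6):
        for y0_0 in (0.0, 0.05):
            for t2_scale in (0.5, 1.0, 2.0):
                p0 = [a1_0, max(onset, 1e-3), t2_guess * t2_scale, y0_0]
                if free_t3:
                    p0.append(t2_guess * t2_scale)
                try:
                    res = optimize.least_squares(residual, p0, bounds=(lo, hi))
                except ValueError:
                    continue
                if res.success and (best is None or res.cost < best.cost):
                    best = res
    if best is None:
        raise FitFailureError("lifetime fit did not converge from any start")
    p = best.x
    a1, t1, t2, y0 = p[:4]
    t3 = float(p[4]) if free_t3 else None
    fitted = lifetime_model(t, *p[:4], t3)
    return LifetimeFit(
        a1=float(a1), t1=float(t1), t2=float(t2), y0=float(y0), t3=t3,
        fitted=fitted,
        rms_residual=float(np.sqrt(np.mean((fitted - y) ** 2))),
        lifetime=float(t1 + t2),
        mean_decay_time=float(mean_decay_time),
    )


def _spectrum_peak_period(times, values) -> float | None:
    """Period of the dominant non-DC discrete-spectrum component, or None."""
    values = values - np.mean(values)
    n = len(values)
    if n < 4 or np.allclose(values, 0):
        return None
    dt = float(np.median(np.diff(times)))
    mag = np.abs(np.fft.rfft(values))
    freqs = np.fft.rfftfreq(n, d=dt)
    k = int(np.argmax(mag[1:])) + 1
    if freqs[k] == 0:
        return None
    return 1.0 / freqs[k]


def fit_sinusoid(times, values, period_hint: float | None = None) -> SinusoidFit:
    """Least-squares fit of A*sin(2*pi*t/T + phi) + c.

    The period is seeded from ``period_hint`` or the dominant spectral
    component; amplitude is normalized to be non-negative.  A flat series
    returns amplitude 0 with the ``flat`` flag set (period meaningless).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & np.isfinite(times)
    times, values = times[ok], values[ok]
    if len(values) < 4:
        raise EmptyPopulationError("too few samples for a sinusoid fit")
    if np.ptp(values) < 1e-12:
        return SinusoidFit(0.0, float("nan"), 0.0, float(values.mean()), 0.0, flat=True)
    T0 = period_hint or _spectrum_peak_period(times, values)
    if T0 is None:
        T0 = (times[-1] - times[0]) / 2

    def residual(p):
        A, T, phi, c = p
        return A * np.sin(2 * np.pi * times / T + phi) + c - values

    A0 = float(np.std(values) * np.sqrt(2))
    best = None
    for T_scale in (0.5, 1.0, 2.0):
        for phi0 in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            res = optimize.least_squares(
                residual,
                [A0, T0 * T_scale, phi0, float(values.mean())],
                bounds=([0.0, 1e-6, -2 * np.pi, -np.inf], [np.inf, np.inf, 4 * np.pi, np.inf]),
            )
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise FitFailureError("sinusoid fit did not converge")
    A, T, phi, c = best.x
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return SinusoidFit(float(A), float(T), float(phi % (2 * np.pi)), float(c), rms)


def decompose_alpha(
    times, avg_alpha, promoter_period_hint: float, rms_threshold: float = 5.0
) -> AlphaDecomposition:
    """Split an averaged twist series into linear drift + oscillation.

    The drift is a Theil-Sen robust line; the residual is fitted with a
    sinusoid seeded at the promoter period hint (e.g. the wag period); a
    final joint least-squares pass refines line and sinusoid together (the
    two-stage estimate leaves a bias when the oscillation does not average
    out over the window).  A residual rms above ``rms_threshold`` (degrees)
    keeps the result but sets the ``poor`` flag.
    """
    times = np.asarray(times, dtype=float)
    avg_alpha = np.asarray(avg_alpha, dtype=float)
    ok = np.isfinite(avg_alpha)
    times, avg_alpha = times[ok], avg_alpha[ok]
    slope, intercept, *_ = stats.theilslopes(avg_alpha, times)
    residual = avg_alpha - (intercept + slope * times)
    osc = fit_sinusoid(times, residual, period_hint=promoter_period_hint)

    if not osc.flat:
        def joint_residual(p):
            b0, b1, A, T, phi = p
            return b0 + b1 * times + A * np.sin(2 * np.pi * times / T + phi) - avg_alpha

        res = optimize.least_squares(
            joint_residual,
            [intercept, slope, osc.amplitude, osc.period, osc.phase],
            bounds=(
                [-np.inf, -np.inf, 0.0, 1e-6, -2 * np.pi],
                [np.inf, np.inf, np.inf, np.inf, 4 * np.pi],
            ),
        )
        if res.success:
            intercept, slope, A, T, phi = res.x
            osc = SinusoidFit(
                float(A), float(T), float(phi % (2 * np.pi)), 0.0,
                float(np.sqrt(np.mean(res.fun ** 2))),
            )
    recon = intercept + slope * times + osc.value_at(times)
    rms = float(np.sqrt(np.mean((recon - avg_alpha) ** 2)))
    return AlphaDecomposition(
        intercept=float(intercept),
        slope=float(slope),
        oscillation=osc,
        rms_residual=rms,
        poor=rms > rms_threshold,
    )


def dominant_frequency(series, dt: float, n_peaks: int = 2) -> list[dict]:
    """Vibrational wavenumbers (1/cm) of the strongest spectral peaks.

    The mean-removed series is Fourier transformed; up to ``n_peaks`` local
    maxima of the magnitude spectrum are converted via nu = 1/(T * c).  Peaks
    weaker than 4x the median spectral magnitude are flagged unstable (white
    noise yields no stable peak).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 32:
        raise EmptyPopulationError("need at least 32 samples for a spectral estimate")
    values = series - series.mean()
    mag = np.abs(np.fft.rfft(values))
    freqs = np.fft.rfftfreq(len(values), d=dt)  # cycles / fs
    peaks, _ = signal.find_peaks(mag)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(mag[1:])) + 1])
    order = peaks[np.argsort(mag[peaks])[::-1]][:n_peaks]
    floor = np.median(mag[1:])
    out = []
    for k in sorted(order, key=lambda k: freqs[k]):
        if freqs[k] == 0:
            continue
        out.append(
            {
                "wavenumber_cm1": float(freqs[k] / C_CM_PER_FS),
                "period_fs": float(1.0 / freqs[k]),
                "magnitude": float(mag[k]),
                "stable": bool(mag[k] > 4 * floor),
            }
        )
    return out
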