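"""Stokes-shift dynamics of the energy-gap coordinate.

From a gap series X(t) this module computes the time correlation function
C_X(t) = <dX(t) dX(0)>, its loss spectrum chi''(omega) = omega*C_X(omega) /
(2 k_B T) (one-sided cosine transform), a multi-Debye decomposition of
C_X(t), and a fourth-order Gaussianity diagnostic.  The loss spectrum is
normalized so that (2/pi) * integral of chi''/omega over omega equals
2*lambda, i.e. each spectral band carries its share of the reorganization
energy; peaks sit at omega = 1/tau_k for Debye modes.

Frequencies are reported as nu (1/ps) with omega = 2*pi*nu.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import kt
from .gap_analysis import GapSeries

__all__ = [
    "TimeCorrelation",
    "LossSpectrum",
    "DebyeFit",
    "autocorrelation",
    "truncation_lag",
    "loss_spectrum",
    "sum_rule_lambda",
    "debye_fit",
    "gaussian_excess",
]


@dataclass(frozen=True)
class TimeCorrelation:
    """Autocovariance C_X(t) on a uniform lag grid; ``c[0]`` is the
    population variance.  ``n_pairs[k] = N - k`` origin pairs enter lag k
    (the estimator still divides by N; see :func:`autocorrelation`)."""

    lags: np.ndarray  # ps
    c: np.ndarray  # eV^2
    n_pairs: np.ndarray
    n_frames: int

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0


@dataclass(frozen=True)
class LossSpectrum:
    """chi''(nu) with omega = 2*pi*nu; ``c_omega`` is the cosine transform
    C_X(omega) (eV^2 ps) kept for the sum rule."""

    nu: np.ndarray  # 1/ps
    chi: np.ndarray  # eV
    c_omega: np.ndarray  # eV^2 * ps
    temperature: float


@dataclass(frozen=True)
class DebyeFit:
    """Multi-exponential fit C_X(t) = sum_k a_k exp(-t/tau_k): per-mode
    reorganization weights lambda_k = a_k/(2 k_B T) and times tau_k."""

    amplitudes: np.ndarray  # eV^2
    taus: np.ndarray  # ps
    lambdas: np.ndarray  # eV
    residual: float

    @property
    def n_modes(self) -> int:
        return self.taus.size


def autocorrelation(gaps: GapSeries, max_lag: int) -> TimeCorrelation:
    """Mean-subtracted autocovariance, biased (1/N) estimator via FFT.

    The 1/N normalization guarantees a non-negative spectral density
    (Bochner), at the price of damping long lags; ``c[0]`` equals the
    population variance exactly.
    """
    x = np.asarray(gaps.x, float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 frames")
    if not 0 < max_lag < n / 2:
        raise ValueError(f"max_lag must be in (0, n/2) = (0, {n / 2}), got {max_lag}")
    dx = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(dx, nfft)) ** 2
    c = np.fft.irfft(spec, nfft)[: max_lag + 1] / n
    dt = float(gaps.times[1] - gaps.times[0]) if gaps.times.size > 1 else 1.0
    lags = np.arange(max_lag + 1) * dt
    return TimeCorrelation(lags=lags, c=c, n_pairs=n - np.arange(max_lag + 1), n_frames=n)


def truncation_lag(corr: TimeCorrelation) -> int:
    """First lag where |C| drops below twice its Bartlett standard error.

    Beyond this point the estimate is statistically indistinguishable from
    zero; integrating further mostly accumulates noise.
    """
    c0 = corr.c[0]
    if c0 <= 0:
        return 1
    rho = corr.c / c0
    cum = 1.0 + 2.0 * np.cumsum(rho[1:] ** 2)
    se = np.sqrt(np.concatenate(([1.0], cum)) / corr.n_frames)
    below = np.flatnonzero(np.abs(rho[1:]) < 2.0 * se[:-1]) + 1
    return int(below[0]) if below.size else corr.lags.size - 1


def _fit_tail(corr: TimeCorrelation, k_trunc: int) -> tuple[float, float] | None:
    """Single-exponential fit C ~ A exp(-t/tau) over the closing half of the
    resolved window; returns (C at truncation, tau) or None if unusable."""
    lo = max(k_trunc // 2, 1)
    t = corr.lags[lo : k_trunc + 1]
    c = corr.c[lo : k_trunc + 1]
    if t.size < 4 or np.any(c <= 0):
        return None
    slope, intercept = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        return None
    tau = -1.0 / slope
    c_end = float(np.exp(intercept + slope * corr.lags[k_trunc]))
    return c_end, tau


def _cosine_transform(t: np.ndarray, c: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """integral_0^T c(t) cos(omega t) dt, exact for the piecewise-linear
    interpolant of c (Filon-type).

    Plain trapezoid degrades as omega*dt grows because the integrand
    oscillates within a step; integrating the linear interpolant
    analytically keeps the relative error ~(dt/tau)^2 at all frequencies.
    The telescoped closed form is
    F(w) = c_N sin(w T)/w + (1/(w^2 h)) sum_i dc_i * dcos_i.
    """
    out = np.empty(omega.size)
    zero = omega == 0.0
    if zero.any():
        out[zero] = np.trapezoid(c, t)
    nz = ~zero
    if nz.any():
        w = omega[nz][:, None]
        h = t[1] - t[0]
        dc = np.diff(c)[None, :]
        dcos = np.diff(np.cos(w * t[None, :]), axis=1)
        out[nz] = (c[-1] * np.sin(w[:, 0] * t[-1]) / w[:, 0]
                   + (dc * dcos).sum(axis=1) / (w[:, 0] ** 2 * h))
    return out


def loss_spectrum(
    corr: TimeCorrelation,
    temperature: float = 300.0,
    nu: np.ndarray | None = None,
    tail: str = "fit",
) -> LossSpectrum:
    """One-sided cosine transform of C_X(t) and the loss function
    chi''(omega) = omega * C_X(omega) / (2 k_B T).

    The transform integrates the measured C_X(t) (trapezoid) up to the
    statistical truncation lag.  ``tail='fit'`` (default) extends it with an
    analytic single-exponential tail fitted to the closing half of the
    resolved window — without it the sharp cut both loses slow-mode mass
    and rings; ``tail='truncate'`` cuts sharply; ``tail='none'`` uses every
    stored lag.
    """
    if corr.lags.size > 1:
        steps = np.diff(corr.lags)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("non-uniform lag grid")
    dt = corr.dt
    if tail not in ("fit", "truncate", "none"):
        raise ValueError(f"unknown tail treatment {tail!r}")
    k = corr.lags.size - 1 if tail == "none" else min(truncation_lag(corr), corr.lags.size - 1)
    t = corr.lags[: k + 1]
    c = corr.c[: k + 1]
    tail_params = _fit_tail(corr, k) if tail == "fit" else None

    if nu is None:
        t_span = max(t[-1], dt)
        if tail_params is not None:
            t_span = max(t_span, 5.0 * tail_params[1])
        nu = np.concatenate(
            ([0.0], np.geomspace(1.0 / (20.0 * np.pi * t_span), 1.0 / (2.0 * dt), 400))
        )
    nu = np.asarray(nu, float)
    omega = 2.0 * np.pi * nu

    c_omega = 2.0 * _cosine_transform(t, c, omega)
    if tail_params is not None:
        c_end, tau_f = tail_params
        t_end = t[-1]
        wt = omega * tau_f
        # 2 * integral_{T}^{inf} c_end e^{-(t-T)/tau} cos(wt) dt
        c_omega += (
            2.0 * c_end * tau_f
            * (np.cos(omega * t_end) - wt * np.sin(omega * t_end))
            / (1.0 + wt**2)
        )
    chi = omega * c_omega / (2.0 * kt(temperature))
    return LossSpectrum(nu=nu, chi=chi, c_omega=c_omega, temperature=temperature)


def sum_rule_lambda(spec: LossSpectrum) -> float:
    """Reorganization energy from the spectral sum rule,
    lambda = (1/pi) * integral of chi''(omega)/omega d(omega), eV.

    The integrand chi''/omega = C_X(omega)/(2kT) is finite at omega = 0; a
    1/omega^2 high-frequency tail estimate closes the integral beyond the
    stored grid.
    """
    omega = 2.0 * np.pi * spec.nu
    integrand = spec.c_omega / (2.0 * kt(spec.temperature))
    lam = np.trapezoid(integrand, omega) / np.pi
    if omega.size > 1 and integrand[-1] > 0:
        lam += integrand[-1] * omega[-1] / np.pi  # Debye-like 1/omega^2 closure
    return float(lam)


def _multi_exp(t, *params):
    half = len(params) // 2
    a = np.asarray(params[:half])
    tau = np.asarray(params[half:])
    return np.exp(-t[:, None] / tau[None, :]) @ a


def debye_fit(corr: TimeCorrelation, n_modes: int, temperature: float = 300.0) -> DebyeFit:
    """Non-negative multi-exponential (Debye) decomposition of C_X(t).

    Nonlinear least squares with multi-start over log-spaced relaxation-time
    initializations (deterministic), amplitudes bounded below by zero.  Fits
    over the statistically resolved window (see :func:`truncation_lag`).
    """
    if not 1 <= n_modes <= 5:
        raise ValueError(f"n_modes must be in [1, 5], got {n_modes}")
    k = max(truncation_lag(corr), 4 * n_modes)
    k = min(k, corr.lags.size - 1)
    t = corr.lags[: k + 1]
    c = corr.c[: k + 1]
    c0 = c[0]
    if c0 <= 0:
        raise ValueError("zero-variance series cannot be fitted")

    t_lo = max(corr.dt, t[-1] * 1e-4)
    candidates = np.geomspace(t_lo, max(t[-1], 2 * t_lo), 6)
    starts = list(itertools.combinations(range(6), n_modes))
    best = None
    for comb in starts:
        tau0 = candidates[list(comb)]
        a0 = np.full(n_modes, c0 / n_modes)
        p0 = np.concatenate([a0, tau0])
        lb = np.concatenate([np.zeros(n_modes), np.full(n_modes, t_lo * 1e-3)])
        ub = np.concatenate([np.full(n_modes, 10 * c0), np.full(n_modes, 1e6 * t[-1])])
        try:
            popt, _ = curve_fit(
                _multi_exp, t, c, p0=p0, bounds=(lb, ub), maxfev=20000
            )
        except RuntimeError:
            continue
        resid = float(np.sqrt(np.mean((_multi_exp(t, *popt) - c) ** 2)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError(
            f"Debye fit failed to converge from {len(starts)} starts "
            f"(n_modes={n_modes}, window={t[-1]:.3g} ps)"
        )
    popt, resid = best
    a = popt[:n_modes]
    tau = popt[n_modes:]
    order = np.argsort(tau)
    a, tau = a[order], tau[order]
    return DebyeFit(
        amplitudes=a,
        taus=tau,
        lambdas=a / (2.0 * kt(temperature)),
        residual=resid,
    )


def gaussian_excess(
    gaps: GapSeries, corr: TimeCorrelation
) -> tuple[np.ndarray, bool]:
    """Fourth-order Gaussianity diagnostic of the gap fluctuations.

    Gamma(t) = [<dX^2(t) dX^2(0)> - <dX^2>^2 - 2 C_X(t)^2] / <dX^2>^2
    vanishes for a Gaussian process (Wick factorization), so the full
    fourth-order dynamics are determined by the Stokes-shift correlation
    alone.  Returns (Gamma on the correlation's lag grid, reliable flag);
    the flag is False for short (< 10^4 frames) or degenerate series.
    """
    x = np.asarray(gaps.x, float)
    n = x.size
    max_lag = corr.lags.size - 1
    dx = x - x.mean()
    var = dx @ dx / n
    if var == 0:
        warnings.warn("constant series: Gaussian excess undefined", stacklevel=2)
        return np.full(max_lag + 1, np.nan), False
    y = dx * dx
    y -= y.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(y, nfft)) ** 2
    c4 = np.fft.irfft(spec, nfft)[: max_lag + 1] / n
    gamma = (c4 - 2.0 * corr.c[: max_lag + 1] ** 2) / var**2
    reliable = n >= 10_000
    if not reliable:
        warnings.warn(
            f"only {n} frames; fourth-order statistics are unreliable", stacklevel=2
        )
    return gamma, reliable
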