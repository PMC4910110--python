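"""Time correlation, loss spectra, Debye fits, Gaussianity diagnostic."""

import numpy as np
import pytest

import polarsite as ps
from polarsite.constants import kt
from polarsite.dynamics import TimeCorrelation
from conftest import make_gaps


def _ou_gaps(sigma2, tau, dt, n, seed):
    x = ps.generate_ou(ps.OUModeSpec(np.sqrt(sigma2), tau), dt, n, seed)
    return make_gaps(x, dt=dt)


def _exact_ou_corr(sigma2, tau, dt, n_lags, n_frames=10**9):
    lags = np.arange(n_lags + 1) * dt
    return TimeCorrelation(
        lags=lags,
        c=sigma2 * np.exp(-lags / tau),
        n_pairs=n_frames - np.arange(n_lags + 1),
        n_frames=n_frames,
    )


def test_autocorrelation_zero_lag_is_population_variance():
    g = _ou_gaps(0.04, 5.0, 0.1, 100_000, 1)
    corr = ps.autocorrelation(g, 500)
    assert corr.c[0] == pytest.approx(g.x.var(), rel=1e-12)


def test_autocorrelation_white_noise():
    rng = np.random.default_rng(3)
    g = make_gaps(rng.normal(0, 1, 200_000))
    corr = ps.autocorrelation(g, 50)
    assert corr.c[0] == pytest.approx(1.0, abs=0.02)
    assert np.all(np.abs(corr.c[1:]) < 3 / np.sqrt(g.n_frames) * 3)


def test_autocorrelation_matches_ou_closed_form():
    sigma2, tau, dt = 0.05, 5.0, 0.1
    g = _ou_gaps(sigma2, tau, dt, 1_000_000, 7)
    corr = ps.autocorrelation(g, 300)
    expected = sigma2 * np.exp(-corr.lags / tau)
    se = 3 * sigma2 * np.sqrt(2 * tau / dt / g.n_frames)
    assert np.all(np.abs(corr.c - expected) < 3 * se + 0.02 * sigma2)


def test_autocorrelation_constant_series_is_zero():
    corr = ps.autocorrelation(make_gaps(np.ones(100)), 10)
    assert np.allclose(corr.c, 0.0)


def test_autocorrelation_max_lag_guard():
    with pytest.raises(ValueError):
        ps.autocorrelation(make_gaps(np.zeros(100)), 60)


def test_loss_spectrum_matches_analytic_debye_over_three_decades():
    """On the exact OU correlation function the transform reproduces the
    Debye loss 2*lambda*omega*tau/(1+(omega*tau)^2) to well under 2% across
    three decades around the peak."""
    sigma2, tau, dt = 2 * kt(300.0) * 1.0, 10.0, 0.2
    corr = _exact_ou_corr(sigma2, tau, dt, 20_000)
    nu = np.concatenate(([0.0], np.geomspace(2e-4, 0.2, 200)))
    spec = ps.loss_spectrum(corr, 300.0, nu=nu, tail="none")
    lam = sigma2 / (2 * kt(300.0))
    om = 2 * np.pi * spec.nu[1:]
    chi_an = 2 * lam * om * tau / (1 + (om * tau) ** 2)
    assert np.max(np.abs(spec.chi[1:] / chi_an - 1)) < 0.02
    assert spec.chi[0] == 0.0


def test_loss_spectrum_peak_and_sum_rule_on_sampled_ou():
    sigma2, tau = 2 * kt(300.0) * 1.0, 10.0
    g = _ou_gaps(sigma2, tau, 0.2, 1_000_000, 11)
    corr = ps.autocorrelation(g, 20_000)
    spec = ps.loss_spectrum(corr, 300.0)
    nu_peak = spec.nu[np.argmax(spec.chi)]
    assert nu_peak == pytest.approx(1 / (2 * np.pi * tau), rel=0.1)
    lam_var = corr.c[0] / (2 * kt(300.0))
    assert ps.sum_rule_lambda(spec) == pytest.approx(lam_var, rel=0.02)


def test_loss_spectrum_linearity_two_modes():
    """Spectrum of a sum of independent components is the sum of spectra."""
    kT = kt(300.0)
    dt, n = 0.2, 1_000_000
    a = ps.generate_ou(ps.OUModeSpec(np.sqrt(1.2 * kT), 0.5), dt, n, 21)
    b = ps.generate_ou(ps.OUModeSpec(np.sqrt(0.8 * kT), 50.0), dt, n, 22)
    nu = np.concatenate(([0.0], np.geomspace(1e-4, 2.0, 150)))
    specs = []
    for x in (a, b, a + b):
        corr = ps.autocorrelation(make_gaps(x, dt=dt), 10_000)
        specs.append(ps.loss_spectrum(corr, 300.0, nu=nu))
    total = specs[0].chi + specs[1].chi
    scale = np.max(total)
    assert np.max(np.abs(specs[2].chi - total)) < 0.1 * scale


def test_loss_spectrum_zero_variance():
    corr = ps.autocorrelation(make_gaps(np.ones(1000)), 100)
    spec = ps.loss_spectrum(corr, 300.0)
    assert np.allclose(spec.chi, 0.0)


def test_loss_spectrum_nonuniform_lags_rejected():
    corr = TimeCorrelation(lags=np.array([0.0, 0.1, 0.3]),
                           c=np.array([1.0, 0.5, 0.2]),
                           n_pairs=np.array([10, 9, 8]), n_frames=10)
    with pytest.raises(ValueError, match="non-uniform"):
        ps.loss_spectrum(corr, 300.0)


def test_protein_water_compensation_suppresses_slow_loss_peak():
    """Strongly anticorrelated slow protein/water modes: the slow-band loss
    of the total gap is far below either component's."""
    spec = ps.BathSpec(
        dt=0.2, n_frames=400_000, seed=5,
        protein_modes=(ps.OUModeSpec(0.25, 20.0), ps.OUModeSpec(0.08, 0.4)),
        water_modes=(ps.OUModeSpec(0.25, 20.0), ps.OUModeSpec(0.08, 0.4)),
        rho_pw=-0.95,
    )
    traj = ps.generate_bath(spec, "Ox")
    x_p, x_w = ps.split_components(traj, dq_total=-1.0)
    nu = np.concatenate(([0.0], np.geomspace(1e-4, 1.0, 200)))
    slow_band = (nu > 1 / (2 * np.pi * 60)) & (nu < 1 / (2 * np.pi * 7))
    peaks = {}
    for name, x in (("p", x_p), ("w", x_w), ("tot", x_p + x_w)):
        corr = ps.autocorrelation(make_gaps(x, dt=0.2), 8_000)
        s = ps.loss_spectrum(corr, 300.0, nu=nu)
        peaks[name] = s.chi[slow_band].max()
    assert peaks["tot"] < 0.5 * min(peaks["p"], peaks["w"])


def test_debye_fit_single_mode_self_recovery():
    sigma2, tau = 2 * kt(300.0) * 1.0, 5.0
    g = _ou_gaps(sigma2, tau, 0.25, 1_000_000, 31)
    corr = ps.autocorrelation(g, 10_000)
    fit = ps.debye_fit(corr, 1, 300.0)
    assert fit.amplitudes[0] == pytest.approx(sigma2, rel=0.02)
    assert fit.taus[0] == pytest.approx(tau, rel=0.02)
    assert fit.lambdas[0] == pytest.approx(1.0, rel=0.02)


def test_debye_fit_two_separated_modes():
    kT = kt(300.0)
    # the slow 500 ps mode needs T >> tau for percent-level recovery
    dt, n = 0.25, 10_000_000
    a = ps.generate_ou(ps.OUModeSpec(np.sqrt(1.0 * kT), 0.5), dt, n, 41)
    b = ps.generate_ou(ps.OUModeSpec(np.sqrt(1.0 * kT), 500.0), dt, n, 42)
    corr = ps.autocorrelation(make_gaps(a + b, dt=dt), 20_000)
    fit = ps.debye_fit(corr, 2, 300.0)
    assert fit.taus[0] == pytest.approx(0.5, rel=0.05)
    assert fit.taus[1] == pytest.approx(500.0, rel=0.05)
    assert fit.amplitudes[0] == pytest.approx(kT, rel=0.05)
    assert fit.amplitudes[1] == pytest.approx(kT, rel=0.05)


def test_debye_fit_mode_count_guard():
    corr = _exact_ou_corr(1.0, 5.0, 0.1, 100)
    with pytest.raises(ValueError):
        ps.debye_fit(corr, 0)
    with pytest.raises(ValueError):
        ps.debye_fit(corr, 6)


def test_gaussian_excess_near_zero_for_ou():
    """Wick factorization: the normalized fourth-order excess of a Gaussian
    OU gap stays below 0.05 out to 10 tau."""
    tau, dt = 2.0, 0.2
    g = _ou_gaps(0.05, tau, dt, 1_000_000, 51)
    corr = ps.autocorrelation(g, int(10 * tau / dt))
    gamma, reliable = ps.gaussian_excess(g, corr)
    assert reliable
    assert np.max(np.abs(gamma)) < 0.05


def test_gaussian_excess_detects_chi_square_process():
    tau, dt = 2.0, 0.2
    z = ps.generate_ou(ps.OUModeSpec(1.0, tau), dt, 500_000, 52)
    g = make_gaps(z**2, dt=dt)
    corr = ps.autocorrelation(g, int(5 * tau / dt))
    gamma, _ = ps.gaussian_excess(g, corr)
    assert gamma[0] > 0.5


def test_gaussian_excess_flags_degenerate_and_short_series():
    g = make_gaps(np.ones(100))
    corr = ps.autocorrelation(g, 10)
    with pytest.warns(UserWarning):
        gamma, reliable = ps.gaussian_excess(g, corr)
    assert not reliable
    assert np.all(np.isnan(gamma))
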