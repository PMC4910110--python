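"""Statistical properties of the synthetic bath and manifold generators."""

import numpy as np
import pytest

import polarsite as ps
from polarsite.constants import kt


def test_zero_sigma_gives_constant_series():
    s = ps.generate_ou(ps.OUModeSpec(0.0, 5.0), 0.1, 100, 0, mean=1.5)
    assert np.all(s == 1.5)


def test_ou_moments_match_closed_form():
    """Exact AR(1) discretization: stationary variance and lag-tau
    autocorrelation e^{-1} at any dt."""
    mode = ps.OUModeSpec(1.0, 10.0)
    s = ps.generate_ou(mode, 0.1, 200_000, seed=42, mean=2.0)
    assert s.mean() == pytest.approx(2.0, abs=0.05)
    assert s.var() == pytest.approx(1.0, abs=0.03)
    lag = 100  # = tau/dt
    rho = np.corrcoef(s[:-lag], s[lag:])[0, 1]
    assert rho == pytest.approx(np.exp(-1.0), abs=0.02)


def test_ou_deterministic_under_seed():
    mode = ps.OUModeSpec(0.7, 3.0)
    a = ps.generate_ou(mode, 0.1, 1000, seed=7)
    b = ps.generate_ou(mode, 0.1, 1000, seed=7)
    assert np.array_equal(a, b)
    c = ps.generate_ou(mode, 0.1, 1000, seed=8)
    assert not np.array_equal(a, c)


def _simple_spec(rho, seed=0, n=200_000):
    return ps.BathSpec(
        dt=0.1,
        n_frames=n,
        seed=seed,
        protein_modes=(ps.OUModeSpec(0.2, 5.0), ps.OUModeSpec(0.1, 0.5)),
        water_modes=(ps.OUModeSpec(0.25, 5.0), ps.OUModeSpec(0.1, 0.3)),
        rho_pw=rho,
        field_modes=(ps.OUModeSpec(0.1, 1.0),),
    )


def test_perfect_anticorrelation_cancels_slow_variance():
    """rho_pw = -1 with equal slow sigma: slow parts of phi_p and phi_w sum
    to a constant, leaving only the fast-mode variance in phi_fe."""
    spec = ps.BathSpec(
        dt=0.1, n_frames=100_000, seed=3,
        protein_modes=(ps.OUModeSpec(0.3, 5.0), ps.OUModeSpec(0.05, 0.4)),
        water_modes=(ps.OUModeSpec(0.3, 5.0), ps.OUModeSpec(0.05, 0.4)),
        rho_pw=-1.0,
    )
    traj = ps.generate_bath(spec, "Ox")
    fast_var = 2 * 0.05**2
    assert traj.phi_fe.var() == pytest.approx(fast_var, rel=0.1)
    # components individually retain the slow variance
    assert traj.phi_p.var() == pytest.approx(0.3**2 + 0.05**2, rel=0.1)


def test_uncorrelated_components_add_variances():
    traj = ps.generate_bath(_simple_spec(0.0), "Ox")
    total = traj.phi_fe.var()
    assert total == pytest.approx(traj.phi_p.var() + traj.phi_w.var(), rel=0.05)


def test_ensembles_differ_only_by_means_when_label_shared():
    spec = ps.BathSpec(
        dt=0.1, n_frames=500, seed=1,
        protein_modes=(ps.OUModeSpec(0.2, 2.0),),
        water_modes=(ps.OUModeSpec(0.2, 2.0),),
        mean_ox=ps.EnsembleMeans(phi_p=0.0),
        mean_red=ps.EnsembleMeans(phi_p=1.0),
    )
    ox = ps.generate_bath(spec, "Ox", seed_label="shared")
    red = ps.generate_bath(spec, "Red", seed_label="shared")
    assert np.allclose(red.phi_p - ox.phi_p, 1.0)
    assert np.array_equal(red.phi_w, ox.phi_w)


def test_bath_reproducible_and_ensembles_independent():
    spec = _simple_spec(-0.5, n=2000)
    a = ps.generate_bath(spec, "Ox")
    b = ps.generate_bath(spec, "Ox")
    assert np.array_equal(a.phi_p, b.phi_p)
    red = ps.generate_bath(spec, "Red")
    assert not np.array_equal(a.phi_p - a.phi_p.mean(), red.phi_p - red.phi_p.mean())


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ps.OUModeSpec(-1.0, 1.0)
    with pytest.raises(ValueError):
        ps.OUModeSpec(1.0, 0.0)
    with pytest.raises(ValueError):
        _simple_spec(1.5)
    with pytest.raises(ValueError):
        ps.generate_ou(ps.OUModeSpec(1, 1), 0.1, 0, 0)


def test_linear_response_spec_hits_targets():
    """Requested (lambda_st, lambda) recovered by the energetics module
    within 5% from the generated classical gap."""
    spec = ps.linear_response_spec(1.0, 1.3, dt=0.2, n_frames=400_000, seed=21)
    ox = ps.generate_bath(spec, "Ox")
    red = ps.generate_bath(spec, "Red")
    g_ox, g_red = ps.gap_from_bath(ox), ps.gap_from_bath(red)
    assert ps.stokes_reorg(g_ox, g_red) == pytest.approx(1.0, rel=0.05)
    lam, _ = ps.variance_reorg(g_ox, spec.temperature)
    assert lam == pytest.approx(1.3, rel=0.05)


def test_linear_response_spec_rejects_degenerate_requests():
    with pytest.raises(ValueError):
        ps.linear_response_spec(1.0, 1.0, delta_q=0.0)
    with pytest.raises(ValueError):
        ps.linear_response_spec(1.0, 1.0, timescales=())
    with pytest.raises(ValueError):
        ps.linear_response_spec(-1.0, 1.0)


def test_generated_manifold_polarizability_matches_hand_sum():
    m = ps.generate_manifold(n_states=2, gap_scale=1.0, dipole_scale=0.5, seed=4)
    mu = m.dipoles[0, 1]
    expected = 2.0 * (mu[:, None] * mu[None, :]) / (m.energies[1] - m.energies[0])
    tensor, _ = ps.polarizability(m, 0, 1.0)
    assert np.allclose(tensor, expected * ps.ALPHA_TO_A3)


def test_manifold_alpha_calibration():
    m = ps.generate_manifold(n_states=30, target_alpha=54.0, seed=8)
    _, iso = ps.polarizability(m, 0, 1.0)
    assert iso == pytest.approx(54.0, rel=1e-6)


def test_manifold_deterministic_and_guards():
    a = ps.generate_manifold(n_states=10, seed=2)
    b = ps.generate_manifold(n_states=10, seed=2)
    assert np.array_equal(a.dipoles, b.dipoles)
    with pytest.raises(ValueError):
        ps.generate_manifold(n_states=1, target_alpha=10.0)


def test_single_mode_gap_spectrum_is_debye_peak():
    """Cross-module check: the loss spectrum of a one-mode OU gap peaks at
    omega = 1/tau, i.e. nu = 1/(2 pi tau)."""
    tau = 4.0
    sig2 = 2 * kt(300.0) * 0.8
    x = ps.generate_ou(ps.OUModeSpec(np.sqrt(sig2), tau), 0.1, 400_000, 13)
    gaps = ps.GapSeries("Ox", np.arange(x.size) * 0.1, x)
    corr = ps.autocorrelation(gaps, 10_000)
    spec = ps.loss_spectrum(corr, 300.0)
    nu_peak = spec.nu[np.argmax(spec.chi)]
    assert nu_peak == pytest.approx(1.0 / (2 * np.pi * tau), rel=0.1)
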