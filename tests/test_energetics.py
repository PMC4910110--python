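"""Reorganization energies, kappa_G, barriers, surfaces, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polarsite as ps
from polarsite.constants import kt
from conftest import make_gaps


def test_stokes_reorg_direct_formula():
    g_ox = make_gaps(np.zeros(100))
    g_red = make_gaps(np.full(100, 2.52), ensemble="Red")
    assert ps.stokes_reorg(g_ox, g_red) == pytest.approx(1.26)


def test_stokes_reorg_identical_distributions_zero():
    g = make_gaps(np.sin(np.arange(50)))
    assert ps.stokes_reorg(g, make_gaps(g.x, ensemble="Red")) == 0.0


def test_stokes_reorg_negative_warns_not_raises():
    g_ox = make_gaps(np.ones(10))
    g_red = make_gaps(np.zeros(10), ensemble="Red")
    with pytest.warns(UserWarning, match="negative"):
        assert ps.stokes_reorg(g_ox, g_red) == -0.5


def test_stokes_reorg_empty_rejected():
    with pytest.raises(ValueError):
        ps.stokes_reorg(make_gaps([]), make_gaps([1.0], ensemble="Red"))


def test_variance_reorg_hand_computation():
    """Population variance of {-1, 0, 1} eV is 2/3; at k_BT = 0.5 eV the
    reorganization energy is 2/3 eV."""
    g = make_gaps([-1.0, 0.0, 1.0])
    lam, _ = ps.variance_reorg(g, temperature=0.5 / ps.K_B)
    assert lam == pytest.approx(2.0 / 3.0)


def test_variance_reorg_constructed_unity():
    rng = np.random.default_rng(0)
    target_var = 2 * kt(300.0) * 1.0
    x = rng.normal(0, 1, 5000)
    x = (x - x.mean()) / x.std() * np.sqrt(target_var)
    lam, se = ps.variance_reorg(make_gaps(x), 300.0)
    assert lam == pytest.approx(1.0, abs=1e-12)
    assert se < 0.1


def test_variance_reorg_ou_series():
    x = ps.generate_ou(ps.OUModeSpec(np.sqrt(0.0517), 2.0), 0.1, 300_000, 5)
    lam, _ = ps.variance_reorg(make_gaps(x), 300.0)
    assert lam == pytest.approx(1.0, abs=0.05)


def test_variance_reorg_bad_temperature():
    with pytest.raises(ValueError):
        ps.variance_reorg(make_gaps([0.0, 1.0]), temperature=-5.0)


@pytest.mark.parametrize(
    "lam_st,lam_ox,lam_red,printed",
    [(1.26, 1.67, 1.64, 1.3), (1.13, 1.57, 1.50, 1.4),
     (1.24, 3.07, 2.32, 2.2), (1.40, 6.40, 5.16, 4.1)],
)
def test_kappa_g_rounds_to_printed_values(lam_st, lam_ox, lam_red, printed):
    assert ps.round_half_up(ps.kappa_g(lam_st, lam_ox, lam_red), 1) == printed


def test_kappa_g_marcus_limit_and_guard():
    assert ps.kappa_g(1.5, 1.5, 1.5) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ps.kappa_g(0.0, 1.0, 1.0)


def test_barriers_marcus_limit():
    dg1, dg2, lam_r = ps.barriers(1.0, 1.0)
    assert dg1 == dg2 == pytest.approx(0.25)
    assert lam_r == pytest.approx(1.0)


def test_barriers_three_parameter_form():
    dg1, dg2, lam_r = ps.barriers(1.0, 2.0)
    assert (dg1, dg2, lam_r) == (pytest.approx(0.5), pytest.approx(0.125),
                                 pytest.approx(0.5))
    # the effective (reaction) reorganization energy from the measured pair
    dg1, dg2, lam_r = ps.barriers(1.24, 2.695)
    assert lam_r == pytest.approx(0.5705, abs=1e-4)
    assert dg2 == pytest.approx(0.1426, abs=1e-4)


def test_barriers_reject_nonzero_dg0():
    with pytest.raises(NotImplementedError):
        ps.barriers(1.0, 1.0, dg0=0.1)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 5))
def test_barrier_inequality_tracks_kappa(lam_st, lam_ox, lam_red):
    """Three-parameter barrier <= Marcus barrier iff kappa_G >= 1."""
    lam = (lam_ox + lam_red) / 2
    kg = ps.kappa_g(lam_st, lam_ox, lam_red)
    dg1, dg2, _ = ps.barriers(lam_st, lam)
    assert (dg2 <= dg1 + 1e-15) == (kg >= 1 - 1e-12)


def _gaussian_pair(lam, lam_st, n=400_000, seed=0, temperature=300.0):
    rng = np.random.default_rng(seed)
    sig = np.sqrt(2 * kt(temperature) * lam)
    x_ox = rng.normal(-lam_st, sig, n)
    x_red = rng.normal(+lam_st, sig, n)
    return make_gaps(x_ox), make_gaps(x_red, ensemble="Red")


def test_surfaces_gaussian_curvature():
    """Gaussian gap statistics give parabolic surfaces with curvature
    1/(4 lambda)."""
    lam = 0.8
    g_ox, g_red = _gaussian_pair(lam, lam, seed=2)
    surf = ps.surfaces(g_ox, g_red, 300.0, n_bins=60)
    assert surf.curvature_ox == pytest.approx(1 / (4 * lam), rel=0.05)
    assert surf.curvature_red == pytest.approx(1 / (4 * lam), rel=0.05)
    assert surf.vertex_ox == pytest.approx(-lam, abs=0.05)


def test_surfaces_marcus_crossing_barrier():
    """With lambda_st = lambda the fitted crossing barrier is lambda/4."""
    lam = 1.0
    g_ox, g_red = _gaussian_pair(lam, lam, seed=3)
    surf = ps.surfaces(g_ox, g_red, 300.0, n_bins=60)
    assert surf.crossing_x == pytest.approx(0.0, abs=0.05)
    assert surf.barrier_ox == pytest.approx(lam / 4, rel=0.05)


def test_surfaces_degenerate_input_rejected():
    g = make_gaps(np.zeros(100))
    with pytest.raises(ValueError):
        ps.surfaces(g, make_gaps(np.zeros(100), ensemble="Red"), 300.0, 60)
    with pytest.raises(ValueError):
        ps.surfaces(g, g, 300.0, n_bins=5)


def test_decompose_perfect_compensation():
    rng = np.random.default_rng(1)
    x_p = rng.normal(0, 0.3, 10_000)
    d = ps.decompose(x_p, -x_p, 300.0)
    assert d.lambda_pw == pytest.approx(-2 * d.lambda_p)
    assert d.total == pytest.approx(0.0, abs=1e-12)


def test_decompose_independent_components_no_cross_term():
    rng = np.random.default_rng(2)
    d = ps.decompose(rng.normal(0, 0.2, 200_000), rng.normal(0, 0.2, 200_000))
    assert abs(d.lambda_pw) < 0.05 * (d.lambda_p + d.lambda_w)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 1000), n=st.integers(2, 200))
def test_decomposition_identity_is_algebraic(seed, n):
    """lambda_p + lambda_w + lambda_pw equals the reorganization energy of
    the summed series to machine precision, for any inputs."""
    rng = np.random.default_rng(seed)
    x_p = rng.normal(0, 1, n)
    x_w = 0.5 * x_p + rng.normal(0, 2, n)
    d = ps.decompose(x_p, x_w, 300.0)
    lam_total, _ = ps.variance_reorg(make_gaps(x_p + x_w), 300.0)
    assert d.total == pytest.approx(lam_total, abs=1e-9 * max(1.0, lam_total))


def test_summarize_consistency():
    g_ox, g_red = _gaussian_pair(1.2, 1.0, n=100_000, seed=4)
    s = ps.summarize(g_ox, g_red, 300.0)
    assert s.lambda_mean == pytest.approx((s.lambda_ox + s.lambda_red) / 2)
    assert s.kappa_g == pytest.approx(s.lambda_mean / s.lambda_st)
    assert s.lambda_r == pytest.approx(s.lambda_st**2 / s.lambda_mean)
    assert np.isfinite(s.se_lambda_ox) and s.se_lambda_ox > 0
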