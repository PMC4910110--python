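"""Synthetic bath trajectories and state manifolds.

Stand-ins for the two expensive inputs of the real analysis — long classical
MD of the solvated protein (for the bath electrostatics) and semi-empirical
excited-state calculations (for the site manifold).  The generator emulates
the statistical structure the analysis assumes:

* Gaussian fluctuations of the potential at the metal centre, as sums of
  Ornstein-Uhlenbeck (OU) modes spanning sub-ps to ns relaxation times;
* separate protein and water potential components whose slow modes are
  strongly anti-correlated (the interfacial-water compensation effect);
* two ensembles (Ox / Red) differing in their means, as linear response
  prescribes;
* an isotropic fluctuating bath field driving the site polarizability;
* state manifolds with ~100 excited states calibrated to a target
  ground-state polarizability.

Every generator is deterministic under a fixed seed; per-component seeds are
derived from the base seed plus a CRC32 of "<ensemble>:<component>" so the
Ox and Red trajectories are independent but reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .constants import kt
from .quantum_center import StateManifold, RedoxSite

__all__ = [
    "OUModeSpec",
    "EnsembleMeans",
    "BathSpec",
    "BathTrajectory",
    "generate_ou",
    "generate_bath",
    "linear_response_spec",
    "generate_manifold",
    "generate_site",
]

ENSEMBLES = ("Ox", "Red")


@dataclass(frozen=True)
class OUModeSpec:
    """One Ornstein-Uhlenbeck relaxation mode: stationary standard deviation
    ``sigma`` (V, or V/Å for field components) and relaxation time ``tau``
    (ps)."""

    sigma: float
    tau: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class EnsembleMeans:
    """Stationary means of one ensemble: protein and water potentials (V)
    and the bath field vector (V/Å)."""

    phi_p: float = 0.0
    phi_w: float = 0.0
    e_field: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class BathSpec:
    """Full recipe for a pair of (Ox, Red) bath trajectories."""

    temperature: float = 300.0
    dt: float = 0.1
    n_frames: int = 10_000
    seed: int = 0
    protein_modes: tuple[OUModeSpec, ...] = ()
    water_modes: tuple[OUModeSpec, ...] = ()
    rho_pw: float = 0.0
    field_modes: tuple[OUModeSpec, ...] = ()
    mean_ox: EnsembleMeans = field(default_factory=EnsembleMeans)
    mean_red: EnsembleMeans = field(default_factory=EnsembleMeans)

    def __post_init__(self):
        if abs(self.rho_pw) > 1:
            raise ValueError(f"|rho_pw| must be <= 1, got {self.rho_pw}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        object.__setattr__(self, "protein_modes", tuple(self.protein_modes))
        object.__setattr__(self, "water_modes", tuple(self.water_modes))
        object.__setattr__(self, "field_modes", tuple(self.field_modes))


@dataclass(frozen=True)
class BathTrajectory:
    """Time series of the bath electrostatics at the site for one ensemble."""

    times: np.ndarray  # ps
    phi_p: np.ndarray  # V, protein component of the potential
    phi_w: np.ndarray  # V, water component
    e_field: np.ndarray  # (n, 3), V/Å
    ensemble: str

    def __post_init__(self):
        for name in ("times", "phi_p", "phi_w", "e_field"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.times.size
        if not (self.phi_p.size == n and self.phi_w.size == n
                and self.e_field.shape == (n, 3)):
            raise ValueError("trajectory columns have mismatched lengths")
        if self.ensemble not in ENSEMBLES:
            raise ValueError(f"ensemble must be one of {ENSEMBLES}, got {self.ensemble!r}")

    @property
    def phi_fe(self) -> np.ndarray:
        """Total potential at the metal centre, V."""
        return self.phi_p + self.phi_w

    @property
    def n_frames(self) -> int:
        return self.times.size


def _derive_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component generator: base seed + CRC32(label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def _ar1(eta0: float, eta: np.ndarray, sigma: float, tau: float, dt: float) -> np.ndarray:
    """Exact stationary AR(1) path from unit-normal innovations.

    x_0 = sigma*eta0;  x_{i+1} = a x_i + sigma*sqrt(1-a^2)*eta_i with
    a = exp(-dt/tau).  Moments are exact at any dt (no discretization bias).
    """
    a = np.exp(-dt / tau)
    x0 = sigma * eta0
    n = eta.size + 1
    out = np.empty(n)
    out[0] = x0
    if n > 1:
        w = sigma * np.sqrt(1.0 - a * a) * eta
        out[1:], _ = lfilter([1.0], [1.0, -a], w, zi=[a * x0])
    return out


def generate_ou(mode: OUModeSpec, dt: float, n: int, seed, mean: float = 0.0) -> np.ndarray:
    """Stationary OU series of length ``n`` with the exact AR(1) update.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  The series
    starts in the stationary distribution, so its mean is ``mean`` and its
    variance ``sigma**2`` at every index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = rng.standard_normal(n)
    return mean + _ar1(eta[0], eta[1:], mode.sigma, mode.tau, dt)


def _slowest(modes: tuple[OUModeSpec, ...]) -> int:
    return int(np.argmax([m.tau for m in modes])) if modes else -1


def _correlated_pair(
    rng: np.random.Generator,
    mode_a: OUModeSpec,
    mode_b: OUModeSpec,
    rho: float,
    dt: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two OU paths driven by jointly Gaussian innovations with correlation
    rho.  When the two relaxation times are equal the stationary
    cross-correlation equals rho exactly."""
    z = rng.standard_normal((2, n))
    eta_a = z[0]
    eta_b = rho * z[0] + np.sqrt(1.0 - rho * rho) * z[1]
    xa = _ar1(eta_a[0], eta_a[1:], mode_a.sigma, mode_a.tau, dt)
    xb = _ar1(eta_b[0], eta_b[1:], mode_b.sigma, mode_b.tau, dt)
    return xa, xb


def generate_bath(spec: BathSpec, ensemble: str, seed_label: str | None = None) -> BathTrajectory:
    """Generate one ensemble's bath trajectory from a :class:`BathSpec`.

    The protein and water potentials are sums of independent OU modes,
    except for the *slowest* mode of each, which are drawn jointly with
    innovation correlation ``spec.rho_pw`` (the protein-water compensation
    channel).  Field components are independent OU sums.  Ensemble means are
    added last.

    ``seed_label`` overrides the label used in seed derivation; passing the
    same label for both ensembles yields trajectories differing only in
    their means.
    """
    if ensemble not in ENSEMBLES:
        raise ValueError(f"ensemble must be one of {ENSEMBLES}, got {ensemble!r}")
    label = ensemble if seed_label is None else seed_label
    n, dt = spec.n_frames, spec.dt
    means = spec.mean_ox if ensemble == "Ox" else spec.mean_red

    phi_p = np.zeros(n)
    phi_w = np.zeros(n)
    ip, iw = _slowest(spec.protein_modes), _slowest(spec.water_modes)
    couple = spec.rho_pw != 0.0 and ip >= 0 and iw >= 0
    if couple:
        rng = _derive_rng(spec.seed, f"{label}:pw_slow")
        xa, xb = _correlated_pair(
            rng, spec.protein_modes[ip], spec.water_modes[iw], spec.rho_pw, dt, n
        )
        phi_p += xa
        phi_w += xb
    for i, mode in enumerate(spec.protein_modes):
        if couple and i == ip:
            continue
        phi_p += generate_ou(mode, dt, n, _derive_rng(spec.seed, f"{label}:phi_p:{i}"))
    for i, mode in enumerate(spec.water_modes):
        if couple and i == iw:
            continue
        phi_w += generate_ou(mode, dt, n, _derive_rng(spec.seed, f"{label}:phi_w:{i}"))

    e_field = np.zeros((n, 3))
    for ax, ax_name in enumerate("xyz"):
        for i, mode in enumerate(spec.field_modes):
            e_field[:, ax] += generate_ou(
                mode, dt, n, _derive_rng(spec.seed, f"{label}:eb_{ax_name}:{i}")
            )
        e_field[:, ax] += means.e_field[ax]

    return BathTrajectory(
        times=np.arange(n) * dt,
        phi_p=phi_p + means.phi_p,
        phi_w=phi_w + means.phi_w,
        e_field=e_field,
        ensemble=ensemble,
    )


# Shape of the protein/water variance split used by linear_response_spec,
# mirroring the observed decomposition lambda_p : lambda_w : lambda_pw
# = 2.28 : 3.39 : -4.0 (normalized to a total of 1.67):
_P_RATIO = 2.28 / 1.67
_W_RATIO = 3.39 / 1.67
_SLOW_FRACTION = 0.85  # share of each component's variance in the slowest mode


def linear_response_spec(
    target_lambda_st: float,
    target_lambda: float,
    timescales: tuple[float, ...] = (0.2, 2.0, 20.0),
    temperature: float = 300.0,
    delta_q: float = -1.0,
    dt: float = 0.1,
    n_frames: int = 100_000,
    seed: int = 0,
    field_sigma: float = 0.0,
    field_tau: float = 2.0,
) -> BathSpec:
    """Bath spec whose classical gap X = delta_q * phi_fe satisfies the
    requested reorganization energies.

    Construction: var(X) = 2 k_B T * target_lambda in each ensemble and
    <X>_Red - <X>_Ox = 2 * target_lambda_st, with <X>_Ox = -lambda_st and
    <X>_Red = +lambda_st.  With ``target_lambda_st == target_lambda`` the
    bath satisfies the fluctuation-dissipation relation X_0 = lambda (a
    Marcus, linear-response bath).

    The variance is split into protein and water components in the ratio
    2.28 : 3.39 with the excess removed by anti-correlating their slowest
    modes (cross component -4.0/1.67 of the total), emulating the
    protein-water electrostatic compensation; 85% of each component's
    variance sits in the slowest timescale and the rest is split equally
    over the faster ones.  The mean gap is carried by the potentials with
    opposite protein/water signs (phi_p at +1.5x, phi_w at -0.5x the total).

    ``field_sigma``/``field_tau`` give each Cartesian field component a
    single OU mode (identical statistics in both ensembles, zero mean), so
    the field contributes no Stokes shift.
    """
    if target_lambda_st <= 0 or target_lambda <= 0:
        raise ValueError("target reorganization energies must be positive")
    if delta_q == 0:
        raise ValueError("delta_q = 0 cannot carry a finite reorganization energy")
    timescales = tuple(float(t) for t in timescales)
    if len(timescales) == 0:
        raise ValueError("at least one relaxation timescale is required")
    if any(t <= 0 for t in timescales):
        raise ValueError("timescales must be positive")

    var_phi = 2.0 * kt(temperature) * target_lambda / delta_q**2
    var_p, var_w = _P_RATIO * var_phi, _W_RATIO * var_phi
    f_slow = _SLOW_FRACTION if len(timescales) > 1 else 1.0
    # cross term closes the budget: var_p + var_w + 2 rho sqrt(slow_p slow_w) = var_phi
    rho = (var_phi - var_p - var_w) / (2.0 * f_slow * np.sqrt(var_p * var_w))
    if not -1.0 <= rho <= 1.0:  # pragma: no cover - fixed ratios keep |rho| < 1
        raise ValueError("variance split requires |rho_pw| > 1; unreachable target")

    slow = max(timescales)
    fast = [t for t in sorted(timescales) if t != slow]
    n_fast = max(len(fast), 1)

    def modes(var_total: float) -> tuple[OUModeSpec, ...]:
        out = [OUModeSpec(np.sqrt(var_total * f_slow), slow)]
        for t in fast:
            out.append(OUModeSpec(np.sqrt(var_total * (1 - f_slow) / n_fast), t))
        return tuple(out)

    phi_mean_ox = -target_lambda_st / delta_q
    phi_mean_red = +target_lambda_st / delta_q
    field_modes = (OUModeSpec(field_sigma, field_tau),) if field_sigma > 0 else ()
    return BathSpec(
        temperature=temperature,
        dt=dt,
        n_frames=n_frames,
        seed=seed,
        protein_modes=modes(var_p),
        water_modes=modes(var_w),
        rho_pw=float(rho),
        field_modes=field_modes,
        mean_ox=EnsembleMeans(phi_p=1.5 * phi_mean_ox, phi_w=-0.5 * phi_mean_ox),
        mean_red=EnsembleMeans(phi_p=1.5 * phi_mean_red, phi_w=-0.5 * phi_mean_red),
    )


def generate_manifold(
    n_states: int = 101,
    gap_scale: float = 2.0,
    dipole_scale: float = 0.3,
    target_alpha: float | None = None,
    charge: float = -1.0,
    seed: int = 0,
) -> StateManifold:
    """Random state manifold with a controllable ground-state polarizability.

    Excited energies are drawn from a shifted exponential,
    ``E_m = gap_scale * (0.25 + Exp(1))`` (eV, sorted), so every upward gap
    is bounded away from zero.  Transition dipoles are i.i.d. normal with
    r.m.s. magnitude ``dipole_scale`` (e·Å), symmetrized; permanent
    (diagonal) dipoles are zero, so the fixed-charge limit of Ox/Red gaps is
    exactly the point-charge expression.  If ``target_alpha`` (Å³) is given,
    all transition dipoles are rescaled once so the ground-state isotropic
    polarizability at xi = 1 equals it.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if target_alpha is not None:
        if n_states < 2:
            raise ValueError("target_alpha requires at least 2 states")
        if target_alpha <= 0:
            raise ValueError("ground-state target_alpha must be positive")
    rng = np.random.default_rng(seed)
    energies = np.zeros(n_states)
    if n_states > 1:
        energies[1:] = np.sort(gap_scale * (0.25 + rng.exponential(1.0, n_states - 1)))
    raw = rng.normal(0.0, dipole_scale / np.sqrt(3.0), (n_states, n_states, 3))
    dipoles = np.triu(np.ones((n_states, n_states)), 1)[:, :, None] * raw
    dipoles = dipoles + dipoles.transpose(1, 0, 2)  # symmetric, zero diagonal
    manifold = StateManifold(energies=energies, dipoles=dipoles, charge=charge)
    if target_alpha is not None:
        from .quantum_center import polarizability

        _, a_iso = polarizability(manifold, 0, xi=1.0)
        manifold = StateManifold(
            energies=energies,
            dipoles=dipoles * np.sqrt(target_alpha / a_iso),
            charge=charge,
        )
    return manifold


def generate_site(
    alpha_ox: float = 85.0,
    alpha_red: float = 54.0,
    n_states: int = 101,
    gap_scale: float = 2.0,
    seed: int = 0,
    vacuum_gap: float = 0.0,
) -> RedoxSite:
    """Redox site with calibrated ground-state polarizabilities (Å³, xi = 1).

    Defaults reproduce the study conditions this package emulates:
    alpha_Red = 54 Å³ and a Red-Ox difference of -31 Å³, with M = 100
    excited states per manifold.
    """
    ox = generate_manifold(n_states, gap_scale, target_alpha=alpha_ox,
                           charge=-1.0, seed=seed)
    red = generate_manifold(n_states, gap_scale, target_alpha=alpha_red,
                            charge=-2.0, seed=seed + 1)
    return RedoxSite(ox=ox, red=red, vacuum_gap=vacuum_gap)
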