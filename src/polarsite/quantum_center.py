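"""Polarizable active site as an electronic state manifold.

The redox site (heme plus axial ligands, in the system this package emulates)
is represented by its ground state and M excited states.  Coupling to the
surrounding protein/water bath enters through the electrostatic potential at
the metal centre, phi_Fe, and the bath electric field E_b, in the dipolar
truncation of the bath-potential expansion.  The site Hamiltonian

    H_jj = E_j + Q*phi_Fe - mu_jj . E_b
    H_jk = -xi * mu_jk . E_b          (j != k)

is diagonalized to give the instantaneous ground energy of each redox state.
The dimensionless factor xi scales the transition dipoles (mu_km -> xi*mu_km),
which tunes the site polarizability as alpha(xi) = xi^2 * alpha(1); xi = 0 is
the non-polarizable (fixed-charge) limit.

Units: eV / e / Å / V (see :mod:`polarsite.constants`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ALPHA_TO_A3

__all__ = [
    "StateManifold",
    "RedoxSite",
    "BathField",
    "build_hamiltonian",
    "ground_energy",
    "polarizability",
    "stark_shift",
    "delta_polarizability",
]

_SYM_ATOL = 1e-9  # e·Å, tolerance for dipole-matrix symmetry


@dataclass(frozen=True)
class StateManifold:
    """Electronic states of one redox form of the quantum centre.

    Parameters
    ----------
    energies
        State energies in eV relative to the ground state, shape (M+1,),
        sorted non-decreasing; ``energies[0]`` is the ground state.
    dipoles
        Transition/permanent dipole vectors in e·Å, shape (M+1, M+1, 3),
        symmetric in the first two indices.  Diagonal entries are permanent
        dipoles; off-diagonal entries are transition dipoles.
    charge
        Total charge of the quantum centre in units of e (e.g. -1 for the
        oxidized, -2 for the reduced heme).
    """

    energies: np.ndarray
    dipoles: np.ndarray
    charge: float

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        d = np.asarray(self.dipoles, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "dipoles", d)
        if e.ndim != 1 or e.size < 1:
            raise ValueError("energies must be a non-empty 1-d array")
        n = e.size
        if d.shape != (n, n, 3):
            raise ValueError(
                f"dipoles must have shape ({n}, {n}, 3), got {d.shape}"
            )
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(d))):
            raise ValueError("manifold contains non-finite entries")
        if np.any(np.diff(e) < 0):
            raise ValueError("energies must be sorted non-decreasing")
        dev = np.max(np.abs(d - d.transpose(1, 0, 2)))
        if dev > _SYM_ATOL:
            raise ValueError(
                f"dipole matrix is not symmetric (max deviation {dev:.3e} e·Å)"
            )

    @property
    def n_states(self) -> int:
        """Number of states M+1 (ground plus M excited)."""
        return self.energies.size


@dataclass(frozen=True)
class RedoxSite:
    """Pair of state manifolds for the oxidized and reduced site.

    ``vacuum_gap`` is a constant offset (eV) between the Red and Ox ground
    references.  It cancels from every reorganization quantity, so the
    default 0 is almost always appropriate.
    """

    ox: StateManifold
    red: StateManifold
    vacuum_gap: float = 0.0

    def __post_init__(self):
        dq = self.ox.charge - self.red.charge
        if abs(dq - 1.0) > 1e-9:
            raise ValueError(
                "one transferred electron requires ox.charge - red.charge = +1, "
                f"got {dq}"
            )

    @property
    def delta_q(self) -> float:
        """Charge change on reduction, Q_red - Q_ox (= -1 e)."""
        return self.red.charge - self.ox.charge


@dataclass(frozen=True)
class BathField:
    """Instantaneous bath electrostatics at the site: potential at the metal
    centre (V) and the bath electric field vector (V/Å)."""

    phi_fe: float
    e_field: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        ef = np.asarray(self.e_field, dtype=float)
        object.__setattr__(self, "e_field", ef)
        if ef.shape != (3,):
            raise ValueError(f"e_field must be a 3-vector, got shape {ef.shape}")
        if not (np.isfinite(self.phi_fe) and np.all(np.isfinite(ef))):
            raise ValueError("bath field contains non-finite entries")


def build_hamiltonian(
    manifold: StateManifold,
    bath: BathField,
    xi: float = 1.0,
    include_permanent: bool = True,
) -> np.ndarray:
    """Quantum-centre Hamiltonian coupled to the bath electrostatics.

    ``H[j, j] = E_j + Q*phi_Fe - mu_jj.E_b`` and
    ``H[j, k] = -xi * mu_jk.E_b`` for ``j != k``; symmetric, in eV.

    ``include_permanent`` keeps the permanent-dipole term ``-mu_jj.E_b`` on
    the diagonal (default).  Only transition (off-diagonal) dipoles are
    scaled by xi, so xi = 0 turns off state mixing without removing the
    permanent-dipole coupling.
    """
    if xi < 0:
        raise ValueError(f"xi must be non-negative, got {xi}")
    mu_dot_e = manifold.dipoles @ bath.e_field  # (n, n)
    h = -xi * mu_dot_e
    diag = manifold.energies + manifold.charge * bath.phi_fe
    if include_permanent:
        diag = diag - np.diagonal(mu_dot_e)
    np.fill_diagonal(h, diag)
    return h


def ground_energy(h: np.ndarray) -> float:
    """Minimum eigenvalue of a symmetric Hamiltonian (eV).

    By the variational principle the result never exceeds the smallest
    diagonal element; any off-diagonal coupling to the minimal state lowers
    it further — this is the energetic origin of barrier reduction by a
    polarizable site.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError(f"Hamiltonian must be square, got shape {h.shape}")
    if not np.allclose(h, h.T, atol=1e-10, rtol=0):
        raise ValueError("Hamiltonian is not symmetric")
    return float(np.linalg.eigvalsh(h)[0])


def polarizability(
    manifold: StateManifold, k: int = 0, xi: float = 1.0
) -> tuple[np.ndarray, float]:
    """Sum-over-states polarizability tensor of state ``k``, in Å³.

    alpha_k^{ab} = 2 xi^2 sum_{m != k} mu_km^a mu_km^b / (E_m - E_k),
    evaluated in e²Å²/eV and converted by e²/(4πε₀) = 14.3996 eV·Å.  The
    isotropic scalar is trace/3.  Scales exactly as xi².

    For the ground state every denominator is an upward gap, so alpha_0 > 0
    whenever any transition dipole is nonzero; excited states can have
    negative contributions from downward gaps.
    """
    n = manifold.n_states
    if not 0 <= k < n:
        raise IndexError(f"state index {k} out of range for {n} states")
    de = manifold.energies - manifold.energies[k]  # E_m - E_k
    mu = manifold.dipoles[k]  # (n, 3), mu_km
    degenerate = (de == 0) & (np.arange(n) != k) & (np.linalg.norm(mu, axis=1) > 0)
    if np.any(degenerate):
        m = int(np.flatnonzero(degenerate)[0])
        raise ZeroDivisionError(
            f"degenerate states k={k}, m={m} with nonzero transition dipole: "
            "sum-over-states polarizability undefined"
        )
    mask = np.arange(n) != k
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_de = np.where(mask & (de != 0), 1.0 / np.where(de == 0, 1.0, de), 0.0)
    tensor = 2.0 * xi**2 * np.einsum("m,ma,mb->ab", inv_de, mu, mu) * ALPHA_TO_A3
    return tensor, float(np.trace(tensor) / 3.0)


def stark_shift(
    manifold: StateManifold, k: int, bath: BathField, xi: float = 1.0
) -> float:
    """Quadratic Stark shift of level k: -(1/2) E_b . alpha_k . E_b, in eV.

    Agrees with the exact diagonalization shift to second order in |E_b|
    (relative error of order (mu.E / dE)^2).
    """
    tensor, _ = polarizability(manifold, k, xi)
    alpha_ev = tensor / ALPHA_TO_A3  # back to e²Å²/eV
    e = bath.e_field
    return float(-0.5 * e @ alpha_ev @ e)


def delta_polarizability(site: RedoxSite, xi: float = 1.0) -> float:
    """Ground-state isotropic polarizability difference Red - Ox, in Å³.

    Negative when the oxidized site is the more polarizable, as for the
    heme system this package emulates.
    """
    _, a_red = polarizability(site.red, 0, xi)
    _, a_ox = polarizability(site.ox, 0, xi)
    return a_red - a_ox
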