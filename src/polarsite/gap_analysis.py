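"""Energy-gap reaction coordinate from bath trajectories.

The electron-transfer coordinate is the vertical energy gap
X = E_g(Red) - E_g(Ox) (+ constant vacuum offset) evaluated at a fixed bath
configuration.  Two routes are provided:

* **quantum**: the site Hamiltonian of each redox state is diagonalized at
  every frame's (phi_Fe, E_b), giving ground energies that include the
  field-induced mixing of excited states (polarizability);
* **classical**: the site is a set of fixed atomic charges, and
  X = sum_alpha dq_alpha * phi_alpha is a charge-weighted potential sum.

With the transition dipoles switched off (xi = 0) and matched permanent
dipoles the two routes agree frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantum_center import RedoxSite, StateManifold
from .synthetic_bath import BathTrajectory, ENSEMBLES

__all__ = ["GapSeries", "ChargeSet", "quantum_gap", "classical_gap", "split_components"]

_CHUNK = 2048  # frames per stacked diagonalization batch


@dataclass(frozen=True)
class GapSeries:
    """Reaction-coordinate time series X(t) (eV) for one ensemble, with
    optional protein/water components (classical route only)."""

    ensemble: str
    times: np.ndarray  # ps
    x: np.ndarray  # eV
    x_p: np.ndarray | None = None
    x_w: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "x", np.asarray(self.x, float))
        if self.ensemble not in ENSEMBLES:
            raise ValueError(f"ensemble must be one of {ENSEMBLES}, got {self.ensemble!r}")
        if self.times.size != self.x.size:
            raise ValueError("times and x have different lengths")
        for name in ("x_p", "x_w"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                object.__setattr__(self, name, v)
                if v.size != self.x.size:
                    raise ValueError(f"{name} length mismatch")

    @property
    def n_frames(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class ChargeSet:
    """Fixed-charge representation of the site: per-atom charge differences
    dq = q_red - q_ox (e) and per-atom potential series phi (V).

    ``phi`` has shape (n_frames, n_atoms).  The default invariant
    sum(dq) = -1 (one electron gained on reduction) can be lifted with
    ``allow_any_total``.
    """

    labels: tuple[str, ...]
    dq: np.ndarray
    phi: np.ndarray
    allow_any_total: bool = False

    def __post_init__(self):
        dq = np.atleast_1d(np.asarray(self.dq, float))
        phi = np.asarray(self.phi, float)
        if phi.ndim == 1:
            phi = phi[:, None]
        object.__setattr__(self, "dq", dq)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != dq.size:
            raise ValueError("labels and dq have different lengths")
        if phi.shape[1] != dq.size:
            raise ValueError(
                f"phi has {phi.shape[1]} atom columns but dq has {dq.size} entries"
            )
        total = float(dq.sum())
        if not self.allow_any_total and abs(total + 1.0) > 1e-9:
            raise ValueError(
                f"sum(dq) = {total}, expected -1 (one electron gained on "
                "reduction); pass allow_any_total=True to override"
            )


def _ground_energies(
    manifold: StateManifold, traj: BathTrajectory, xi: float,
    include_permanent: bool,
) -> np.ndarray:
    """Minimum eigenvalue of the site Hamiltonian at every frame.

    Frames are independent; they are diagonalized in stacked batches purely
    for speed, and the result does not depend on the batch size.
    """
    n = traj.n_frames
    m = manifold.n_states
    mu = manifold.dipoles  # (m, m, 3)
    diag_base = manifold.energies + manifold.charge * traj.phi_fe[:, None]  # (n, m)
    out = np.empty(n)
    for start in range(0, n, _CHUNK):
        sl = slice(start, min(start + _CHUNK, n))
        ef = traj.e_field[sl]  # (b, 3)
        mu_dot_e = np.einsum("jka,ba->bjk", mu, ef)  # (b, m, m)
        h = -xi * mu_dot_e
        idx = np.arange(m)
        h[:, idx, idx] = diag_base[sl]
        if include_permanent:
            h[:, idx, idx] -= mu_dot_e[:, idx, idx]
        try:
            out[sl] = np.linalg.eigvalsh(h)[:, 0]
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise RuntimeError(
                f"diagonalization failed in frame block starting at {start}"
            ) from err
    return out


def quantum_gap(
    site: RedoxSite,
    traj: BathTrajectory,
    xi: float = 1.0,
    include_permanent: bool = True,
) -> GapSeries:
    """Reaction coordinate by per-frame diagonalization of both redox states.

    X(t) = E_g^Red(t) - E_g^Ox(t) + vacuum_gap, with each ground energy
    obtained from the site Hamiltonian at that frame's (phi_Fe, E_b).
    """
    if xi < 0:
        raise ValueError(f"xi must be non-negative, got {xi}")
    e_red = _ground_energies(site.red, traj, xi, include_permanent)
    e_ox = _ground_energies(site.ox, traj, xi, include_permanent)
    return GapSeries(
        ensemble=traj.ensemble,
        times=traj.times,
        x=e_red - e_ox + site.vacuum_gap,
    )


def classical_gap(
    charges: ChargeSet,
    times: np.ndarray | None = None,
    ensemble: str = "Ox",
    vacuum_gap: float = 0.0,
    phi_p: np.ndarray | None = None,
    phi_w: np.ndarray | None = None,
) -> GapSeries:
    """Fixed-charge reaction coordinate X(t) = sum_alpha dq_alpha phi_alpha(t).

    If per-atom protein/water potential parts are supplied (same shape as
    ``charges.phi``), the corresponding gap components are returned too.
    """
    x = charges.phi @ charges.dq + vacuum_gap
    n = x.size
    if times is None:
        times = np.arange(n, dtype=float)
    kw = {}
    if phi_p is not None or phi_w is not None:
        if phi_p is None or phi_w is None:
            raise ValueError("provide both phi_p and phi_w or neither")
        phi_p = np.asarray(phi_p, float).reshape(n, -1)
        phi_w = np.asarray(phi_w, float).reshape(n, -1)
        kw["x_p"] = phi_p @ charges.dq
        kw["x_w"] = phi_w @ charges.dq
    return GapSeries(ensemble=ensemble, times=np.asarray(times, float), x=x, **kw)


def gap_from_bath(
    traj: BathTrajectory, dq_total: float = -1.0, vacuum_gap: float = 0.0
) -> GapSeries:
    """Single-site classical gap from a bath trajectory: the full charge
    difference sits on the metal centre, X = dq_total * phi_fe, with the
    protein/water split carried through."""
    return GapSeries(
        ensemble=traj.ensemble,
        times=traj.times,
        x=dq_total * traj.phi_fe + vacuum_gap,
        x_p=dq_total * traj.phi_p,
        x_w=dq_total * traj.phi_w,
    )


def split_components(traj: BathTrajectory, dq_total: float = -1.0) -> tuple[np.ndarray, np.ndarray]:
    """Protein and water parts of the single-site classical gap,
    (x_p, x_w) = dq_total * (phi_p, phi_w); their sum is the total gap."""
    if traj.phi_p is None or traj.phi_w is None:  # pragma: no cover - always set
        raise ValueError("trajectory lacks protein/water potential components")
    return dq_total * traj.phi_p, dq_total * traj.phi_w
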