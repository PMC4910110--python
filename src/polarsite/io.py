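"""Readers and writers for sites, bath trajectories and gap series.

Formats are plain text: JSON for state manifolds / redox sites and for
summary or provenance records, CSV (comma, dot decimal, fixed headers) for
time series.  Readers enforce the same invariants as the in-memory types
and report the offending key or line on failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .energetics import ReorgSummary, FreeEnergySurface
from .gap_analysis import GapSeries
from .quantum_center import RedoxSite, StateManifold
from .synthetic_bath import BathSpec, BathTrajectory, EnsembleMeans, OUModeSpec

__all__ = [
    "read_site", "write_site", "read_trajectory", "write_trajectory",
    "read_gaps", "write_gaps", "write_summary", "write_surface", "file_sha256",
]

TRAJ_COLUMNS = ["time_ps", "phi_p_V", "phi_w_V", "eb_x_VA", "eb_y_VA", "eb_z_VA"]
GAP_COLUMNS = ["time_ps", "x_eV"]
GAP_COMPONENT_COLUMNS = ["time_ps", "x_eV", "xp_eV", "xw_eV"]


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# -- state manifolds / redox sites -----------------------------------------

def _manifold_to_dict(m: StateManifold) -> dict:
    return {
        "n_states": int(m.n_states),
        "charge_e": float(m.charge),
        "energies_eV": m.energies.tolist(),
        "dipoles_eA": m.dipoles.tolist(),
    }


def _manifold_from_dict(d: dict, where: str) -> StateManifold:
    for key in ("n_states", "charge_e", "energies_eV", "dipoles_eA"):
        if key not in d:
            raise ValueError(f"{where}: missing required key {key!r}")
    energies = np.asarray(d["energies_eV"], float)
    if energies.size != int(d["n_states"]):
        raise ValueError(
            f"{where}: n_states = {d['n_states']} but {energies.size} energies given"
        )
    try:
        return StateManifold(
            energies=energies,
            dipoles=np.asarray(d["dipoles_eA"], float),
            charge=float(d["charge_e"]),
        )
    except ValueError as err:
        raise ValueError(f"{where}: {err}") from None


def write_site(path: str | Path, site: RedoxSite) -> None:
    payload = {
        "ox": _manifold_to_dict(site.ox),
        "red": _manifold_to_dict(site.red),
        "vacuum_gap_eV": float(site.vacuum_gap),
    }
    Path(path).write_text(json.dumps(payload))


def read_site(path: str | Path) -> RedoxSite:
    d = json.loads(Path(path).read_text())
    for key in ("ox", "red"):
        if key not in d:
            raise ValueError(f"site file {path}: missing required key {key!r}")
    return RedoxSite(
        ox=_manifold_from_dict(d["ox"], f"site file {path} [ox]"),
        red=_manifold_from_dict(d["red"], f"site file {path} [red]"),
        vacuum_gap=float(d.get("vacuum_gap_eV", 0.0)),
    )


# -- bath trajectories -------------------------------------------------------

def _spec_to_dict(spec: BathSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def write_trajectory(path: str | Path, traj: BathTrajectory, spec: BathSpec | None = None) -> None:
    """CSV of the bath time series; a ``.json`` sidecar records the ensemble
    label and, when given, the generating spec for provenance."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ps": traj.times,
            "phi_p_V": traj.phi_p,
            "phi_w_V": traj.phi_w,
            "eb_x_VA": traj.e_field[:, 0],
            "eb_y_VA": traj.e_field[:, 1],
            "eb_z_VA": traj.e_field[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {"ensemble": traj.ensemble}
    if spec is not None:
        sidecar["bath_spec"] = _spec_to_dict(spec)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trajectory(path: str | Path, ensemble: str | None = None) -> BathTrajectory:
    """Read a trajectory CSV; the ensemble label comes from the sidecar JSON
    unless given explicitly."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRAJ_COLUMNS:
        raise ValueError(
            f"{path}: header must be exactly {','.join(TRAJ_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise ValueError(f"{path}: empty trajectory")
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: NaN/missing cell at line {line}")
    t = df["time_ps"].to_numpy()
    if np.any(np.diff(t) <= 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ValueError(f"{path}: time column not strictly increasing at line {line}")
    if ensemble is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no ensemble given and no sidecar {sidecar.name} found"
            )
        ensemble = json.loads(sidecar.read_text())["ensemble"]
    return BathTrajectory(
        times=t,
        phi_p=df["phi_p_V"].to_numpy(),
        phi_w=df["phi_w_V"].to_numpy(),
        e_field=df[["eb_x_VA", "eb_y_VA", "eb_z_VA"]].to_numpy(),
        ensemble=ensemble,
    )


# -- gap series --------------------------------------------------------------

def write_gaps(
    path: str | Path,
    gaps: GapSeries,
    xi: float | None = None,
    site_checksum: str | None = None,
) -> None:
    path = Path(path)
    data = {"time_ps": gaps.times, "x_eV": gaps.x}
    if gaps.x_p is not None and gaps.x_w is not None:
        data["xp_eV"] = gaps.x_p
        data["xw_eV"] = gaps.x_w
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    sidecar = {"ensemble": gaps.ensemble, "xi": xi, "site_sha256": site_checksum}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_gaps(path: str | Path, ensemble: str | None = None) -> GapSeries:
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols not in (GAP_COLUMNS, GAP_COMPONENT_COLUMNS):
        raise ValueError(
            f"{path}: header must be {','.join(GAP_COLUMNS)} "
            f"(optionally + xp_eV,xw_eV), got {','.join(map(str, cols))}"
        )
    if df.empty:
        raise ValueError(f"{path}: empty gap file")
    if df.isna().any().any():
        raise ValueError(f"{path}: file contains missing values")
    if ensemble is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"{path}: no ensemble given and no sidecar found")
        ensemble = json.loads(sidecar.read_text())["ensemble"]
    kw = {}
    if "xp_eV" in cols:
        kw = {"x_p": df["xp_eV"].to_numpy(), "x_w": df["xw_eV"].to_numpy()}
    return GapSeries(
        ensemble=ensemble, times=df["time_ps"].to_numpy(), x=df["x_eV"].to_numpy(), **kw
    )


# -- derived results ---------------------------------------------------------

def write_summary(path: str | Path, summary: ReorgSummary, provenance: dict | None = None) -> None:
    payload = summary.as_dict()
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=1))


def write_surface(path: str | Path, surf: FreeEnergySurface) -> None:
    pd.DataFrame(
        {"x_eV": surf.bin_centers, "f_ox_eV": surf.f_ox, "f_red_eV": surf.f_red}
    ).to_csv(path, index=False, float_format="%.8g")
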