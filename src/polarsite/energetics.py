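"""Reorganization energies, barrier factors and free-energy surfaces.

Two reorganization energies characterize the gap statistics:

* the Stokes-shift value, 2*lambda_St = <X>_Red - <X>_Ox, from the mean
  vertical gaps of the two redox ensembles;
* the variance value, lambda_i = <dX^2>_i / (2 k_B T), for each ensemble,
  averaged as lambda = (lambda_Ox + lambda_Red)/2.

When the bath is Gaussian and fully sampled (linear response) the two
coincide and the activation barrier of a half reaction (dG0 = 0) is the
Marcus result dG = lambda/4.  When they separate, the three-parameter
description applies: the effective "reaction" reorganization energy is
lambda_r = lambda_St^2 / lambda and the barrier dG = lambda_r/4, lower than
Marcus whenever kappa_G = lambda/lambda_St > 1.  A large kappa_G is the
signature of a polarizable active site (or of ergodicity breaking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .constants import kt
from .gap_analysis import GapSeries

__all__ = [
    "ReorgSummary",
    "FreeEnergySurface",
    "Decomposition",
    "stokes_reorg",
    "variance_reorg",
    "kappa_g",
    "barriers",
    "surfaces",
    "decompose",
    "summarize",
]

N_BLOCKS = 10  # blocks for batch-means standard errors


@dataclass(frozen=True)
class ReorgSummary:
    """Reorganization energetics of one Ox/Red pair of gap series (eV,
    except the dimensionless kappa_g)."""

    lambda_st: float
    lambda_ox: float
    lambda_red: float
    lambda_mean: float
    kappa_g: float
    lambda_r: float
    dg_marcus: float
    dg_three_param: float
    dg0: float = 0.0
    se_lambda_ox: float = float("nan")
    se_lambda_red: float = float("nan")
    se_lambda_st: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FreeEnergySurface:
    """Histogram free-energy curves F_i(X) = -k_B T ln P_i(X) with parabola
    fits.  Empty bins carry NaN, never -inf.  ``curvature`` relates to the
    reorganization energy of a Gaussian ensemble as a = 1/(4 lambda)."""

    bin_centers: np.ndarray
    f_ox: np.ndarray
    f_red: np.ndarray
    curvature_ox: float
    curvature_red: float
    vertex_ox: float
    vertex_red: float
    crossing_x: float
    barrier_ox: float
    barrier_red: float


@dataclass(frozen=True)
class Decomposition:
    """Protein/water split of a reorganization energy: lambda_total =
    lambda_p + lambda_w + lambda_pw holds algebraically, with the cross term
    lambda_pw = cov(x_p, x_w)/(k_B T) typically negative (compensation)."""

    lambda_p: float
    lambda_w: float
    lambda_pw: float
    mean_xp: float
    mean_xw: float

    @property
    def total(self) -> float:
        return self.lambda_p + self.lambda_w + self.lambda_pw


def _check_nonempty(gaps: GapSeries, min_frames: int = 1) -> np.ndarray:
    x = np.asarray(gaps.x, float)
    if x.size < min_frames:
        raise ValueError(f"gap series needs >= {min_frames} frames, got {x.size}")
    return x


def _block_se(values: np.ndarray, stat, n_blocks: int = N_BLOCKS) -> float:
    """Batch-means standard error of ``stat`` over equal contiguous blocks;
    exposes slow convergence that the naive i.i.d. error hides."""
    n = values.size
    if n < n_blocks:
        return float("nan")
    m = n // n_blocks
    blocks = np.array([stat(values[i * m:(i + 1) * m]) for i in range(n_blocks)])
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def stokes_reorg(gaps_ox: GapSeries, gaps_red: GapSeries) -> float:
    """Stokes-shift reorganization energy (<X>_Red - <X>_Ox)/2, eV."""
    x_ox = _check_nonempty(gaps_ox)
    x_red = _check_nonempty(gaps_red)
    lam = float((x_red.mean() - x_ox.mean()) / 2.0)
    if lam < 0:
        warnings.warn(
            f"negative Stokes-shift reorganization energy ({lam:.4f} eV); "
            "check the ensemble labelling/sign convention",
            stacklevel=2,
        )
    return lam


def variance_reorg(gaps: GapSeries, temperature: float = 300.0) -> tuple[float, float]:
    """Variance reorganization energy <dX^2>/(2 k_B T) (population variance)
    and its 10-block batch-means standard error, both in eV."""
    x = _check_nonempty(gaps, 2)
    beta2 = 2.0 * kt(temperature)
    lam = float(x.var() / beta2)
    se = _block_se(x, lambda b: b.var() / beta2)
    return lam, se


def kappa_g(lambda_st: float, lambda_ox: float, lambda_red: float) -> float:
    """Barrier-reduction factor kappa_G = ((lambda_Ox + lambda_Red)/2) / lambda_St."""
    if lambda_st <= 0:
        raise ValueError(f"lambda_st must be positive, got {lambda_st}")
    return (lambda_ox + lambda_red) / 2.0 / lambda_st


def barriers(
    lambda_st: float, lambda_mean: float, dg0: float = 0.0
) -> tuple[float, float, float]:
    """Activation barriers of the half reaction (dG0 = 0 only).

    Returns (dG_Marcus, dG_three_param, lambda_r) with dG_Marcus =
    lambda/4, lambda_r = lambda_St^2/lambda and dG_three_param =
    lambda_r/4.  The three-parameter barrier is below Marcus exactly when
    kappa_G > 1.
    """
    if dg0 != 0.0:
        raise NotImplementedError(
            "nonzero reaction free energy is not supported; the half-reaction "
            "barrier formulas assume dG0 = 0"
        )
    if lambda_st <= 0 or lambda_mean <= 0:
        raise ValueError("reorganization energies must be positive")
    lambda_r = lambda_st**2 / lambda_mean
    return lambda_mean / 4.0, lambda_r / 4.0, lambda_r


def _fit_parabola(
    x: np.ndarray, f: np.ndarray, counts: np.ndarray
) -> tuple[float, float, float]:
    """Count-weighted quadratic fit over bins with >= 10 samples; returns
    (curvature, vertex, minimum).  Tail bins otherwise dominate the
    log-scale fit."""
    mask = counts >= 10
    if mask.sum() < 3:
        raise ValueError(
            "fewer than 3 bins with >= 10 counts; use fewer bins or more frames"
        )
    a, b, c = np.polyfit(x[mask], f[mask], 2, w=np.sqrt(counts[mask]))
    if a <= 0:
        raise ValueError("fitted surface is not convex; distribution too narrow or bimodal")
    return float(a), float(-b / (2 * a)), float(c - b * b / (4 * a))


def surfaces(
    gaps_ox: GapSeries,
    gaps_red: GapSeries,
    temperature: float = 300.0,
    n_bins: int = 60,
) -> FreeEnergySurface:
    """Free-energy curves of both ensembles on a shared uniform grid.

    F_i = -k_B T ln(count/(N*binwidth)), shifted to min 0; parabolas are
    fitted with count weights over well-populated bins, and the barrier is
    read from each fitted parabola at their crossing point between the two
    vertices.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    x_ox = _check_nonempty(gaps_ox, 2)
    x_red = _check_nonempty(gaps_red, 2)
    lo = min(x_ox.min(), x_red.min())
    hi = max(x_ox.max(), x_red.max())
    if hi <= lo:
        raise ValueError("all samples identical; free-energy surface undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    beta_inv = kt(temperature)

    def curve(x):
        counts, _ = np.histogram(x, bins=edges)
        if (counts > 0).sum() < 2:
            raise ValueError(
                "all probability mass in one bin; increase n_bins or the sample range"
            )
        with np.errstate(divide="ignore"):
            f = -beta_inv * np.log(counts / (x.size * width))
        f[counts == 0] = np.nan
        return f - np.nanmin(f), counts

    f_ox, c_ox = curve(x_ox)
    f_red, c_red = curve(x_red)
    a_ox, x0_ox, fmin_ox = _fit_parabola(centers, f_ox, c_ox)
    a_red, x0_red, fmin_red = _fit_parabola(centers, f_red, c_red)

    # crossing of the two fitted parabolas between the vertices
    da = a_ox - a_red
    db = -2 * (a_ox * x0_ox - a_red * x0_red)
    dc = a_ox * x0_ox**2 - a_red * x0_red**2 + fmin_ox - fmin_red
    if abs(da) < 1e-14:
        roots = np.array([-dc / db]) if db != 0 else np.array([])
    else:
        disc = db * db - 4 * da * dc
        roots = (
            np.array([(-db + s * np.sqrt(disc)) / (2 * da) for s in (+1, -1)])
            if disc >= 0
            else np.array([])
        )
    lo_v, hi_v = sorted((x0_ox, x0_red))
    inside = roots[(roots >= lo_v) & (roots <= hi_v)]
    if inside.size:
        crossing = float(inside[0])
    elif roots.size:
        crossing = float(roots[np.argmin(np.abs(roots - 0.5 * (lo_v + hi_v)))])
    else:
        raise ValueError("fitted parabolas do not cross; cannot place the transition state")
    barrier_ox = float(a_ox * (crossing - x0_ox) ** 2)
    barrier_red = float(a_red * (crossing - x0_red) ** 2)
    return FreeEnergySurface(
        bin_centers=centers,
        f_ox=f_ox,
        f_red=f_red,
        curvature_ox=a_ox,
        curvature_red=a_red,
        vertex_ox=x0_ox,
        vertex_red=x0_red,
        crossing_x=crossing,
        barrier_ox=barrier_ox,
        barrier_red=barrier_red,
    )


def decompose(
    x_p: np.ndarray, x_w: np.ndarray, temperature: float = 300.0
) -> Decomposition:
    """Protein/water/cross split of the variance reorganization energy.

    lambda_p = var(x_p)/(2kT), lambda_w = var(x_w)/(2kT),
    lambda_pw = cov(x_p, x_w)/(kT); their sum equals the reorganization
    energy of x_p + x_w identically (population moments).
    """
    x_p = np.asarray(x_p, float)
    x_w = np.asarray(x_w, float)
    if x_p.size != x_w.size:
        raise ValueError("component series have different lengths")
    if x_p.size < 2:
        raise ValueError("need at least 2 frames")
    beta2 = 2.0 * kt(temperature)
    dp = x_p - x_p.mean()
    dw = x_w - x_w.mean()
    return Decomposition(
        lambda_p=float(dp @ dp / dp.size / beta2),
        lambda_w=float(dw @ dw / dw.size / beta2),
        lambda_pw=float(2.0 * (dp @ dw) / dp.size / beta2),
        mean_xp=float(x_p.mean()),
        mean_xw=float(x_w.mean()),
    )


def summarize(
    gaps_ox: GapSeries, gaps_red: GapSeries, temperature: float = 300.0
) -> ReorgSummary:
    """All reorganization quantities of an Ox/Red pair in one pass."""
    lam_st = stokes_reorg(gaps_ox, gaps_red)
    lam_ox, se_ox = variance_reorg(gaps_ox, temperature)
    lam_red, se_red = variance_reorg(gaps_red, temperature)
    lam_mean = 0.5 * (lam_ox + lam_red)
    kg = kappa_g(lam_st, lam_ox, lam_red)
    dg1, dg2, lam_r = barriers(lam_st, lam_mean)
    se_st = 0.5 * np.hypot(
        _block_se(np.asarray(gaps_ox.x, float), np.mean),
        _block_se(np.asarray(gaps_red.x, float), np.mean),
    )
    return ReorgSummary(
        lambda_st=lam_st,
        lambda_ox=lam_ox,
        lambda_red=lam_red,
        lambda_mean=lam_mean,
        kappa_g=kg,
        lambda_r=lam_r,
        dg_marcus=dg1,
        dg_three_param=dg2,
        se_lambda_ox=se_ox,
        se_lambda_red=se_red,
        se_lambda_st=float(se_st),
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as printed summary tables
    use (numpy's bankers rounding would map 2.25 -> 2.2)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
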