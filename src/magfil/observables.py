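"""Estimators over chain trajectories and their fits.

Every length-like observable is normalized by d_avg, the mean
nearest-neighbour centre distance along the backbone measured in the same
trajectory (computed separately per crosslinking mode, monomer shape, chain
length and bond length).  End-to-end scaling uses <|R|> (a distance, so the
rigid-rod limit gives exponent a = 1 with prefactor b ~ 1); power-law fits
b*L^a are unweighted linear least squares in log-log space over L >= 15.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "ChainSnapshot",
    "FitResult",
    "d_avg",
    "end_to_end",
    "fit_end_to_end_scaling",
    "bond_autocorrelation",
    "persistence_length",
    "gyration_radius_sq",
    "magnetization",
    "magnetization_magnitude",
    "WallForceCurve",
    "wall_force_curve",
    "rod_gyration_sq",
]

FIT_L_MIN = 15
_C_FIT_FLOOR = 0.2  # fit the bond autocorrelation only where C > 0.2


@dataclass
class ChainSnapshot:
    """One recorded conformation: monomer centres and (optional) dipoles."""

    centres: np.ndarray  # (L, 3)
    dipoles: Optional[np.ndarray] = None
    time_index: int = 0


@dataclass
class FitResult:
    """Power-law fit y = b * L^a."""

    a: float
    b: float
    covariance: np.ndarray
    L_min: int = FIT_L_MIN


def _as_frames(trajectory) -> np.ndarray:
    """Accept (n_snap, L, 3), a single (L, 3) frame, or a Trajectory."""
    if hasattr(trajectory, "positions"):
        trajectory = trajectory.positions
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def d_avg(trajectory) -> float:
    """Mean nearest-neighbour centre distance over all junctions and frames."""
    frames = _as_frames(trajectory)
    dists = np.linalg.norm(np.diff(frames, axis=1), axis=-1)
    return float(np.mean(dists))


def end_to_end(trajectory, d: Optional[float] = None) -> float:
    """Normalized end-to-end distance <|r_L - r_1|> / d_avg."""
    frames = _as_frames(trajectory)
    if d is None:
        d = d_avg(frames)
    r = np.linalg.norm(frames[:, -1] - frames[:, 0], axis=-1)
    return float(np.mean(r) / d)


def gyration_radius_sq(trajectory, d: Optional[float] = None) -> float:
    """Squared normalized gyration radius <(1/L) sum |r_i - r_cm|^2> / d_avg^2."""
    frames = _as_frames(trajectory)
    if d is None:
        d = d_avg(frames)
    cm = frames.mean(axis=1, keepdims=True)
    rg2 = np.mean(np.sum((frames - cm) ** 2, axis=-1), axis=1)
    return float(np.mean(rg2) / d**2)


def rod_gyration_sq(L: int) -> float:
    """(R*_g)^2 of a fully elongated chain: (L^2 - 1)/12."""
    return (L**2 - 1) / 12.0


def fit_end_to_end_scaling(L_values, Re_values, L_min: int = FIT_L_MIN) -> FitResult:
    """Fit b*L^a to normalized end-to-end distances, using only L >= L_min."""
    L_values = np.asarray(L_values, dtype=float)
    Re_values = np.asarray(Re_values, dtype=float)
    keep = L_values >= L_min
    if keep.sum() < 3:
        raise ValueError(f"need at least 3 chain lengths with L >= {L_min}")
    x = np.log(L_values[keep])
    y = np.log(Re_values[keep])
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    return FitResult(a=float(coeffs[0]), b=float(np.exp(coeffs[1])),
                     covariance=cov, L_min=L_min)


def bond_autocorrelation(trajectory) -> np.ndarray:
    """C(n) = <u_i . u_{i+n}> over unit bond vectors, averaged over i and frames."""
    frames = _as_frames(trajectory)
    if frames.shape[1] < 3:
        raise ValueError("bond autocorrelation needs at least 3 monomers")
    bonds = np.diff(frames, axis=1)
    u = bonds / np.linalg.norm(bonds, axis=-1, keepdims=True)
    nb = u.shape[1]
    c = np.empty(nb)
    for n in range(nb):
        dots = np.sum(u[:, : nb - n] * u[:, n:], axis=-1)
        c[n] = dots.mean()
    return c


def persistence_length(c: np.ndarray, d: float, sigma: float = 1.0) -> float:
    """Persistence length from C(n) = exp(-n d_avg / L_p), in units of sigma.

    Through-origin least squares of ln C(n) against n over the initial decay
    (points with C > 0.2); raises if the correlation does not decay.
    """
    c = np.asarray(c, dtype=float)
    n = np.arange(len(c))
    keep = (c > _C_FIT_FLOOR) & (c < 1.0) | (n == 0)
    keep &= c > 0
    n_sel = n[keep]
    c_sel = c[keep]
    if np.sum(n_sel > 0) < 1 or np.any(c[1:2] >= 1.0):
        raise ValueError("bond autocorrelation does not decay; only a lower "
                         "bound on L_p can be quoted")
    logc = np.log(c_sel)
    slope = np.sum(n_sel * logc) / np.sum(n_sel**2)
    if slope >= 0:
        raise ValueError("bond autocorrelation does not decay")
    return float(-d / slope / sigma)


def magnetization(mu_traj, H, mu_max: float, exclude: Optional[set] = None) -> float:
    """Normalized projection <sum_i mu_i . Hhat> / (L mu_max) in [-1, 1].

    ``exclude`` drops (grafted) monomer indices from both the sum and the
    normalization.  Raises for H = 0, where the projection direction is
    undefined (use magnetization_magnitude instead).
    """
    H = np.asarray(H, dtype=float)
    hn = np.linalg.norm(H)
    if hn == 0:
        raise ValueError("H = 0: projection direction undefined; "
                         "use magnetization_magnitude")
    mu = _as_frames(mu_traj)
    keep = [i for i in range(mu.shape[1]) if not exclude or i not in exclude]
    proj = np.sum(mu[:, keep] @ (H / hn), axis=-1)
    return float(np.mean(proj) / (len(keep) * mu_max))


def magnetization_magnitude(mu_traj, mu_max: float,
                            exclude: Optional[set] = None) -> float:
    """Field-free variant |sum_i mu_i| / (L mu_max), averaged over frames."""
    mu = _as_frames(mu_traj)
    keep = [i for i in range(mu.shape[1]) if not exclude or i not in exclude]
    mag = np.linalg.norm(np.sum(mu[:, keep], axis=1), axis=-1)
    return float(np.mean(mag) / (len(keep) * mu_max))


@dataclass
class WallForceCurve:
    """Force-compression curve with its exponential fit and zero crossing."""

    compression: np.ndarray  # wall displacement from full stretch
    force: np.ndarray  # mean z-force on the bottom wall (positive = pulling)
    d_c: Optional[float]  # zero crossing, None if the force never changes sign
    fit_params: Optional[tuple]  # (A, k, C) of F = A exp(-k x) + C


def wall_force_curve(compression, force) -> WallForceCurve:
    """Summarize a compression run: exponential fit and zero crossing d_C."""
    x = np.asarray(compression, dtype=float)
    f = np.asarray(force, dtype=float)
    d_c = None
    sign_change = np.nonzero(np.diff(np.sign(f)))[0]
    if len(sign_change):
        k = sign_change[0]
        # linear interpolation across the first crossing
        d_c = float(x[k] - f[k] * (x[k + 1] - x[k]) / (f[k + 1] - f[k]))
    fit = None
    try:
        scale = max(abs(f[0]), 1e-9)
        p, _ = optimize.curve_fit(
            lambda xx, a, k_, c: a * np.exp(-k_ * xx) + c,
            x, f, p0=(scale, 1.0, f[-1]), maxfev=10_000)
        fit = tuple(float(v) for v in p)
    except Exception:
        pass
    return WallForceCurve(compression=x, force=f, d_c=d_c, fit_params=fit)
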