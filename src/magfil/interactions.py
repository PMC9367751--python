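"""Pair potentials, forces, torques and the superparamagnetic moment update.

Reduced units throughout: k_BT = 1 sets the energy scale, the dipolar
prefactor mu0/4pi is absorbed into the moments (so mu_max^2 = 3 is the
dimensionless dipolar coupling), and lengths are in monomer-size units.

These are straightforward NumPy implementations, used directly for two-body
analysis and as the reference the compiled simulation kernels are tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairParams",
    "DipoleState",
    "FieldSpec",
    "wca_energy_force",
    "fene_energy_force",
    "dipole_dipole_energy_force_torque",
    "dipole_field",
    "zeeman_energy_torque",
    "langevin_function",
    "spm_moments_one_pass",
    "spm_moments_fixed_point",
    "update_spm_moments",
    "pair_scan",
    "BondOverstretchError",
    "WCA_CUTOFF_FACTOR",
]

WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


class BondOverstretchError(RuntimeError):
    """A FENE bond was driven to or past its maximal extension r_f."""


@dataclass
class PairParams:
    """Mixed WCA parameters for one site pair; r_cut defaults to 2^(1/6) sigma."""

    sigma: float
    epsilon: float
    r_cut: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r_cut is None:
            self.r_cut = WCA_CUTOFF_FACTOR * self.sigma

    @staticmethod
    def mix(sigma_i, epsilon_i, sigma_j, epsilon_j) -> "PairParams":
        """Lorentz-Berthelot mixing for unlike sites."""
        return PairParams(0.5 * (sigma_i + sigma_j), np.sqrt(epsilon_i * epsilon_j))


@dataclass
class DipoleState:
    """Point dipole of a monomer: fixed length for FM, field-set for SPM."""

    moment: np.ndarray
    kind: str  # "FM" | "SPM"
    body_axis: np.ndarray | None = None  # FM only: moment direction in body frame

    def __post_init__(self) -> None:
        self.moment = np.asarray(self.moment, dtype=float)
        if self.body_axis is not None:
            self.body_axis = np.asarray(self.body_axis, dtype=float)
            self.body_axis = self.body_axis / np.linalg.norm(self.body_axis)


@dataclass
class FieldSpec:
    """Uniform reduced external field."""

    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)


# ---------------------------------------------------------------------------
# steric & bonded
# ---------------------------------------------------------------------------

def wca_energy_force(r_vec, params: PairParams):
    """WCA energy and force on particle i, with r_vec = r_i - r_j.

    U(r) = U_LJ(r) + epsilon for r < r_cut, 0 beyond; the shift makes the
    potential vanish continuously at the cutoff, leaving pure repulsion.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r == 0:
        raise ValueError("overlapping point centres (r = 0)")
    if r >= params.r_cut:
        return 0.0, np.zeros(3)
    sr6 = (params.sigma / r) ** 6
    energy = 4 * params.epsilon * (sr6 * sr6 - sr6) + params.epsilon
    fmag = 24 * params.epsilon * (2 * sr6 * sr6 - sr6) / r
    return energy, fmag * r_vec / r


def fene_energy_force(r_vec, K_f: float, r0: float, r_f: float):
    """Finitely extensible spring with shifted equilibrium length r0.

    U(r) = -(K_f r_f^2 / 2) ln[1 - ((r - r0)/r_f)^2]; diverges at extension
    |r - r0| = r_f, which raises BondOverstretchError.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    x = (r - r0) / r_f
    if abs(x) >= 1.0:
        raise BondOverstretchError(
            f"FENE bond stretched to |r - r0| = {abs(r - r0):.4g} >= r_f = {r_f:.4g}"
        )
    energy = -0.5 * K_f * r_f**2 * np.log1p(-(x * x))
    fmag = -K_f * (r - r0) / (1 - x * x)  # restoring toward r0
    return energy, fmag * r_vec / r


# ---------------------------------------------------------------------------
# magnetic
# ---------------------------------------------------------------------------

def dipole_dipole_energy_force_torque(mu_i, mu_j, r_vec):
    """Point dipole-dipole pair: energy, force on i, and spin torques.

    U = [mu_i . mu_j - 3 (mu_i . rhat)(mu_j . rhat)] / r^3 with r_vec from j
    to i (r_i - r_j) and unit dipolar prefactor.  Torques are mu x B of the
    partner's dipole field; together with the r x F couple they conserve
    total angular momentum.
    """
    mu_i = np.asarray(mu_i, dtype=float)
    mu_j = np.asarray(mu_j, dtype=float)
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r == 0:
        raise ValueError("coincident dipoles (r = 0)")
    rhat = r_vec / r
    mi_r = np.dot(mu_i, rhat)
    mj_r = np.dot(mu_j, rhat)
    mi_mj = np.dot(mu_i, mu_j)
    energy = (mi_mj - 3 * mi_r * mj_r) / r**3
    force = (
        3 * (mi_mj * rhat + mj_r * mu_i + mi_r * mu_j - 5 * mi_r * mj_r * rhat)
        / r**4
    )
    torque_i = np.cross(mu_i, dipole_field(mu_j, r_vec))
    torque_j = np.cross(mu_j, dipole_field(mu_i, -r_vec))
    return energy, force, torque_i, torque_j


def dipole_field(mu_j, r_vec):
    """Field of dipole mu_j at displacement r_vec from it: [3 rhat(mu.rhat) - mu]/r^3."""
    mu_j = np.asarray(mu_j, dtype=float)
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r == 0:
        raise ValueError("field requested at the dipole position (r = 0)")
    rhat = r_vec / r
    return (3 * rhat * np.dot(mu_j, rhat) - mu_j) / r**3


def zeeman_energy_torque(mu, H):
    """Zeeman coupling U = -mu.H and the torque mu x H."""
    mu = np.asarray(mu, dtype=float)
    H = np.asarray(H, dtype=float)
    return -float(np.dot(mu, H)), np.cross(mu, H)


def langevin_function(alpha):
    """L(alpha) = coth(alpha) - 1/alpha, the equilibrium single-spin magnetization.

    Below |alpha| = 1e-4 the Taylor series alpha/3 - alpha^3/45 is used to
    avoid catastrophic cancellation; the function is odd and saturates at 1.
    """
    a = np.asarray(alpha, dtype=float)
    small = np.abs(a) < 1e-4
    out = np.empty_like(a)
    a_s = a[small]
    out[small] = a_s / 3.0 - a_s**3 / 45.0
    a_l = a[~small]
    out[~small] = 1.0 / np.tanh(a_l) - 1.0 / a_l
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# superparamagnetic moment update
# ---------------------------------------------------------------------------

def _total_fields(positions: np.ndarray, moments: np.ndarray, H: np.ndarray):
    """H plus the dipole fields of all other monomers, at every centre."""
    n = len(positions)
    B = np.tile(np.asarray(H, dtype=float), (n, 1))
    for i in range(n):
        for j in range(n):
            if i != j and np.any(moments[j]):
                B[i] += dipole_field(moments[j], positions[i] - positions[j])
    return B


def spm_moments_one_pass(positions, moments, H, mu_max: float, kT: float = 1.0):
    """One relaxation-style update: moments follow the Langevin law of the
    local field computed from the previous-step moments."""
    positions = np.asarray(positions, dtype=float)
    moments = np.asarray(moments, dtype=float)
    B = _total_fields(positions, moments, H)
    new = np.zeros_like(moments)
    for i, b in enumerate(B):
        bn = np.linalg.norm(b)
        if bn > 0:
            new[i] = mu_max * langevin_function(mu_max * bn / kT) * b / bn
    return new


def spm_moments_fixed_point(
    positions, moments, H, mu_max: float, kT: float = 1.0,
    tol: float = 1e-10, max_iter: int = 10_000,
):
    """Iterate the one-pass update to self-consistency (validation mode)."""
    cur = np.asarray(moments, dtype=float).copy()
    for _ in range(max_iter):
        nxt = spm_moments_one_pass(positions, cur, H, mu_max, kT)
        if np.max(np.abs(nxt - cur)) < tol:
            return nxt
        cur = nxt
    raise RuntimeError("SPM fixed-point iteration did not converge")


def update_spm_moments(system, mode: str = "one_pass", tol: float = 1e-10):
    """Update the dipole moments of an all-SPM FilamentSystem in place."""
    if system.template.magnetic_kind != "SPM":
        raise ValueError("update_spm_moments requires an SPM system")
    fn = spm_moments_one_pass if mode == "one_pass" else None
    if fn is not None:
        system.mu = fn(system.positions, system.mu, system.field.H,
                       system.template.mu_max)
    elif mode == "fixed_point":
        system.mu = spm_moments_fixed_point(
            system.positions, system.mu, system.field.H,
            system.template.mu_max, tol=tol)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return system.mu


def pair_scan(kind: str, r_min: float = 0.5, r_max: float = 2.5, n: int = 100,
              **params):
    """Two-body energy/force table over a centre-distance scan (debug aid).

    kind: "wca" (params sigma, epsilon), "fene" (K_f, r0, r_f) or
    "dipole_head_to_tail" (mu). Returns a DataFrame with columns r, energy,
    force (radial component on the first body).
    """
    import pandas as pd

    rows = []
    for r in np.linspace(r_min, r_max, n):
        r_vec = np.array([0.0, 0.0, r])
        try:
            if kind == "wca":
                pp = PairParams(params.get("sigma", 1.0),
                                params.get("epsilon", 1.0))
                e, f = wca_energy_force(r_vec, pp)
            elif kind == "fene":
                e, f = fene_energy_force(r_vec, params.get("K_f", 10.0),
                                         params.get("r0", 0.6),
                                         params.get("r_f", 1.8))
            elif kind == "dipole_head_to_tail":
                mu = np.array([0.0, 0.0, params.get("mu", np.sqrt(3.0))])
                e, f, _, _ = dipole_dipole_energy_force_torque(mu, mu, r_vec)
            else:
                raise ValueError(f"unknown pair kind {kind!r}")
        except BondOverstretchError:
            continue
        rows.append({"r": r, "energy": e, "force": f[2]})
    return pd.DataFrame(rows)
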