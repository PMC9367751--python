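"""Synthetic chain trajectories with known statistics, for estimator checks.

The worm-like chain generator draws successive bond directions from the
exact von Mises-Fisher transition kernel, so the bond autocorrelation is
exactly exponential, C(n) = g^n with g = L(kappa): estimators can be
round-tripped against a known persistence length without running dynamics.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .interactions import langevin_function

__all__ = ["wlc_trajectory", "freely_jointed_trajectory", "rigid_rod_trajectory"]


def _kappa_for_decay(g: float) -> float:
    """Solve L(kappa) = g for the vMF concentration, 0 < g < 1."""
    return float(optimize.brentq(lambda k: langevin_function(k) - g, 1e-8, 1e6))


def _sample_vmf_step(u: np.ndarray, kappa: float, rng: np.random.Generator):
    """New unit vector at polar angle ~ vMF(kappa) around u, uniform azimuth."""
    w = rng.random()
    cos_t = 1.0 + np.log(w + (1.0 - w) * np.exp(-2.0 * kappa)) / kappa
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
    phi = 2 * np.pi * rng.random()
    # orthonormal frame around u
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return cos_t * u + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)


def wlc_trajectory(L: int, n_frames: int, lp_bonds: float, spacing: float = 1.0,
                   seed: int = 0) -> np.ndarray:
    """Worm-like chains with persistence length lp_bonds (in bond units).

    Returns centres of shape (n_frames, L, 3); C(n) = exp(-n / lp_bonds)
    holds exactly in expectation, so the recovered persistence length is
    spacing * lp_bonds.
    """
    rng = np.random.default_rng(seed)
    g = np.exp(-1.0 / lp_bonds)
    kappa = _kappa_for_decay(g)
    frames = np.zeros((n_frames, L, 3))
    for f in range(n_frames):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos = np.zeros((L, 3))
        for i in range(1, L):
            pos[i] = pos[i - 1] + spacing * u
            u = _sample_vmf_step(u, kappa, rng)
        frames[f] = pos
    return frames


def freely_jointed_trajectory(L: int, n_frames: int, spacing: float = 1.0,
                              seed: int = 0) -> np.ndarray:
    """Freely jointed chains: bond directions independent and isotropic."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_frames, L - 1, 3))
    steps /= np.linalg.norm(steps, axis=-1, keepdims=True)
    frames = np.zeros((n_frames, L, 3))
    frames[:, 1:] = spacing * np.cumsum(steps, axis=1)
    return frames


def rigid_rod_trajectory(L: int, n_frames: int = 1, spacing: float = 1.0,
                         direction=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Perfectly straight chains along a fixed direction."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    line = np.outer(np.arange(L), spacing * d)
    return np.tile(line, (n_frames, 1, 1))
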