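"""Assembly of filament systems: CTC/FTF topologies, grafting, slit walls.

All printed model constants live in :func:`parameter_table`; the builders
never accept ad-hoc overrides of them.  Chains are created fully straight
and stretched along a (optionally random) backbone direction, with every
FENE bond at (or, for cube FTF junctions, symmetrically straddling) its
equilibrium length.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import (
    MonomerTemplate,
    build_cube_monomer,
    build_sphere_monomer,
    quat_align_z,
    random_unit_vector,
)
from .interactions import FieldSpec

__all__ = [
    "BondSpec",
    "SlitWalls",
    "FilamentSystem",
    "parameter_table",
    "build_filament",
    "graft_to_slit",
    "bond_table",
    "ALPHA_VALUES",
]

#: printed equilibrium-bond-length multipliers r0 = alpha * sigma
ALPHA_VALUES = (0.6, 0.8, 0.9, 1.0)
L_RANGE = (2, 50)
R_F_FACTOR = 3.0  # maximal extension r_f = 3 r0


@dataclass(frozen=True)
class BondSpec:
    """One FENE bond between anchor sites of consecutive monomers."""

    monomer_i: int
    site_i: int
    monomer_j: int
    site_j: int
    K_f: float
    r0: float
    r_f: float

    def __post_init__(self) -> None:
        if self.monomer_j != self.monomer_i + 1:
            raise ValueError("bonds must link consecutive monomers")
        if abs(self.r_f - R_F_FACTOR * self.r0) > 1e-12:
            raise ValueError("maximal extension must be 3x the equilibrium length")


@dataclass
class SlitWalls:
    """Two flat repulsive planes normal to z."""

    z_bottom: float
    z_top: float
    epsilon: float = 1.0

    @property
    def separation(self) -> float:
        return self.z_top - self.z_bottom


@dataclass
class FilamentSystem:
    """L rigid monomers sharing one template, a FENE bond path, and a field."""

    template: MonomerTemplate
    positions: np.ndarray  # (L,3)
    orientations: np.ndarray  # (L,4)
    velocities: np.ndarray  # (L,3)
    angular_velocities: np.ndarray  # (L,3), body frame
    mu: np.ndarray  # (L,3)
    bonds: list
    field: FieldSpec = dc_field(default_factory=lambda: FieldSpec(np.zeros(3)))
    walls: Optional[SlitWalls] = None
    grafted: set = dc_field(default_factory=set)
    fm_axis: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    crosslink: str = "CTC"
    alpha: float = 1.0
    spacing: float = 1.0  # initial straight-chain centre spacing

    @property
    def n_monomers(self) -> int:
        return len(self.positions)

    def copy(self) -> "FilamentSystem":
        return FilamentSystem(
            template=self.template,
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            velocities=self.velocities.copy(),
            angular_velocities=self.angular_velocities.copy(),
            mu=self.mu.copy(),
            bonds=list(self.bonds),
            field=FieldSpec(self.field.H.copy()),
            walls=None if self.walls is None else SlitWalls(
                self.walls.z_bottom, self.walls.z_top, self.walls.epsilon),
            grafted=set(self.grafted),
            fm_axis=self.fm_axis.copy(),
            crosslink=self.crosslink,
            alpha=self.alpha,
            spacing=self.spacing,
        )


def parameter_table(shape: str, crosslink: str) -> dict:
    """Printed reduced-unit constants for a (shape, crosslink) combination.

    Spheres: sigma = 0.91, epsilon = 100.  Cubes: central sigma = 1,
    epsilon = 1, corner sites sigma = 0.41, edge sites sigma = 0.49.
    Bond rigidity: K_f = 90 for CTC, 10 for FTF.
    """
    shape = shape.lower()
    crosslink = crosslink.upper()
    if shape not in ("sphere", "cube") or crosslink not in ("CTC", "FTF"):
        raise ValueError(f"unknown combination ({shape!r}, {crosslink!r})")
    k_f = 90.0 if crosslink == "CTC" else 10.0
    if shape == "sphere":
        return {"sigma": 0.91, "epsilon": 100.0, "K_f": k_f}
    return {
        "sigma": 1.0,
        "epsilon": 1.0,
        "sigma_corner": 0.41,
        "sigma_edge": 0.49,
        "K_f": k_f,
    }


def _crown_pairs():
    """FTF sphere junction: forward-crown site k bonds to backward-crown site k."""
    # sites 1..8 are the +sigma/4 crown, 9..16 the -sigma/4 crown
    return [(1 + k, 9 + k) for k in range(8)]


def _cube_face_pairs(template: MonomerTemplate):
    """FTF cube junction: 4 corner-corner + 4 edge-edge bonds on facing faces.

    Each +z site of monomer i pairs with the -z site of monomer i+1 that has
    the same transverse (x, y) coordinates, so a straight chain is torsion
    free.
    """
    body = template.body_positions()
    plus = [s for s in range(1, len(body)) if body[s, 2] > 1e-9]
    pairs = []
    for sp in plus:
        target = np.array([body[sp, 0], body[sp, 1], -body[sp, 2]])
        for sm in range(1, len(body)):
            if np.allclose(body[sm], target, atol=1e-12):
                pairs.append((sp, sm))
                break
        else:  # pragma: no cover - template construction guarantees a match
            raise RuntimeError("no mirror site found for FTF cube bond")
    assert len(pairs) == 8
    return pairs


def _straight_spacing(template, pairs, k_f: float, r0: float, r_f: float) -> float:
    """Centre spacing of two aligned monomers at zero net axial force.

    Solves (FENE tension of all junction bonds) = (WCA repulsion between all
    steric site pairs) along the backbone axis with both bodies in their
    construction orientation.  When the steric cores do not overlap this is
    simply the spacing that puts every bond at r0.
    """
    from scipy.optimize import brentq

    from .interactions import PairParams, fene_energy_force, wca_energy_force

    body = template.body_positions()
    ster = np.flatnonzero(template.steric_mask())
    sig = template.diameters()
    eps = template.epsilons()
    z = np.array([0.0, 0.0, 1.0])

    # bond validity window: every bond length must stay inside (r0-r_f, r0+r_f)
    offsets = [body[si, 2] - body[sj, 2] for si, sj in pairs]  # length = D - off
    lo = max(max(off + r0 - r_f for off in offsets) + 1e-6 * r0, 1e-3)
    hi = min(off + r0 + r_f for off in offsets) - 1e-6 * r0

    def net_force_on_upper(D: float) -> float:
        f = 0.0
        for si, sj in pairs:  # bond from lower site si to upper site sj
            r_vec = (body[sj] + D * z) - body[si]
            _, fb = fene_energy_force(r_vec, k_f, r0, r_f)
            f += fb[2]
        for a in ster:
            for b in ster:
                r_vec = (body[b] + D * z) - body[a]
                pp = PairParams.mix(sig[b], eps[b], sig[a], eps[a])
                if np.linalg.norm(r_vec) < pp.r_cut:
                    _, fw = wca_energy_force(r_vec, pp)
                    f += fw[2]
        return f

    if net_force_on_upper(hi) > 0:  # never balances within bond validity
        raise RuntimeError("no straight-chain force balance found")
    # deep overlap makes the axial force non-monotone (sites passing through
    # one another); the physical balance point is the outermost root, so walk
    # inward from the stretched side until the force turns repulsive
    step = max(0.01 * template.size, 1e-3)
    d_hi = hi
    d_lo = hi - step
    while d_lo > lo and net_force_on_upper(d_lo) < 0:
        d_hi = d_lo
        d_lo -= step
    d_lo = max(d_lo, lo)
    return float(brentq(net_force_on_upper, d_lo, d_hi, xtol=1e-12))


def build_filament(
    shape: str,
    crosslink: str,
    L: int,
    alpha: float,
    magnetic_kind: str = "none",
    mu_max: Optional[float] = None,
    direction: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> FilamentSystem:
    """Straight initial chain of L monomers along a (random) direction.

    CTC: one centre-centre bond per junction.  FTF spheres: 8 index-paired
    crown bonds per junction.  FTF cubes: 4 corner + 4 edge-midpoint bonds
    between facing faces.  r0 = alpha * sigma with sigma the monomer size;
    FM dipoles are initialized along the backbone.
    """
    if not (L_RANGE[0] <= L <= L_RANGE[1]):
        raise ValueError(f"L must lie in {L_RANGE}")
    if not any(abs(alpha - a) < 1e-12 for a in ALPHA_VALUES):
        raise ValueError(f"alpha must be one of {ALPHA_VALUES}")
    crosslink = crosslink.upper()
    pars = parameter_table(shape, crosslink)
    sigma = pars["sigma"]
    if mu_max is None:
        mu_max = np.sqrt(3.0) if magnetic_kind != "none" else 0.0

    if shape == "sphere":
        template = build_sphere_monomer(sigma, crosslink, magnetic_kind, mu_max)
    else:
        template = build_cube_monomer(sigma, magnetic_kind, mu_max)

    r0 = alpha * sigma
    r_f = R_F_FACTOR * r0
    k_f = pars["K_f"]

    # junction bond pattern
    if crosslink == "CTC":
        pairs = [(0, 0)]
    elif shape == "sphere":
        pairs = _crown_pairs()
    else:
        pairs = _cube_face_pairs(template)

    # straight-chain centre spacing at nearest-neighbour force balance: for
    # short bonds the FENE equilibrium length would bury the steric cores in
    # each other (the WCA force at r0 = 0.6 sigma is astronomically large),
    # so the physically stretched straight state has the bonds under tension
    # against the steric repulsion
    spacing = _straight_spacing(template, pairs, k_f, r0, r_f)

    bonds = [
        BondSpec(i, si, i + 1, sj, k_f, r0, r_f)
        for i in range(L - 1)
        for si, sj in pairs
    ]

    if direction is None:
        rng = rng or np.random.default_rng()
        direction = random_unit_vector(rng)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    positions = np.outer(np.arange(L), spacing * direction)
    q0 = quat_align_z(direction)
    orientations = np.tile(q0, (L, 1))
    mu = np.zeros((L, 3))
    if magnetic_kind == "FM":
        mu = np.tile(mu_max * direction, (L, 1))

    return FilamentSystem(
        template=template,
        positions=positions,
        orientations=orientations,
        velocities=np.zeros((L, 3)),
        angular_velocities=np.zeros((L, 3)),
        mu=mu,
        bonds=bonds,
        crosslink=crosslink,
        alpha=alpha,
        spacing=spacing,
    )


def graft_to_slit(system: FilamentSystem,
                  separation: Optional[float] = None) -> FilamentSystem:
    """Freeze the chain ends on two slit walls, chain stretched along +z.

    The chain is repositioned fully straight along +z with all bonds at
    their construction spacing; the first monomer is frozen at the bottom
    wall, the last at the top.  The external field (if any) points along +z;
    compression moves the top wall along -z.
    """
    if system.crosslink != "FTF":
        raise ValueError("slit grafting is defined for FTF filaments")
    L = system.n_monomers
    sigma = system.template.size
    extent = (L - 1) * system.spacing + sigma  # wall-to-wall straight extent
    if separation is None:
        separation = extent
    if separation < extent - 1e-9:
        raise ValueError(
            f"slit separation {separation} shorter than the stretched chain {extent}")

    out = system.copy()
    # end monomers sit on the wall surfaces; a wider slit stretches the chain
    spacing_eff = (separation - sigma) / (L - 1)
    if (spacing_eff - system.spacing) >= R_F_FACTOR * system.bonds[0].r0 - 1e-9:
        raise ValueError("slit separation would overstretch the bonds")
    z0 = sigma / 2
    out.positions = np.outer(np.arange(L), np.array([0.0, 0.0, spacing_eff]))
    out.positions[:, 2] += z0
    q0 = quat_align_z(np.array([0.0, 0.0, 1.0]))
    out.orientations = np.tile(q0, (L, 1))
    out.velocities[:] = 0.0
    out.angular_velocities[:] = 0.0
    if system.template.magnetic_kind == "FM":
        out.mu = np.tile(system.template.mu_max * np.array([0.0, 0.0, 1.0]), (L, 1))
    out.walls = SlitWalls(z_bottom=0.0, z_top=separation)
    out.grafted = {0, L - 1}
    return out


def bond_table(system: FilamentSystem) -> pd.DataFrame:
    """Human-readable topology dump."""
    return pd.DataFrame(
        [
            {
                "monomer_i": b.monomer_i,
                "site_i": b.site_i,
                "monomer_j": b.monomer_j,
                "site_j": b.site_j,
                "K_f": b.K_f,
                "r0": b.r0,
                "r_f": b.r_f,
            }
            for b in system.bonds
        ]
    )
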