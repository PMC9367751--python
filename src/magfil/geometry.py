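"""Rigid monomer blueprints and body-frame transforms.

Monomers are rigid raspberry bodies: one real central particle plus virtual
sites fixed in its body frame.  Spherical monomers are a single WCA sphere,
optionally decorated with two crowns of bond-anchor sites for face-to-face
(FTF) crosslinking.  Cubic monomers (DNA-nanochamber stand-ins) are q=2
superball raspberries: a central sphere, 8 corner sites along the <111> body
diagonals and 12 edge-midpoint sites along <110>, all centred on the
superball surface.

Quaternions are scalar-first, unit-norm, and encode active right-handed
rotations from body frame to lab frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "SiteSpec",
    "MonomerTemplate",
    "BodyFrame",
    "superball_implicit",
    "build_sphere_monomer",
    "build_cube_monomer",
    "site_lab_positions",
    "inertia_from_sites",
    "template_table",
    "quat_multiply",
    "quat_rotate",
    "quat_to_matrix",
    "quat_from_axis_angle",
    "quat_align_z",
    "random_unit_vector",
]

QUAT_NORM_TOL = 1e-9

Role = Literal["steric", "anchor", "steric+anchor"]
MagneticKind = Literal["none", "FM", "SPM"]


# ---------------------------------------------------------------------------
# quaternion algebra (scalar-first convention)
# ---------------------------------------------------------------------------

def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b, scalar-first."""
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of the active rotation encoded by unit quaternion q."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v (shape (3,) or (n,3)) by unit quaternion q."""
    return np.asarray(v) @ quat_to_matrix(q).T


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_align_z(direction: np.ndarray) -> np.ndarray:
    """Quaternion rotating the body +z axis onto ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, d))
    if c > 1 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if c < -1 + 1e-12:
        # 180 deg about x
        return np.array([0.0, 1.0, 0.0, 0.0])
    axis = np.cross(z, d)
    return quat_from_axis_angle(axis, np.arccos(c))


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere."""
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SiteSpec:
    """One raspberry site: a body-frame position with steric/anchor roles.

    ``diameter`` and ``epsilon`` parameterize the WCA repulsion carried by the
    site; anchor-only sites carry no steric interaction (diameter/epsilon are
    ignored for them and stored as 0).
    """

    body_position: np.ndarray
    diameter: float
    epsilon: float
    role: Role
    site_id: int

    def __post_init__(self) -> None:
        self.body_position = np.asarray(self.body_position, dtype=float)
        if not np.all(np.isfinite(self.body_position)):
            raise ValueError("site position must be finite")
        if "steric" in self.role and self.diameter <= 0:
            raise ValueError("steric sites need diameter > 0")

    @property
    def is_steric(self) -> bool:
        return "steric" in self.role

    @property
    def is_anchor(self) -> bool:
        return "anchor" in self.role


@dataclass
class MonomerTemplate:
    """Rigid-body blueprint shared by every monomer of a filament.

    Site 0 is the real central particle at the body origin; all other sites
    are virtual and rigidly attached.  Total mass is 1 in reduced units.
    """

    shape: Literal["sphere", "cube"]
    sites: list[SiteSpec]
    mass: float = 1.0
    magnetic_kind: MagneticKind = "none"
    mu_max: float = 0.0
    inertia: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        if np.linalg.norm(self.sites[0].body_position) > 1e-12:
            raise ValueError("site 0 must sit at the body origin")
        if self.magnetic_kind != "none" and self.mu_max <= 0:
            raise ValueError("magnetic template needs mu_max > 0")
        if self.inertia is None:
            self.inertia = inertia_from_sites(self)
        self.inertia = np.asarray(self.inertia, dtype=float)
        if not np.allclose(self.inertia, self.inertia.T):
            raise ValueError("inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ValueError("inertia must be positive definite")

    # -- convenience array views -------------------------------------------
    def body_positions(self) -> np.ndarray:
        return np.array([s.body_position for s in self.sites])

    def steric_mask(self) -> np.ndarray:
        return np.array([s.is_steric for s in self.sites])

    def anchor_mask(self) -> np.ndarray:
        return np.array([s.is_anchor for s in self.sites])

    def diameters(self) -> np.ndarray:
        return np.array([s.diameter for s in self.sites])

    def epsilons(self) -> np.ndarray:
        return np.array([s.epsilon for s in self.sites])

    @property
    def size(self) -> float:
        """Characteristic monomer size sigma (central-site diameter)."""
        return self.sites[0].diameter


@dataclass
class BodyFrame:
    """Lab-frame placement of a rigid body: position + unit quaternion."""

    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(self.orientation) - 1.0) > QUAT_NORM_TOL:
            raise ValueError("orientation quaternion must be unit norm")


# ---------------------------------------------------------------------------
# superball geometry
# ---------------------------------------------------------------------------

def superball_implicit(point, r: float, q: float):
    """Implicit superball function |x|^2q + |y|^2q + |z|^2q - r^2q.

    Zero on the surface, negative inside.  q=1 is the sphere of radius r;
    q -> inf approaches the cube of half-extent r.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if q < 1:
        raise ValueError("q must be >= 1")
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    e = 2.0 * q
    return np.sum(np.abs(p) ** e, axis=-1) - r**e


def _superball_radius_along(direction: np.ndarray, r: float, q: float) -> float:
    """Distance from the origin to the q-superball surface along ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    e = 2.0 * q
    return r / np.sum(np.abs(d) ** e) ** (1.0 / e)


# ---------------------------------------------------------------------------
# template builders
# ---------------------------------------------------------------------------

#: printed steric parameters of the cube raspberry (reduced units)
CUBE_CORNER_SIGMA = 0.41
CUBE_EDGE_SIGMA = 0.49
CUBE_EPSILON = 1.0
SPHERE_EPSILON = 100.0
CROWN_SITES = 8


def build_sphere_monomer(
    sigma: float,
    crosslink: str = "CTC",
    magnetic_kind: MagneticKind = "none",
    mu_max: float = 0.0,
) -> MonomerTemplate:
    """Spherical monomer: one WCA sphere, plus two 8-site anchor crowns for FTF.

    The crowns are the intersections of the sphere surface with planes at
    body-z offsets +-sigma/4; each carries 8 equidistant anchor-only sites,
    so the crown circle radius is sqrt((sigma/2)^2 - (sigma/4)^2).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    crosslink = crosslink.upper()
    if crosslink not in ("CTC", "FTF"):
        raise ValueError(f"unknown crosslink mode {crosslink!r}")
    sites = [SiteSpec(np.zeros(3), sigma, SPHERE_EPSILON, "steric", 0)]
    if crosslink == "FTF":
        rho = np.sqrt((sigma / 2) ** 2 - (sigma / 4) ** 2)
        sid = 1
        for zoff in (+sigma / 4, -sigma / 4):
            for k in range(CROWN_SITES):
                phi = 2 * np.pi * k / CROWN_SITES
                pos = np.array([rho * np.cos(phi), rho * np.sin(phi), zoff])
                sites.append(SiteSpec(pos, 0.0, 0.0, "anchor", sid))
                sid += 1
    return MonomerTemplate(
        shape="sphere", sites=sites, magnetic_kind=magnetic_kind, mu_max=mu_max
    )


def build_cube_monomer(
    sigma_central: float = 1.0,
    magnetic_kind: MagneticKind = "none",
    mu_max: float = 0.0,
) -> MonomerTemplate:
    """q=2 superball raspberry cube of half-extent sigma_central/2.

    8 corner sites (sigma=0.41) sit on the superball surface along the <111>
    body diagonals; 12 edge-midpoint sites (sigma=0.49) along <110>.  Shell
    sites are both steric and bond anchors; FTF junctions bond the 4 corners
    and 4 edge midpoints of facing faces.
    """
    if sigma_central <= 0:
        raise ValueError("sigma_central must be positive")
    r = sigma_central / 2
    sites = [SiteSpec(np.zeros(3), sigma_central, CUBE_EPSILON, "steric", 0)]
    sid = 1
    # corners: <111> directions
    t = _superball_radius_along(np.ones(3), r, q=2) / np.sqrt(3.0)
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                pos = t * np.array([sx, sy, sz], dtype=float)
                sites.append(
                    SiteSpec(pos, CUBE_CORNER_SIGMA, CUBE_EPSILON, "steric+anchor", sid)
                )
                sid += 1
    # edge midpoints: <110> directions
    c = _superball_radius_along(np.array([1.0, 1.0, 0.0]), r, q=2) / np.sqrt(2.0)
    edge_dirs = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for si in (-1, 1):
            for sj in (-1, 1):
                d = np.zeros(3)
                d[i], d[j] = si, sj
                edge_dirs.append(d)
    for d in edge_dirs:
        sites.append(
            SiteSpec(c * d, CUBE_EDGE_SIGMA, CUBE_EPSILON, "steric+anchor", sid)
        )
        sid += 1
    return MonomerTemplate(
        shape="cube", sites=sites, magnetic_kind=magnetic_kind, mu_max=mu_max
    )


# ---------------------------------------------------------------------------
# transforms & inertia
# ---------------------------------------------------------------------------

def site_lab_positions(template: MonomerTemplate, frame: BodyFrame) -> np.ndarray:
    """Lab-frame positions of all sites: rotate by the quaternion, translate."""
    q = frame.orientation
    if abs(np.linalg.norm(q) - 1.0) > QUAT_NORM_TOL:
        raise ValueError("quaternion not unit norm")
    return quat_rotate(q, template.body_positions()) + frame.position


def inertia_from_sites(template: MonomerTemplate) -> np.ndarray:
    """Body-frame inertia tensor with the total mass spread equally over sites.

    A bare sphere (single site at the origin) has no site-based inertia; it
    gets the solid-sphere tensor (1/10) m sigma^2 * identity instead, which is
    immaterial for equilibrium statics but keeps rotational dynamics defined.
    """
    pos = template.body_positions()
    m_site = template.mass / len(pos)
    eye = np.eye(3)
    inertia = np.zeros((3, 3))
    for p in pos:
        inertia += m_site * (np.dot(p, p) * eye - np.outer(p, p))
    if np.any(np.linalg.eigvalsh(inertia) < 1e-12):
        sigma = template.sites[0].diameter
        inertia = 0.1 * template.mass * sigma**2 * eye
    return inertia


def template_table(template: MonomerTemplate):
    """Site table (id, role, x, y, z, sigma, epsilon) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "site_id": s.site_id,
            "role": s.role,
            "x": s.body_position[0],
            "y": s.body_position[1],
            "z": s.body_position[2],
            "sigma": s.diameter,
            "epsilon": s.epsilon,
        }
        for s in template.sites
    ]
    return pd.DataFrame(rows)
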