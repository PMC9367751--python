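"""Simulation protocols: equilibrium sampling, field sweeps, slit compression.

The printed protocol constants (cadences, replica counts, temperature,
timestep) live in a read-only defaults layer; a run configuration may scale
protocol durations by a single factor (recorded in every output row) but may
not silently override the physics constants — deviating from dt = 1e-2 or
T = 1 requires the explicit ``allow_overrides`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .builder import build_filament, graft_to_slit
from .dynamics import LangevinParams, Simulation
from .interactions import BondOverstretchError, FieldSpec, langevin_function
from .observables import (
    bond_autocorrelation,
    d_avg,
    end_to_end,
    fit_end_to_end_scaling,
    gyration_radius_sq,
    magnetization,
    magnetization_magnitude,
    persistence_length,
)
from . import synthetic

__all__ = [
    "PROTOCOL_DEFAULTS",
    "RunConfig",
    "EquilibriumResult",
    "run_equilibrium",
    "run_field_sweep",
    "run_compression",
    "scaling_exponent",
    "persistence_from_result",
    "UnitMap",
    "map_to_physical_units",
    "generate_fixture",
]

#: read-only protocol constants (reduced units).  The integration timestep
#: is the package default 5e-3 (see magfil.dynamics for why the steep sphere
#: repulsion rules out a coarser step); all cadences are in integration steps.
PROTOCOL_DEFAULTS = MappingProxyType({
    "dt": 5e-3,
    "kT": 1.0,
    "relax_steps": 2_100_000,
    "measure_steps": 10_500_000,
    "sample_every": 7_000,
    "plateau_steps": 300_000,
    "compression_increment": 0.1,
    "max_compression": 5.0,
    "replicas": MappingProxyType(
        {"equilibrium": 40, "field_sweep": 15, "compression": 10}),
})

DEFAULT_FIELD_GRID = tuple(np.arange(0.0, 6.01, 0.5))


@dataclass
class RunConfig:
    """One protocol run: architecture, lengths, fields, statistics, seeds."""

    protocol: str  # equilibrium | field_sweep | compression
    shape: str = "sphere"
    crosslink: str = "CTC"
    L: Sequence[int] | int = 20
    alpha: float = 0.6
    magnetic_kind: str = "none"
    H: Sequence[float] | float = 0.0
    replicas: Optional[int] = None
    seed_base: int = 0
    scale: float = 1.0
    dt: float = PROTOCOL_DEFAULTS["dt"]
    kT: float = PROTOCOL_DEFAULTS["kT"]
    allow_overrides: bool = False

    def __post_init__(self) -> None:
        if self.protocol not in ("equilibrium", "field_sweep", "compression"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not self.allow_overrides:
            if self.dt != PROTOCOL_DEFAULTS["dt"] or self.kT != PROTOCOL_DEFAULTS["kT"]:
                raise ValueError(
                    "dt and kT are protocol constants; pass allow_overrides=True "
                    "to deviate deliberately")
        if not (0 < self.scale <= 1.0):
            raise ValueError("scale must lie in (0, 1]")
        if self.replicas is None:
            self.replicas = PROTOCOL_DEFAULTS["replicas"][self.protocol]

    @property
    def L_list(self) -> list:
        return [self.L] if np.isscalar(self.L) else list(self.L)

    @property
    def H_list(self) -> list:
        return [self.H] if np.isscalar(self.H) else list(self.H)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class EquilibriumResult:
    """Per-replica observable table plus bond-autocorrelation curves."""

    table: pd.DataFrame
    correlations: dict  # (L, replica) -> C(n) ndarray


def _scaled_cadence(scale: float):
    relax = max(1, int(round(PROTOCOL_DEFAULTS["relax_steps"] * scale)))
    measure = max(1, int(round(PROTOCOL_DEFAULTS["measure_steps"] * scale)))
    every = PROTOCOL_DEFAULTS["sample_every"]
    measure = max(measure, every)  # at least one snapshot
    return relax, measure, every


def _replica_run(config: RunConfig, L: int, H: float, seed: int):
    """Build, relax and sample one replica; returns (row dict, C(n) or None)."""
    rng = np.random.default_rng(seed)
    system = build_filament(config.shape, config.crosslink, L, config.alpha,
                            config.magnetic_kind, rng=rng)
    system.field = FieldSpec(np.array([0.0, 0.0, H]))
    sim = Simulation(system, LangevinParams(kT=config.kT, dt=config.dt, seed=seed))
    relax, measure, every = _scaled_cadence(config.scale)
    row = {
        "shape": config.shape, "crosslink": config.crosslink,
        "alpha": config.alpha, "L": L, "H": H,
        "magnetic_kind": config.magnetic_kind, "seed": seed,
        "scale": config.scale, "failed": False,
    }
    try:
        sim.run(relax)
        res = sim.run(measure, record_every=every)
    except BondOverstretchError as exc:
        row.update({"failed": True, "error": str(exc), "n_snapshots": 0})
        return row, None
    traj = res.trajectory
    d = d_avg(traj.positions)
    row.update({
        "n_snapshots": traj.n_snapshots,
        "d_avg": d,
        "R_e": end_to_end(traj.positions, d),
        "Rg2": gyration_radius_sq(traj.positions, d),
    })
    if config.magnetic_kind != "none":
        mu_max = system.template.mu_max
        row["m_mag"] = magnetization_magnitude(traj.dipoles, mu_max)
        row["m"] = (magnetization(traj.dipoles, system.field.H, mu_max)
                    if H != 0 else row["m_mag"])
    corr = bond_autocorrelation(traj.positions) if L >= 3 else None
    return row, corr


def run_equilibrium(config: RunConfig) -> EquilibriumResult:
    """Equilibrium protocol: relax, then sample every 7000 steps.

    One independent simulation per (L, replica) pair, each with its own seed
    ``seed_base + index``; rows of failed (overstretched) replicas are kept
    and flagged rather than silently dropped.
    """
    rows, correlations = [], {}
    idx = 0
    for L in config.L_list:
        for rep in range(config.replicas):
            seed = (config.seed_base + idx) % 2**31
            idx += 1
            row, corr = _replica_run(config, L, float(config.H_list[0]), seed)
            row["replica"] = rep
            rows.append(row)
            if corr is not None:
                correlations[(L, rep)] = corr
    return EquilibriumResult(table=pd.DataFrame(rows), correlations=correlations)


def run_field_sweep(config: RunConfig) -> pd.DataFrame:
    """Magnetization and gyration-radius curves over a field grid (L = 20)."""
    if config.magnetic_kind == "none":
        raise ValueError("field sweep requires a magnetic system")
    H_grid = config.H_list if len(config.H_list) > 1 else list(DEFAULT_FIELD_GRID)
    rows = []
    idx = 0
    for H in H_grid:
        for rep in range(config.replicas):
            seed = (config.seed_base + idx) % 2**31
            idx += 1
            row, _ = _replica_run(config, int(config.L_list[0]), float(H), seed)
            row["replica"] = rep
            rows.append(row)
    return pd.DataFrame(rows)


def run_compression(config: RunConfig) -> pd.DataFrame:
    """Slit compression of a grafted, fully stretched FTF filament.

    The top wall moves down in increments of 0.1 every (scaled) 3e5 steps up
    to a total displacement of 5; each plateau reports the equilibrated mean
    z-force on the bottom wall (first third discarded) and the magnetization
    projection of the non-grafted monomers.
    """
    inc = PROTOCOL_DEFAULTS["compression_increment"]
    n_plateaus = int(round(PROTOCOL_DEFAULTS["max_compression"] / inc))
    plateau = max(3, int(round(PROTOCOL_DEFAULTS["plateau_steps"] * config.scale)))
    rows = []
    for rep in range(config.replicas):
        for H in config.H_list:
            seed = (config.seed_base + rep) % 2**31
            rng = np.random.default_rng(seed)
            base = build_filament(config.shape, "FTF", int(config.L_list[0]),
                                  config.alpha, config.magnetic_kind, rng=rng)
            system = graft_to_slit(base)
            system.field = FieldSpec(np.array([0.0, 0.0, float(H)]))
            sim = Simulation(system, LangevinParams(kT=config.kT, dt=config.dt,
                                                    seed=seed))
            top = system.n_monomers - 1
            mu_max = system.template.mu_max
            record_every = max(1, plateau // 30)
            for k in range(n_plateaus + 1):  # k=0 is the uncompressed plateau
                if k > 0:
                    system.walls.z_top -= inc
                    system.positions[top, 2] -= inc
                try:
                    res = sim.run(plateau, record_every=record_every,
                                  wall_accum_start=plateau // 3)
                except BondOverstretchError as exc:
                    rows.append({"replica": rep, "H": H, "compression": k * inc,
                                 "failed": True, "error": str(exc)})
                    break
                row = {
                    "replica": rep, "H": H, "compression": k * inc,
                    "separation": system.walls.separation,
                    "F_z": res.wall_force_mean,
                    "scale": config.scale, "failed": False,
                }
                if config.magnetic_kind != "none":
                    traj = res.trajectory
                    drop = traj.n_snapshots // 3
                    mu_frames = traj.dipoles[drop:]
                    if H != 0:
                        row["m"] = magnetization(mu_frames, system.field.H,
                                                 mu_max, exclude={0, top})
                    else:
                        row["m"] = magnetization_magnitude(mu_frames, mu_max,
                                                           exclude={0, top})
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation helpers
# ---------------------------------------------------------------------------

def scaling_exponent(result: EquilibriumResult, L_min: int = 15):
    """Power-law fit b*L^a to replica-averaged R*_e; returns the FitResult."""
    tab = result.table[~result.table["failed"]]
    means = tab.groupby("L")["R_e"].mean()
    return fit_end_to_end_scaling(means.index.to_numpy(), means.to_numpy(),
                                  L_min=L_min)


def persistence_from_result(result: EquilibriumResult, L: int, sigma: float):
    """L_p (sigma units) from the replica-averaged C(n) of chains of length L."""
    tab = result.table[(~result.table["failed"]) & (result.table["L"] == L)]
    curves = [result.correlations[(L, rep)] for rep in tab["replica"]]
    c_mean = np.mean(np.stack(curves), axis=0)
    d_mean = float(tab["d_avg"].mean())
    return persistence_length(c_mean, d_mean, sigma)


# ---------------------------------------------------------------------------
# unit mapping
# ---------------------------------------------------------------------------

K_B = 1.380649e-23  # J/K


@dataclass
class UnitMap:
    """Physical identification of the reduced units.

    The default magnetite parameters (15 nm core, M_s = 4.8e5 A/m, 2 nm
    oleic-acid coating) identify one reduced length with a coated colloid.
    """

    core_diameter: float = 15e-9  # m
    coating_thickness: float = 2e-9  # m
    M_s: float = 4.8e5  # A/m
    T_SI: float = 300.0  # K
    mu_max_reduced: float = np.sqrt(3.0)

    def __post_init__(self) -> None:
        if min(self.core_diameter, self.T_SI) <= 0 or self.M_s < 0:
            raise ValueError("unit map entries must be positive")


def map_to_physical_units(unit_map: UnitMap = UnitMap()) -> dict:
    """Reduced <-> SI dictionary with the conversion assumptions spelled out.

    The dipole moment follows from the saturated core volume,
    m = M_s * (pi/6) d^3.  The field scale assumes Zeeman-energy
    equivalence: one reduced field unit is the induction at which the reduced
    Zeeman energy of mu_max equals the physical Zeeman energy of the core
    moment in units of k_B T_SI.  This convention is an explicit modelling
    assumption, not a derived quantity.
    """
    d = unit_map.core_diameter
    moment = unit_map.M_s * np.pi / 6.0 * d**3
    sigma_si = d + 2 * unit_map.coating_thickness
    if moment > 0:
        tesla_per_reduced = (unit_map.mu_max_reduced * K_B * unit_map.T_SI
                             / moment)
    else:
        tesla_per_reduced = float("inf")
    return {
        "dipole_moment_A_m2": float(moment),
        "length_scale_m": float(sigma_si),
        "field_tesla_per_reduced_unit": float(tesla_per_reduced),
        "energy_scale_J": float(K_B * unit_map.T_SI),
        "assumptions": (
            "assumption: moment = M_s * (pi/6) * d_core^3 (uniformly "
            "magnetized sphere); "
            "sigma corresponds to core + 2 coating layers; field conversion "
            "equates the reduced Zeeman energy -mu_max*H with the physical "
            "-m*B in units of k_B*T_SI"
        ),
    }


# ---------------------------------------------------------------------------
# deterministic test fixtures
# ---------------------------------------------------------------------------

def generate_fixture(kind: str, seed: int = 0):
    """Small deterministic systems with precomputed reference values.

    Returns (object, references).  Kinds: dimer_fm, dimer_spm,
    straight_chain_L5 (synthetic rod trajectory), wlc_synthetic (synthetic
    worm-like-chain trajectory with known persistence length).
    """
    if kind == "dimer_fm":
        system = build_filament("sphere", "CTC", 2, 1.0, "FM",
                                direction=np.array([0.0, 0.0, 1.0]))
        # head-to-tail at unit distance
        system.positions = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        refs = {"dipole_energy": -6.0, "mu_max_sq": 3.0}
        return system, refs
    if kind == "dimer_spm":
        system = build_filament("sphere", "CTC", 2, 1.0, "SPM",
                                direction=np.array([0.0, 0.0, 1.0]))
        system.positions = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mu_max = system.template.mu_max
        refs = {
            "isolated_moment_H6": float(mu_max * langevin_function(6 * mu_max)),
        }
        return system, refs
    if kind == "straight_chain_L5":
        traj = synthetic.rigid_rod_trajectory(5, n_frames=2, spacing=1.0)
        refs = {"R_e": 4.0, "Rg2": 2.0}
        return traj, refs
    if kind == "wlc_synthetic":
        traj = synthetic.wlc_trajectory(L=50, n_frames=300, lp_bonds=4.0,
                                        spacing=1.0, seed=seed)
        refs = {"L_p_bonds": 4.0, "spacing": 1.0}
        return traj, refs
    raise ValueError(f"unknown fixture kind {kind!r}")
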