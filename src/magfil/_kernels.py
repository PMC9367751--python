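"""Compiled inner loops: force evaluation and the Langevin velocity-Verlet step.

All monomers of a filament share one rigid template, so the system is stored
as flat arrays (positions, quaternions, velocities, body-frame angular
velocities, dipole moments) plus template-level site tables.  The Python
layer in :mod:`magfil.dynamics` owns flattening and validation; everything
here assumes well-formed float64/int64 inputs.

Integration scheme: velocity Verlet where friction ``-Gamma v`` and bounded
white noise with per-component variance ``2 Gamma k_BT / dt`` are added to
the conservative force once per force evaluation (one evaluation per step),
the standard Langevin-thermostat discretization in rigid-body MD codes.
Uniform bounded noise (instead of Gaussian draws) is the classic speed
trick for Langevin thermostats: the sampled distribution only depends on
the first two noise moments to the order of the integrator.
Quaternions are propagated by the exact exponential of the body-frame
angular velocity over one step and renormalized.

Status codes returned by the integrator: 0 ok, 1 FENE bond overstretched,
2 non-finite state encountered.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_NONFINITE = 2

_NL_SKIN = 0.4  # Verlet-list skin (reduced length)

_SM64_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM64_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM64_M2 = np.uint64(0x94D049BB133111EB)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, fastmath=True, inline="always")
def _rand_sym(state):
    """splitmix64 draw mapped to [-1, 1); state is a 1-element uint64 array."""
    state[0] += _SM64_GAMMA
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * _SM64_M1
    z = (z ^ (z >> np.uint64(27))) * _SM64_M2
    z = z ^ (z >> np.uint64(31))
    return 2.0 * ((z >> np.uint64(11)) * _INV_2_53) - 1.0


@njit(cache=True, fastmath=True)
def _rotmat_from_quat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True, fastmath=True)
def _langevin(a):
    if abs(a) < 1e-4:
        return a / 3.0 - a * a * a / 45.0
    return 1.0 / np.tanh(a) - 1.0 / a


@njit(cache=True, fastmath=True)
def _rebuild_nlist(pos, verlet_cut2, pairs, pos_ref):
    n = pos.shape[0]
    np_pairs = 0
    for i in range(n - 1):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < verlet_cut2:
                pairs[np_pairs, 0] = i
                pairs[np_pairs, 1] = j
                np_pairs += 1
    for i in range(n):
        pos_ref[i, 0] = pos[i, 0]
        pos_ref[i, 1] = pos[i, 1]
        pos_ref[i, 2] = pos[i, 2]
    return np_pairs


@njit(cache=True, fastmath=True)
def _eval_forces(
    pos, quat, vel, omg, mu,
    # template
    site_body, ster_sites, wca_sig2, wca_eps, wca_rc2, prune_cut2,
    bond_i, bond_si, bond_j, bond_sj, K_f, r0, r_f,
    mag_kind, mu_max, fm_axis,
    H, wall_on, z_bot, z_top, wall_sig, grafted,
    inertia, kT, gamma_t, gamma_r, dt, integrate_rotation,
    # neighbour list state
    pairs, npairs, pos_ref, verlet_cut2,
    # work / output arrays
    R, labS, F, Tb, Bf, rng_state,
    add_thermostat, needs_frames, bonds_central,
):
    """Conservative forces/torques (+ optional thermostat terms) in place.

    Returns (status, f_bot_z): f_bot_z is the z-force the filament exerts on
    the bottom-wall assembly (wall plane + grafted bottom monomer).
    """
    n = pos.shape[0]
    ns = ster_sites.shape[0]
    nb = bond_i.shape[0]

    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
        Tb[i, 0] = 0.0
        Tb[i, 1] = 0.0
        Tb[i, 2] = 0.0

    # lab positions of steric sites (bare spheres: the centre itself)
    if needs_frames:
        for i in range(n):
            _rotmat_from_quat(quat[i], R[i])
            for a in range(ns):
                s = ster_sites[a]
                bx, by, bz = site_body[s, 0], site_body[s, 1], site_body[s, 2]
                labS[i, a, 0] = pos[i, 0] + R[i, 0, 0] * bx + R[i, 0, 1] * by + R[i, 0, 2] * bz
                labS[i, a, 1] = pos[i, 1] + R[i, 1, 0] * bx + R[i, 1, 1] * by + R[i, 1, 2] * bz
                labS[i, a, 2] = pos[i, 2] + R[i, 2, 0] * bx + R[i, 2, 1] * by + R[i, 2, 2] * bz
    else:
        for i in range(n):
            for a in range(ns):
                labS[i, a, 0] = pos[i, 0]
                labS[i, a, 1] = pos[i, 1]
                labS[i, a, 2] = pos[i, 2]

    # Tb temporarily holds LAB-frame torques; converted to body frame at the end.

    # --- neighbour-list maintenance -------------------------------------
    half_skin2 = (_NL_SKIN * 0.5) ** 2
    need = False
    for i in range(n):
        dx = pos[i, 0] - pos_ref[i, 0]
        dy = pos[i, 1] - pos_ref[i, 1]
        dz = pos[i, 2] - pos_ref[i, 2]
        if dx * dx + dy * dy + dz * dz > half_skin2:
            need = True
            break
    if need or npairs[0] < 0:
        npairs[0] = _rebuild_nlist(pos, verlet_cut2, pairs, pos_ref)

    # --- WCA between steric sites of different monomers -----------------
    for p in range(npairs[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dxc = pos[i, 0] - pos[j, 0]
        dyc = pos[i, 1] - pos[j, 1]
        dzc = pos[i, 2] - pos[j, 2]
        if dxc * dxc + dyc * dyc + dzc * dzc > prune_cut2:
            continue
        for a in range(ns):
            for b in range(ns):
                dx = labS[i, a, 0] - labS[j, b, 0]
                dy = labS[i, a, 1] - labS[j, b, 1]
                dz = labS[i, a, 2] - labS[j, b, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= wca_rc2[a, b] or r2 <= 0.0:
                    continue
                s2 = wca_sig2[a, b] / r2
                s6 = s2 * s2 * s2
                fpr = 24.0 * wca_eps[a, b] * (2.0 * s6 * s6 - s6) / r2
                fx = fpr * dx
                fy = fpr * dy
                fz = fpr * dz
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
                # torque about each core from off-centre contact
                ax = labS[i, a, 0] - pos[i, 0]
                ay = labS[i, a, 1] - pos[i, 1]
                az = labS[i, a, 2] - pos[i, 2]
                Tb[i, 0] += ay * fz - az * fy
                Tb[i, 1] += az * fx - ax * fz
                Tb[i, 2] += ax * fy - ay * fx
                bx = labS[j, b, 0] - pos[j, 0]
                by = labS[j, b, 1] - pos[j, 1]
                bz = labS[j, b, 2] - pos[j, 2]
                Tb[j, 0] -= by * fz - bz * fy
                Tb[j, 1] -= bz * fx - bx * fz
                Tb[j, 2] -= bx * fy - by * fx

    # --- FENE bonds (anchor sites) ---------------------------------------
    for b in range(nb):
        i = bond_i[b]
        j = bond_j[b]
        si = bond_si[b]
        sj = bond_sj[b]
        if bonds_central:
            pax, pay, paz = pos[i, 0], pos[i, 1], pos[i, 2]
            pbx, pby, pbz = pos[j, 0], pos[j, 1], pos[j, 2]
        else:
            bxi, byi, bzi = site_body[si, 0], site_body[si, 1], site_body[si, 2]
            pax = pos[i, 0] + R[i, 0, 0] * bxi + R[i, 0, 1] * byi + R[i, 0, 2] * bzi
            pay = pos[i, 1] + R[i, 1, 0] * bxi + R[i, 1, 1] * byi + R[i, 1, 2] * bzi
            paz = pos[i, 2] + R[i, 2, 0] * bxi + R[i, 2, 1] * byi + R[i, 2, 2] * bzi
            bxj, byj, bzj = site_body[sj, 0], site_body[sj, 1], site_body[sj, 2]
            pbx = pos[j, 0] + R[j, 0, 0] * bxj + R[j, 0, 1] * byj + R[j, 0, 2] * bzj
            pby = pos[j, 1] + R[j, 1, 0] * bxj + R[j, 1, 1] * byj + R[j, 1, 2] * bzj
            pbz = pos[j, 2] + R[j, 2, 0] * bxj + R[j, 2, 1] * byj + R[j, 2, 2] * bzj
        dx = pax - pbx
        dy = pay - pby
        dz = paz - pbz
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = (r - r0) / r_f
        if x * x >= 1.0:
            return STATUS_OVERSTRETCH, 0.0
        fpr = -K_f * (r - r0) / ((1.0 - x * x) * r)
        fx = fpr * dx
        fy = fpr * dy
        fz = fpr * dz
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz
        ax = pax - pos[i, 0]
        ay = pay - pos[i, 1]
        az = paz - pos[i, 2]
        Tb[i, 0] += ay * fz - az * fy
        Tb[i, 1] += az * fx - ax * fz
        Tb[i, 2] += ax * fy - ay * fx
        ax = pbx - pos[j, 0]
        ay = pby - pos[j, 1]
        az = pbz - pos[j, 2]
        Tb[j, 0] -= ay * fz - az * fy
        Tb[j, 1] -= az * fx - ax * fz
        Tb[j, 2] -= ax * fy - ay * fx

    # --- magnetic interactions -------------------------------------------
    if mag_kind == 1:
        # body-fixed FM moments follow the quaternion
        for i in range(n):
            mu[i, 0] = mu_max * (R[i, 0, 0] * fm_axis[0] + R[i, 0, 1] * fm_axis[1] + R[i, 0, 2] * fm_axis[2])
            mu[i, 1] = mu_max * (R[i, 1, 0] * fm_axis[0] + R[i, 1, 1] * fm_axis[1] + R[i, 1, 2] * fm_axis[2])
            mu[i, 2] = mu_max * (R[i, 2, 0] * fm_axis[0] + R[i, 2, 1] * fm_axis[1] + R[i, 2, 2] * fm_axis[2])
    elif mag_kind == 2:
        # one-pass SPM update: local fields from previous-step moments
        for i in range(n):
            Bf[i, 0] = H[0]
            Bf[i, 1] = H[1]
            Bf[i, 2] = H[2]
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = np.sqrt(r2)
                ir3 = 1.0 / (r2 * r)
                ir5 = ir3 / r2
                # field of j at i
                mjr = mu[j, 0] * dx + mu[j, 1] * dy + mu[j, 2] * dz
                Bf[i, 0] += (3.0 * mjr * dx * ir5 - mu[j, 0] * ir3)
                Bf[i, 1] += (3.0 * mjr * dy * ir5 - mu[j, 1] * ir3)
                Bf[i, 2] += (3.0 * mjr * dz * ir5 - mu[j, 2] * ir3)
                # field of i at j (displacement is -d)
                mir = -(mu[i, 0] * dx + mu[i, 1] * dy + mu[i, 2] * dz)
                Bf[j, 0] += (-3.0 * mir * dx * ir5 - mu[i, 0] * ir3)
                Bf[j, 1] += (-3.0 * mir * dy * ir5 - mu[i, 1] * ir3)
                Bf[j, 2] += (-3.0 * mir * dz * ir5 - mu[i, 2] * ir3)
        for i in range(n):
            bn = np.sqrt(Bf[i, 0] ** 2 + Bf[i, 1] ** 2 + Bf[i, 2] ** 2)
            if bn > 0.0:
                scale = mu_max * _langevin(mu_max * bn / kT) / bn
                mu[i, 0] = scale * Bf[i, 0]
                mu[i, 1] = scale * Bf[i, 1]
                mu[i, 2] = scale * Bf[i, 2]
            else:
                mu[i, 0] = 0.0
                mu[i, 1] = 0.0
                mu[i, 2] = 0.0

    if mag_kind > 0:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = np.sqrt(r2)
                ir2 = 1.0 / r2
                ir4 = ir2 * ir2
                mir = (mu[i, 0] * dx + mu[i, 1] * dy + mu[i, 2] * dz) / r
                mjr = (mu[j, 0] * dx + mu[j, 1] * dy + mu[j, 2] * dz) / r
                mimj = mu[i, 0] * mu[j, 0] + mu[i, 1] * mu[j, 1] + mu[i, 2] * mu[j, 2]
                c = 3.0 * ir4
                fx = c * (mimj * dx / r + mjr * mu[i, 0] + mir * mu[j, 0] - 5.0 * mir * mjr * dx / r)
                fy = c * (mimj * dy / r + mjr * mu[i, 1] + mir * mu[j, 1] - 5.0 * mir * mjr * dy / r)
                fz = c * (mimj * dz / r + mjr * mu[i, 2] + mir * mu[j, 2] - 5.0 * mir * mjr * dz / r)
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
                if mag_kind == 1:
                    ir3 = ir2 / r
                    # field of j at i, field of i at j
                    bix = (3.0 * mjr * dx / r - mu[j, 0]) * ir3
                    biy = (3.0 * mjr * dy / r - mu[j, 1]) * ir3
                    biz = (3.0 * mjr * dz / r - mu[j, 2]) * ir3
                    Tb[i, 0] += mu[i, 1] * biz - mu[i, 2] * biy
                    Tb[i, 1] += mu[i, 2] * bix - mu[i, 0] * biz
                    Tb[i, 2] += mu[i, 0] * biy - mu[i, 1] * bix
                    bjx = (3.0 * mir * dx / r - mu[i, 0]) * ir3
                    bjy = (3.0 * mir * dy / r - mu[i, 1]) * ir3
                    bjz = (3.0 * mir * dz / r - mu[i, 2]) * ir3
                    Tb[j, 0] += mu[j, 1] * bjz - mu[j, 2] * bjy
                    Tb[j, 1] += mu[j, 2] * bjx - mu[j, 0] * bjz
                    Tb[j, 2] += mu[j, 0] * bjy - mu[j, 1] * bjx
        if mag_kind == 1:
            for i in range(n):
                Tb[i, 0] += mu[i, 1] * H[2] - mu[i, 2] * H[1]
                Tb[i, 1] += mu[i, 2] * H[0] - mu[i, 0] * H[2]
                Tb[i, 2] += mu[i, 0] * H[1] - mu[i, 1] * H[0]

    # --- slit walls --------------------------------------------------------
    f_bot = 0.0
    if wall_on:
        for i in range(n):
            if grafted[i]:
                continue
            for a in range(ns):
                sig = wall_sig[a]
                rc = 1.122462048309373 * sig
                # bottom wall (normal +z)
                dzb = labS[i, a, 2] - z_bot
                if 0.0 < dzb < rc:
                    s2 = (sig / dzb) ** 2
                    s6 = s2 * s2 * s2
                    fz = 24.0 * (2.0 * s6 * s6 - s6) / dzb
                    F[i, 2] += fz
                    ax = labS[i, a, 0] - pos[i, 0]
                    ay = labS[i, a, 1] - pos[i, 1]
                    Tb[i, 0] += ay * fz
                    Tb[i, 1] += -ax * fz
                    f_bot -= fz  # reaction on the wall plane
                # top wall (normal -z)
                dzt = z_top - labS[i, a, 2]
                if 0.0 < dzt < rc:
                    s2 = (sig / dzt) ** 2
                    s6 = s2 * s2 * s2
                    fz = -24.0 * (2.0 * s6 * s6 - s6) / dzt
                    F[i, 2] += fz
                    ax = labS[i, a, 0] - pos[i, 0]
                    ay = labS[i, a, 1] - pos[i, 1]
                    Tb[i, 0] += ay * fz
                    Tb[i, 1] += -ax * fz
        # pull transmitted through the grafted bottom monomer
        f_bot += F[0, 2]

    # --- lab->body torque conversion + gyroscopic term ---------------------
    if integrate_rotation and needs_frames:
        for i in range(n):
            tx, ty, tz = Tb[i, 0], Tb[i, 1], Tb[i, 2]
            t0 = R[i, 0, 0] * tx + R[i, 1, 0] * ty + R[i, 2, 0] * tz
            t1 = R[i, 0, 1] * tx + R[i, 1, 1] * ty + R[i, 2, 1] * tz
            t2 = R[i, 0, 2] * tx + R[i, 1, 2] * ty + R[i, 2, 2] * tz
            t0 -= omg[i, 1] * inertia[2] * omg[i, 2] - omg[i, 2] * inertia[1] * omg[i, 1]
            t1 -= omg[i, 2] * inertia[0] * omg[i, 0] - omg[i, 0] * inertia[2] * omg[i, 2]
            t2 -= omg[i, 0] * inertia[1] * omg[i, 1] - omg[i, 1] * inertia[0] * omg[i, 0]
            Tb[i, 0] = t0
            Tb[i, 1] = t1
            Tb[i, 2] = t2

    # --- thermostat: friction + bounded white noise ------------------------
    # Uniform noise on [-a, a] with a^2/3 = 2 Gamma kT / dt has exactly the
    # variance the fluctuation-dissipation contract requires; higher moments
    # only enter the sampled distribution at O(dt^2).
    if add_thermostat:
        nt = np.sqrt(3.0 * 2.0 * gamma_t * kT / dt)
        nr = np.sqrt(3.0 * 2.0 * gamma_r * kT / dt)
        for i in range(n):
            if grafted[i]:
                continue
            F[i, 0] += -gamma_t * vel[i, 0] + nt * _rand_sym(rng_state)
            F[i, 1] += -gamma_t * vel[i, 1] + nt * _rand_sym(rng_state)
            F[i, 2] += -gamma_t * vel[i, 2] + nt * _rand_sym(rng_state)
            if integrate_rotation:
                Tb[i, 0] += -gamma_r * omg[i, 0] + nr * _rand_sym(rng_state)
                Tb[i, 1] += -gamma_r * omg[i, 1] + nr * _rand_sym(rng_state)
                Tb[i, 2] += -gamma_r * omg[i, 2] + nr * _rand_sym(rng_state)

    return STATUS_OK, f_bot


@njit(cache=True, fastmath=True)
def run_langevin(
    pos, quat, vel, omg, mu,
    site_body, ster_sites, wca_sig2, wca_eps, wca_rc2, prune_cut2,
    bond_i, bond_si, bond_j, bond_sj, K_f, r0, r_f,
    mag_kind, mu_max, fm_axis,
    H, wall_on, z_bot, z_top, wall_sig, grafted,
    mass, inertia, kT, gamma_t, gamma_r, dt, integrate_rotation,
    n_steps, seed, thermostat, needs_frames, bonds_central,
    record_every, rec_pos, rec_quat, rec_mu, rec_vel, rec_omg,
    wall_accum_start,
):
    """Integrate n_steps; record snapshots every record_every steps (if > 0).

    Returns (status, steps_done, mean bottom-wall force over steps past
    wall_accum_start).
    """
    n = pos.shape[0]
    ns = ster_sites.shape[0]
    rng_state = np.empty(1, dtype=np.uint64)
    rng_state[0] = (np.uint64(seed) * np.uint64(6364136223846793005)
                    + np.uint64(1442695040888963407))

    R = np.empty((n, 3, 3))
    labS = np.empty((n, ns, 3))
    F = np.empty((n, 3))
    Tb = np.empty((n, 3))
    Bf = np.empty((n, 3))
    max_pairs = n * (n - 1) // 2
    pairs = np.empty((max_pairs if max_pairs > 0 else 1, 2), dtype=np.int64)
    npairs = np.full(1, -1, dtype=np.int64)
    pos_ref = np.empty((n, 3))
    verlet_cut2 = (np.sqrt(prune_cut2) + _NL_SKIN) ** 2

    inv_m = 1.0 / mass
    inv_I = np.empty(3)
    for k in range(3):
        inv_I[k] = 1.0 / inertia[k]
    half_dt = 0.5 * dt

    status, f_bot = _eval_forces(
        pos, quat, vel, omg, mu,
        site_body, ster_sites, wca_sig2, wca_eps, wca_rc2, prune_cut2,
        bond_i, bond_si, bond_j, bond_sj, K_f, r0, r_f,
        mag_kind, mu_max, fm_axis,
        H, wall_on, z_bot, z_top, wall_sig, grafted,
        inertia, kT, gamma_t, gamma_r, dt, integrate_rotation,
        pairs, npairs, pos_ref, verlet_cut2,
        R, labS, F, Tb, Bf, rng_state, thermostat, needs_frames, bonds_central,
    )
    if status != STATUS_OK:
        return status, 0, 0.0

    wall_sum = 0.0
    wall_cnt = 0
    rec_idx = 0

    for step in range(n_steps):
        # first half-kick + drift
        for i in range(n):
            if grafted[i]:
                continue
            vel[i, 0] += half_dt * F[i, 0] * inv_m
            vel[i, 1] += half_dt * F[i, 1] * inv_m
            vel[i, 2] += half_dt * F[i, 2] * inv_m
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
            if integrate_rotation:
                omg[i, 0] += half_dt * Tb[i, 0] * inv_I[0]
                omg[i, 1] += half_dt * Tb[i, 1] * inv_I[1]
                omg[i, 2] += half_dt * Tb[i, 2] * inv_I[2]
                wn = np.sqrt(omg[i, 0] ** 2 + omg[i, 1] ** 2 + omg[i, 2] ** 2)
                if wn > 1e-14:
                    th = 0.5 * wn * dt
                    c = np.cos(th)
                    s = np.sin(th) / wn
                    qw, qx, qy, qz = quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3]
                    dw, dx_, dy_, dz_ = c, s * omg[i, 0], s * omg[i, 1], s * omg[i, 2]
                    nw = qw * dw - qx * dx_ - qy * dy_ - qz * dz_
                    nx = qw * dx_ + qx * dw + qy * dz_ - qz * dy_
                    ny = qw * dy_ - qx * dz_ + qy * dw + qz * dx_
                    nz = qw * dz_ + qx * dy_ - qy * dx_ + qz * dw
                    inv = 1.0 / np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
                    quat[i, 0] = nw * inv
                    quat[i, 1] = nx * inv
                    quat[i, 2] = ny * inv
                    quat[i, 3] = nz * inv

        status, f_bot = _eval_forces(
            pos, quat, vel, omg, mu,
            site_body, ster_sites, wca_sig2, wca_eps, wca_rc2, prune_cut2,
            bond_i, bond_si, bond_j, bond_sj, K_f, r0, r_f,
            mag_kind, mu_max, fm_axis,
            H, wall_on, z_bot, z_top, wall_sig, grafted,
            inertia, kT, gamma_t, gamma_r, dt, integrate_rotation,
            pairs, npairs, pos_ref, verlet_cut2,
            R, labS, F, Tb, Bf, rng_state, thermostat, needs_frames, bonds_central,
        )
        if status != STATUS_OK:
            return status, step, 0.0

        # second half-kick
        for i in range(n):
            if grafted[i]:
                continue
            vel[i, 0] += half_dt * F[i, 0] * inv_m
            vel[i, 1] += half_dt * F[i, 1] * inv_m
            vel[i, 2] += half_dt * F[i, 2] * inv_m
            if integrate_rotation:
                omg[i, 0] += half_dt * Tb[i, 0] * inv_I[0]
                omg[i, 1] += half_dt * Tb[i, 1] * inv_I[1]
                omg[i, 2] += half_dt * Tb[i, 2] * inv_I[2]

        if not np.isfinite(pos[0, 0]):
            return STATUS_NONFINITE, step, 0.0

        if step >= wall_accum_start:
            wall_sum += f_bot
            wall_cnt += 1

        if record_every > 0 and (step + 1) % record_every == 0:
            if rec_idx < rec_pos.shape[0]:
                for i in range(n):
                    for k in range(3):
                        rec_pos[rec_idx, i, k] = pos[i, k]
                        rec_mu[rec_idx, i, k] = mu[i, k]
                        rec_vel[rec_idx, i, k] = vel[i, k]
                        rec_omg[rec_idx, i, k] = omg[i, k]
                    for k in range(4):
                        rec_quat[rec_idx, i, k] = quat[i, k]
                rec_idx += 1

    mean_wall = wall_sum / wall_cnt if wall_cnt > 0 else 0.0
    return STATUS_OK, n_steps, mean_wall


@njit(cache=True, fastmath=True)
def potential_energy(
    pos, quat, mu,
    site_body, ster_sites, wca_sig2, wca_eps, wca_rc2,
    bond_i, bond_si, bond_j, bond_sj, K_f, r0, r_f,
    mag_kind, H, wall_on, z_bot, z_top, wall_sig, grafted,
):
    """Total potential energy (diagnostic; mirrors _eval_forces)."""
    n = pos.shape[0]
    ns = ster_sites.shape[0]
    R = np.empty((n, 3, 3))
    labS = np.empty((n, ns, 3))
    for i in range(n):
        _rotmat_from_quat(quat[i], R[i])
        for a in range(ns):
            s = ster_sites[a]
            for k in range(3):
                labS[i, a, k] = (pos[i, k] + R[i, k, 0] * site_body[s, 0]
                                 + R[i, k, 1] * site_body[s, 1]
                                 + R[i, k, 2] * site_body[s, 2])
    U = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            for a in range(ns):
                for b in range(ns):
                    dx = labS[i, a, 0] - labS[j, b, 0]
                    dy = labS[i, a, 1] - labS[j, b, 1]
                    dz = labS[i, a, 2] - labS[j, b, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < wca_rc2[a, b]:
                        s2 = wca_sig2[a, b] / r2
                        s6 = s2 * s2 * s2
                        U += 4.0 * wca_eps[a, b] * (s6 * s6 - s6) + wca_eps[a, b]
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        si = bond_si[b]
        sj = bond_sj[b]
        dx = dy = dz = 0.0
        pa = np.empty(3)
        pb = np.empty(3)
        for k in range(3):
            pa[k] = (pos[i, k] + R[i, k, 0] * site_body[si, 0]
                     + R[i, k, 1] * site_body[si, 1] + R[i, k, 2] * site_body[si, 2])
            pb[k] = (pos[j, k] + R[j, k, 0] * site_body[sj, 0]
                     + R[j, k, 1] * site_body[sj, 1] + R[j, k, 2] * site_body[sj, 2])
        dx, dy, dz = pa[0] - pb[0], pa[1] - pb[1], pa[2] - pb[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = (r - r0) / r_f
        U += -0.5 * K_f * r_f * r_f * np.log(1.0 - x * x)
    if mag_kind > 0:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = np.sqrt(r2)
                mir = (mu[i, 0] * dx + mu[i, 1] * dy + mu[i, 2] * dz) / r
                mjr = (mu[j, 0] * dx + mu[j, 1] * dy + mu[j, 2] * dz) / r
                mimj = (mu[i, 0] * mu[j, 0] + mu[i, 1] * mu[j, 1]
                        + mu[i, 2] * mu[j, 2])
                U += (mimj - 3.0 * mir * mjr) / (r2 * r)
        for i in range(n):
            U -= mu[i, 0] * H[0] + mu[i, 1] * H[1] + mu[i, 2] * H[2]
    if wall_on:
        for i in range(n):
            if grafted[i]:
                continue
            for a in range(ns):
                sig = wall_sig[a]
                rc = 1.122462048309373 * sig
                for dzw in (labS[i, a, 2] - z_bot, z_top - labS[i, a, 2]):
                    if 0.0 < dzw < rc:
                        s2 = (sig / dzw) ** 2
                        s6 = s2 * s2 * s2
                        U += 4.0 * (s6 * s6 - s6) + 1.0
    return U
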