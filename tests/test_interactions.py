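"""Pair potentials and the superparamagnetic moment law.

Analytic forces are checked against centred finite differences of the
energies; conservation laws (Newton's third law, total angular momentum of a
dipole pair) are checked on randomized configurations.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magfil.interactions import (
    BondOverstretchError,
    PairParams,
    dipole_dipole_energy_force_torque,
    dipole_field,
    fene_energy_force,
    langevin_function,
    pair_scan,
    spm_moments_fixed_point,
    spm_moments_one_pass,
    wca_energy_force,
    zeeman_energy_torque,
)

MU2 = 3.0  # reduced saturated moment squared
MU = np.sqrt(MU2)


def num_grad(fn, r_vec, h=1e-6):
    g = np.zeros(3)
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        g[k] = (fn(r_vec + e) - fn(r_vec - e)) / (2 * h)
    return g


class TestWCA:
    def test_vanishes_at_cutoff(self):
        p = PairParams(1.0, 1.0)
        e, f = wca_energy_force(np.array([p.r_cut, 0, 0]), p)
        assert e == 0.0 and np.all(f == 0)

    def test_energy_at_sigma_is_epsilon(self):
        p = PairParams(1.0, 1.0)
        e, _ = wca_energy_force(np.array([1.0, 0, 0]), p)
        assert e == pytest.approx(1.0, rel=1e-12)

    def test_force_is_repulsive_and_continuous(self):
        p = PairParams(1.0, 2.0)
        r = np.array([0.97, 0, 0])
        _, f = wca_energy_force(r, p)
        assert f[0] > 0  # pushes i away from j
        e_edge, f_edge = wca_energy_force(np.array([p.r_cut - 1e-9, 0, 0]), p)
        assert abs(e_edge) < 1e-6 and np.linalg.norm(f_edge) < 1e-4

    def test_force_matches_numeric_gradient(self, rng):
        p = PairParams(0.91, 100.0)
        for _ in range(20):
            r = rng.normal(size=3)
            r *= rng.uniform(0.85, 1.0) * p.r_cut / np.linalg.norm(r)
            _, f = wca_energy_force(r, p)
            g = num_grad(lambda x: wca_energy_force(x, p)[0], r)
            assert np.allclose(f, -g, rtol=1e-5, atol=1e-4)

    def test_zero_distance_error(self):
        with pytest.raises(ValueError):
            wca_energy_force(np.zeros(3), PairParams(1.0, 1.0))

    def test_lorentz_berthelot_mixing(self):
        p = PairParams.mix(0.41, 1.0, 1.0, 4.0)
        assert p.sigma == pytest.approx(0.705)
        assert p.epsilon == pytest.approx(2.0)
        assert p.r_cut == pytest.approx(2 ** (1 / 6) * 0.705)


class TestFENE:
    def test_zero_at_equilibrium(self):
        e, f = fene_energy_force(np.array([0.6, 0, 0]), 10.0, 0.6, 1.8)
        assert e == pytest.approx(0.0) and np.allclose(f, 0)

    def test_diverges_at_maximal_extension(self):
        e1, _ = fene_energy_force(np.array([0.6 + 0.9 * 1.8, 0, 0]), 10.0, 0.6, 1.8)
        e2, _ = fene_energy_force(np.array([0.6 + 0.999 * 1.8, 0, 0]), 10.0, 0.6, 1.8)
        assert e2 > e1 > 0
        with pytest.raises(BondOverstretchError):
            fene_energy_force(np.array([0.6 + 1.800001, 0, 0]), 10.0, 0.6, 1.8)

    def test_harmonic_limit(self):
        # small displacement: F ~ -K_f * delta within 1%
        k_f, r0, r_f = 90.0, 0.6, 1.8
        delta = 0.01 * r_f
        _, f = fene_energy_force(np.array([r0 + delta, 0, 0]), k_f, r0, r_f)
        assert f[0] == pytest.approx(-k_f * delta, rel=0.01)

    def test_attractive_from_both_sides(self):
        _, f_out = fene_energy_force(np.array([0.8, 0, 0]), 10.0, 0.6, 1.8)
        _, f_in = fene_energy_force(np.array([0.4, 0, 0]), 10.0, 0.6, 1.8)
        assert f_out[0] < 0 < f_in[0]

    def test_force_matches_numeric_gradient(self, rng):
        for _ in range(20):
            r = rng.normal(size=3)
            r *= rng.uniform(0.3, 2.0) / np.linalg.norm(r)
            _, f = fene_energy_force(r, 90.0, 0.6, 1.8)
            g = num_grad(lambda x: fene_energy_force(x, 90.0, 0.6, 1.8)[0], r)
            assert np.allclose(f, -g, rtol=1e-5, atol=1e-6)


class TestDipoleDipole:
    def test_head_to_tail(self):
        mu = np.array([0, 0, MU])
        e, _, _, _ = dipole_dipole_energy_force_torque(mu, mu, np.array([0, 0, 1.0]))
        assert e == pytest.approx(-2 * MU2)  # = -6 at mu^2 = 3

    def test_side_by_side(self):
        mu = np.array([0, 0, MU])
        e, _, _, _ = dipole_dipole_energy_force_torque(mu, mu, np.array([1.0, 0, 0]))
        assert e == pytest.approx(MU2)  # = +3

    def test_force_matches_numeric_gradient(self, rng):
        for _ in range(20):
            mi, mj = rng.normal(size=3), rng.normal(size=3)
            r = rng.normal(size=3)
            r *= rng.uniform(0.8, 3.0) / np.linalg.norm(r)
            _, f, _, _ = dipole_dipole_energy_force_torque(mi, mj, r)
            g = num_grad(
                lambda x: dipole_dipole_energy_force_torque(mi, mj, x)[0], r)
            assert np.allclose(f, -g, rtol=1e-5, atol=1e-6)

    def test_angular_momentum_balance(self, rng):
        """Spin torques plus the r x F couple cancel for an isolated pair."""
        for _ in range(10):
            mi, mj = rng.normal(size=3), rng.normal(size=3)
            ri, rj = rng.normal(size=3), rng.normal(size=3)
            _, f, ti, tj = dipole_dipole_energy_force_torque(mi, mj, ri - rj)
            total = ti + tj + np.cross(ri, f) + np.cross(rj, -f)
            assert np.linalg.norm(total) < 1e-10 * max(1, np.linalg.norm(ti))

    def test_energy_rotation_invariance(self, rng):
        from magfil.geometry import quat_rotate
        from conftest import random_quaternion

        mi, mj = rng.normal(size=3), rng.normal(size=3)
        r = rng.normal(size=3)
        e0, *_ = dipole_dipole_energy_force_torque(mi, mj, r)
        q = random_quaternion(rng)
        e1, *_ = dipole_dipole_energy_force_torque(
            quat_rotate(q, mi), quat_rotate(q, mj), quat_rotate(q, r))
        assert e1 == pytest.approx(e0, rel=1e-10)


class TestDipoleField:
    def test_on_axis(self):
        b = dipole_field(np.array([0, 0, MU]), np.array([0, 0, 1.0]))
        assert np.allclose(b, [0, 0, 2 * MU])

    def test_equatorial(self):
        b = dipole_field(np.array([0, 0, MU]), np.array([1.0, 0, 0]))
        assert np.allclose(b, [0, 0, -MU])

    def test_linearity(self, rng):
        mu = rng.normal(size=3)
        r = rng.normal(size=3)
        assert np.allclose(dipole_field(mu, r) + dipole_field(-mu, r), 0)


class TestZeeman:
    def test_aligned(self):
        e, t = zeeman_energy_torque(np.array([0, 0, MU]), np.array([0, 0, 6.0]))
        assert e == pytest.approx(-6 * MU)
        assert np.allclose(t, 0)

    def test_perpendicular(self):
        e, t = zeeman_energy_torque(np.array([MU, 0, 0]), np.array([0, 0, 6.0]))
        assert e == 0
        assert np.linalg.norm(t) == pytest.approx(6 * MU)

    def test_zero_field(self):
        e, t = zeeman_energy_torque(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert e == 0 and np.all(t == 0)


class TestLangevinFunction:
    def test_known_values(self):
        assert langevin_function(0.0) == 0.0
        assert langevin_function(1.0) == pytest.approx(1 / np.tanh(1) - 1, rel=1e-12)
        assert langevin_function(1e4) == pytest.approx(1.0, abs=2e-4)

    @given(st.floats(min_value=1e-8, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_odd_bounded_increasing(self, a):
        la = langevin_function(a)
        assert 0 < la < 1
        assert langevin_function(-a) == pytest.approx(-la, rel=1e-9)

    def test_series_matches_closed_form_at_crossover(self):
        # continuity across the series/closed-form switch at |a| = 1e-4
        lo, hi = langevin_function(0.99e-4), langevin_function(1.01e-4)
        assert hi - lo == pytest.approx(0.02e-4 / 3, rel=1e-4)


class TestSPMUpdate:
    def test_isolated_particle_langevin_law(self):
        pos = np.zeros((1, 3))
        mu = np.zeros((1, 3))
        out = spm_moments_one_pass(pos, mu, np.array([0, 0, 6.0]), MU)
        expect = MU * langevin_function(6 * MU)
        assert np.allclose(out[0], [0, 0, expect])
        assert out[0, 2] == pytest.approx(1.5652, abs=2e-4)

    def test_zero_field_zero_moment(self):
        out = spm_moments_one_pass(np.zeros((1, 3)), np.zeros((1, 3)),
                                   np.zeros(3), MU)
        assert np.all(out == 0)

    def test_mutual_reinforcement_on_axis(self):
        """Two SPM particles stacked along the field develop larger moments
        than an isolated one (each sits in the other's head-to-tail field)."""
        pos = np.array([[0, 0, 0], [0, 0, 1.0]])
        mu0 = np.zeros((2, 3))
        H = np.array([0, 0, 6.0])
        fixed = spm_moments_fixed_point(pos, mu0, H, MU, tol=1e-10)
        isolated = MU * langevin_function(6 * MU)
        assert fixed[0, 2] > isolated
        assert fixed[1, 2] > isolated
        # converged: one more pass is a no-op
        again = spm_moments_one_pass(pos, fixed, H, MU)
        assert np.allclose(again, fixed, atol=1e-9)

    def test_moment_bounded_by_mu_max(self, rng):
        pos = rng.normal(size=(4, 3)) * 2
        mu = rng.normal(size=(4, 3))
        out = spm_moments_one_pass(pos, mu, np.array([0, 0, 6.0]), MU)
        assert np.all(np.linalg.norm(out, axis=1) <= MU + 1e-12)

    def test_converged_moments_parallel_to_field(self):
        """At the fixed point mu_i is parallel to B_tot,i, so the magnetic
        torque on an SPM monomer vanishes identically."""
        from magfil.interactions import _total_fields

        pos = np.array([[0, 0, 0], [0.3, 0.2, 1.1]])
        H = np.array([0.5, 0, 3.0])
        fixed = spm_moments_fixed_point(pos, np.zeros((2, 3)), H, MU)
        B = _total_fields(pos, fixed, H)
        for m, b in zip(fixed, B):
            assert np.linalg.norm(np.cross(m, b)) < 1e-8


class TestPairScan:
    def test_wca_scan_matches_pointwise_evaluation(self):
        tab = pair_scan("wca", sigma=0.91, epsilon=100.0, r_min=0.8,
                        r_max=1.2, n=20)
        assert {"r", "energy", "force"} <= set(tab.columns)
        row = tab.iloc[0]
        e, f = wca_energy_force(np.array([0, 0, row.r]),
                                PairParams(0.91, 100.0))
        assert row.energy == pytest.approx(e)
        assert row.force == pytest.approx(f[2])

    def test_fene_scan_skips_overstretched_separations(self):
        tab = pair_scan("fene", K_f=10.0, r0=0.6, r_f=1.8, r_min=0.1,
                        r_max=3.0, n=50)
        assert tab.r.max() < 2.4

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            pair_scan("coulomb")
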