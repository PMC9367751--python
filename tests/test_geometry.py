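"""Monomer templates: superball surface, crown anchors, raspberry cubes."""

import numpy as np
import pytest

from magfil.geometry import (
    BodyFrame,
    build_cube_monomer,
    build_sphere_monomer,
    inertia_from_sites,
    quat_from_axis_angle,
    site_lab_positions,
    superball_implicit,
    template_table,
)

from conftest import random_quaternion


class TestSuperball:
    @pytest.mark.parametrize("q", [1.0, 2.0])
    def test_axis_point_on_surface(self, q):
        # a point on a principal axis lies on every superball of that radius
        assert superball_implicit((0.5, 0.0, 0.0), r=0.5, q=q) == pytest.approx(0.0)

    def test_diagonal_surface_point_q2(self):
        t = 0.5 / 3**0.25  # solves 3 t^4 = 0.5^4
        assert superball_implicit((t, t, t), r=0.5, q=2) == pytest.approx(0.0, abs=1e-12)

    def test_q1_reduces_to_sphere(self, rng):
        pts = rng.normal(size=(50, 3))
        f = superball_implicit(pts, r=1.0, q=1)
        r2 = np.sum(pts**2, axis=1)
        assert np.allclose(f, r2 - 1.0)

    def test_sign_convention(self):
        assert superball_implicit((0.1, 0.1, 0.1), 0.5, 2) < 0
        assert superball_implicit((1.0, 1.0, 1.0), 0.5, 2) > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            superball_implicit((np.nan, 0, 0), 0.5, 2)
        with pytest.raises(ValueError):
            superball_implicit((1, 0, 0), -1.0, 2)
        with pytest.raises(ValueError):
            superball_implicit((1, 0, 0), 1.0, 0.5)


class TestSphereMonomer:
    def test_ctc_single_site(self):
        t = build_sphere_monomer(0.91, "CTC")
        assert len(t.sites) == 1
        assert t.sites[0].diameter == 0.91
        assert t.sites[0].epsilon == 100.0

    def test_ftf_crown_geometry(self):
        t = build_sphere_monomer(0.91, "FTF")
        assert len(t.sites) == 17
        anchors = [s for s in t.sites if s.is_anchor]
        assert len(anchors) == 16
        # anchors lie on the sphere surface
        for s in anchors:
            assert np.linalg.norm(s.body_position) == pytest.approx(0.455, abs=1e-12)
        # crown circle radius: sphere cut by the plane at sigma/4
        rho = 0.91 * np.sqrt(3) / 4
        for s in anchors:
            assert np.hypot(*s.body_position[:2]) == pytest.approx(rho, abs=1e-12)
        # crowns are mirror images through the equatorial plane
        pos = np.array([s.body_position for s in anchors])
        mirrored = pos * np.array([1, 1, -1])
        for p in mirrored:
            assert np.min(np.linalg.norm(pos - p, axis=1)) < 1e-12

    def test_anchor_sites_carry_no_steric_interaction(self):
        t = build_sphere_monomer(0.91, "FTF")
        assert sum(s.is_steric for s in t.sites) == 1


class TestCubeMonomer:
    def test_site_count(self):
        assert len(build_cube_monomer(1.0).sites) == 21

    def test_corner_distance(self):
        t = build_cube_monomer(1.0)
        corner = t.sites[1].body_position
        # superball surface along the <111> diagonal: 3 x^4 = 0.5^4
        assert np.linalg.norm(corner) == pytest.approx(0.6580, abs=1e-3)

    def test_shell_sites_on_superball_surface(self):
        t = build_cube_monomer(1.0)
        for s in t.sites[1:]:
            assert abs(superball_implicit(s.body_position, 0.5, 2)) < 1e-8

    def test_printed_diameters(self):
        t = build_cube_monomer(1.0)
        diams = sorted({round(s.diameter, 2) for s in t.sites})
        assert diams == [0.41, 0.49, 1.0]
        edges = [s for s in t.sites if s.diameter == 0.49]
        assert len(edges) == 12
        norms = [np.linalg.norm(s.body_position) for s in edges]
        assert np.ptp(norms) < 1e-12

    def test_octahedral_symmetry(self):
        """The template (as a site set per diameter class) is invariant under
        all 24 proper cube rotations."""
        t = build_cube_monomer(1.0)
        pos = t.body_positions()
        diam = t.diameters()
        rotations = []
        # enumerate signed permutation matrices with determinant +1
        from itertools import permutations, product

        for perm in permutations(range(3)):
            for signs in product((-1, 1), repeat=3):
                m = np.zeros((3, 3))
                for row, (col, s) in enumerate(zip(perm, signs)):
                    m[row, col] = s
                if np.isclose(np.linalg.det(m), 1.0):
                    rotations.append(m)
        assert len(rotations) == 24
        for m in rotations:
            rotated = pos @ m.T
            for p, dcls in zip(rotated, diam):
                match = np.linalg.norm(pos - p, axis=1) < 1e-10
                assert np.any(match & (diam == dcls))

    def test_shell_sites_are_anchors(self):
        t = build_cube_monomer(1.0)
        assert all(s.is_anchor and s.is_steric for s in t.sites[1:])


class TestTransforms:
    def test_identity(self):
        t = build_cube_monomer(1.0)
        frame = BodyFrame(np.zeros(3), np.array([1.0, 0, 0, 0]))
        assert np.allclose(site_lab_positions(t, frame), t.body_positions())

    def test_quarter_turn_about_z(self):
        t = build_sphere_monomer(0.91, "FTF")
        q = quat_from_axis_angle([0, 0, 1], np.pi / 2)
        frame = BodyFrame(np.zeros(3), q)
        lab = site_lab_positions(t, frame)
        body = t.body_positions()
        # (x, y, z) -> (-y, x, z)
        expect = np.column_stack([-body[:, 1], body[:, 0], body[:, 2]])
        assert np.allclose(lab, expect, atol=1e-12)

    def test_rigidity_under_random_rotation(self, rng):
        t = build_cube_monomer(1.0)
        body = t.body_positions()
        ref = np.linalg.norm(body[:, None] - body[None, :], axis=-1)
        for _ in range(5):
            frame = BodyFrame(rng.normal(size=3), random_quaternion(rng))
            lab = site_lab_positions(t, frame)
            d = np.linalg.norm(lab[:, None] - lab[None, :], axis=-1)
            assert np.max(np.abs(d - ref)) < 1e-10

    def test_rejects_non_unit_quaternion(self):
        t = build_cube_monomer(1.0)
        with pytest.raises(ValueError):
            BodyFrame(np.zeros(3), np.array([1.0, 0.1, 0, 0]))


class TestInertia:
    def test_cube_isotropic_diagonal(self):
        t = build_cube_monomer(1.0)
        I = t.inertia
        assert np.allclose(I, np.diag(np.diag(I)))
        assert np.ptp(np.diag(I)) < 1e-12

    def test_quadratic_scaling(self):
        t = build_cube_monomer(1.0)
        big = build_cube_monomer(2.0)
        assert np.allclose(big.inertia, 4 * t.inertia)

    def test_direct_summation_oracle(self):
        t = build_cube_monomer(1.0)
        m_site = t.mass / len(t.sites)
        ixx = sum(m_site * (p[1] ** 2 + p[2] ** 2) for p in t.body_positions())
        assert t.inertia[0, 0] == pytest.approx(ixx, rel=1e-12)

    def test_bare_sphere_gets_solid_sphere_floor(self):
        t = build_sphere_monomer(0.91, "CTC")
        assert np.allclose(t.inertia, 0.1 * 0.91**2 * np.eye(3))


def test_template_table_layout():
    tab = template_table(build_cube_monomer(1.0))
    assert list(tab.columns) == ["site_id", "role", "x", "y", "z", "sigma", "epsilon"]
    assert len(tab) == 21
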