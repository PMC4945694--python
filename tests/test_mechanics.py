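"""Finite-strain SVK mechanics: closed forms, solver verification."""

import math

import numpy as np
import pytest

from nucleoflux.mechanics import (BoundaryProgram, MaterialParams,
                                  MechanicsProblem, calibrate_amplitude,
                                  cauchy_from_pk2, kinematics, lame_from_E_nu,
                                  max_volumetric_strain, nucleus_extent,
                                  nuclear_stress_summary, pk2_stress,
                                  solve_linear, solve_quasistatic)

MAT = MaterialParams()


class TestLame:
    @pytest.mark.parametrize("E,nu,lam,mu", [
        (5.0, 0.35, 4.3210, 1.8519),
        (1.0, 0.35, 0.8642, 0.3704),
    ])
    def test_reference_values(self, E, nu, lam, mu):
        l, m = lame_from_E_nu(E, nu)
        assert l == pytest.approx(lam, abs=1e-4)
        assert m == pytest.approx(mu, abs=1e-4)

    def test_zero_poisson(self):
        l, m = lame_from_E_nu(3.0, 0.0)
        assert l == 0.0 and m == 1.5

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            lame_from_E_nu(1.0, 0.5)
        with pytest.raises(ValueError):
            lame_from_E_nu(-1.0, 0.3)


class TestKinematics:
    def test_reference_state(self):
        F, E, J, eV = kinematics(np.zeros((3, 3)))
        np.testing.assert_allclose(F, np.eye(3))
        np.testing.assert_allclose(E, 0.0, atol=1e-15)
        assert J == pytest.approx(1.0) and eV == pytest.approx(0.0)

    def test_uniform_stretch(self):
        alpha = 1.2
        F, E, J, eV = kinematics((alpha - 1) * np.eye(3))
        assert J == pytest.approx(alpha**3, rel=1e-12)
        np.testing.assert_allclose(E, 0.5 * (alpha**2 - 1) * np.eye(3))

    def test_simple_shear(self):
        gamma = 0.3
        grad = np.zeros((3, 3))
        grad[0, 2] = gamma          # u_x = gamma * Z
        F, E, J, eV = kinematics(grad)
        assert J == pytest.approx(1.0, rel=1e-12)
        assert E[0, 2] == pytest.approx(gamma / 2)
        assert E[2, 2] == pytest.approx(gamma**2 / 2)


class TestPK2:
    def test_stress_free_reference(self):
        S = pk2_stress(np.zeros((3, 3)), 4.0, 2.0)
        np.testing.assert_allclose(S, 0.0)

    def test_hydrostatic(self):
        eps = 0.01
        S = pk2_stress(eps * np.eye(3), 4.0, 2.0)
        np.testing.assert_allclose(S, (3 * 4.0 + 2 * 2.0) * eps * np.eye(3))

    def test_pure_shear(self):
        E = np.zeros((3, 3))
        E[0, 2] = E[2, 0] = 0.05
        S = pk2_stress(E, 4.0, 2.0)
        assert S[0, 2] == pytest.approx(2 * 2.0 * 0.05)
        assert abs(np.trace(S)) < 1e-14
        np.testing.assert_allclose(S, S.T)


class TestQuasistatic:
    def test_zero_amplitude_gives_zero_displacement(self, axisym_coarse):
        traj = solve_quasistatic(axisym_coarse, MAT,
                                 BoundaryProgram("uniform_radial", 1.0, 0.0),
                                 n_steps=2)
        assert np.max(np.abs(traj.u_final)) < 1e-10
        np.testing.assert_allclose(traj.J_steps[-1], 1.0, atol=1e-12)

    def test_small_strain_matches_linear_solution(self, axisym_coarse):
        """Nonlinear solve at <=0.5 % strain agrees with linear elasticity."""
        prog = BoundaryProgram("uniform_radial", 1.0, 0.03)
        prob = MechanicsProblem(axisym_coarse, MAT)
        un = solve_quasistatic(prob, program=prog, n_steps=2).u_final
        ul = solve_linear(prob, program=prog)
        assert np.linalg.norm(un - ul) / np.linalg.norm(ul) < 0.01

    def test_jacobian_positive_everywhere(self, axisym_coarse):
        traj = solve_quasistatic(axisym_coarse, MAT,
                                 BoundaryProgram("uniform_radial", 1.0, 4.0,
                                                 volume_factor=1.3),
                                 n_steps=5)
        for J in traj.J_steps:
            assert np.all(J > 0)

    def test_objectivity_under_superposed_rotation(self, octant_coarse):
        """A rigid rotation of a converged state leaves E and J unchanged."""
        prog = BoundaryProgram("uniform_radial", 1.0, 1.0, volume_factor=1.1)
        prob = MechanicsProblem(octant_coarse, MAT)
        traj = solve_quasistatic(prob, program=prog, n_steps=3)
        u = traj.u_final.reshape(-1, 3)
        a = 0.4
        R = np.array([[math.cos(a), -math.sin(a), 0],
                      [math.sin(a), math.cos(a), 0], [0, 0, 1.0]])
        X = octant_coarse.coords
        u_rot = (X + u) @ R.T - X
        F1 = prob.deformation_gradient(traj.u_final)
        F2 = prob.deformation_gradient(u_rot.ravel())
        E1 = 0.5 * (np.einsum("eqki,eqkj->eqij", F1, F1) - np.eye(3))
        E2 = 0.5 * (np.einsum("eqki,eqkj->eqij", F2, F2) - np.eye(3))
        np.testing.assert_allclose(E2, E1, atol=1e-10)
        np.testing.assert_allclose(np.linalg.det(F2), np.linalg.det(F1),
                                   rtol=1e-10)


class TestSymmetryEquivalence:
    def test_octant_matches_axisymmetric(self, octant_coarse, axisym_default):
        """Uniform-radial octant and axisymmetric solutions agree in u."""
        from scipy.interpolate import LinearNDInterpolator

        prog = BoundaryProgram("uniform_radial", 1.0, 2.0, volume_factor=1.3)
        prob3 = MechanicsProblem(octant_coarse, MAT)
        u3 = solve_quasistatic(prob3, program=prog, n_steps=5).u_final
        prob2 = MechanicsProblem(axisym_default, MAT)
        u2 = solve_quasistatic(prob2, program=prog, n_steps=5).u_final

        pts2 = axisym_default.coords
        itp_r = LinearNDInterpolator(pts2, u2[0::2])
        itp_z = LinearNDInterpolator(pts2, u2[1::2])
        # compare on the octant's y=0 plane nodes
        sel = np.flatnonzero(np.abs(octant_coarse.coords[:, 1]) < 1e-8)
        Rz = octant_coarse.coords[sel][:, [0, 2]]
        ur_ref = itp_r(Rz)
        uz_ref = itp_z(Rz)
        ok = np.isfinite(ur_ref)
        u3v = u3.reshape(-1, 3)[sel]
        scale = np.abs(u2).max()
        err = np.max(np.hypot(u3v[ok, 0] - ur_ref[ok], u3v[ok, 2] - uz_ref[ok]))
        assert err / scale < 0.02


class TestCalibration:
    def test_reference_target_needs_no_amplitude(self, axisym_coarse):
        prog, ext, n = calibrate_amplitude(axisym_coarse, MAT,
                                           "uniform_radial", 1.0, [5.0])
        assert prog.amplitude_x == 0.0 and n == 0

    def test_extent_target_reached_within_tolerance(self, axisym_coarse):
        target = 6.0
        prog, ext, n = calibrate_amplitude(axisym_coarse, MAT,
                                           "uniform_radial", 1.0, [target],
                                           tol=0.01)
        assert abs(ext[0] - target) / target < 0.01

    def test_below_reference_target_rejected(self, axisym_coarse):
        with pytest.raises(ValueError):
            calibrate_amplitude(axisym_coarse, MAT, "uniform_radial", 1.0, [4.0])


class TestStressSummary:
    def test_zero_amplitude_zero_stress(self, axisym_coarse):
        traj = solve_quasistatic(axisym_coarse, MAT,
                                 BoundaryProgram("uniform_radial", 1.0, 0.0),
                                 n_steps=2)
        ss = nuclear_stress_summary(traj)
        for v in ss.values():
            assert abs(v) < 1e-8

    def test_cauchy_pushforward_consistency(self):
        F = np.array([[1.2, 0.1, 0], [0, 1.0, 0], [0, 0, 0.9]])
        S = np.array([[2.0, 0.3, 0], [0.3, 1.0, 0], [0, 0, 0.5]])
        J = np.linalg.det(F)
        sig = cauchy_from_pk2(F, S, np.asarray(J))
        np.testing.assert_allclose(sig, F @ S @ F.T / J, rtol=1e-12)
        np.testing.assert_allclose(sig, sig.T)

    def test_spread_state_has_tensile_major_axis(self, axisym_coarse):
        traj = solve_quasistatic(axisym_coarse, MAT,
                                 BoundaryProgram("uniform_radial", 1.0, 4.0,
                                                 volume_factor=1.3),
                                 n_steps=5)
        ss = nuclear_stress_summary(traj)
        assert ss["sigma_major_Pa"] > 500.0


def test_max_volumetric_strain_location(axisym_coarse):
    """Uniform equatorial spreading dilates the nucleus most at its top."""
    traj = solve_quasistatic(axisym_coarse, MAT,
                             BoundaryProgram("uniform_radial", 1.0, 4.0,
                                             volume_factor=1.3),
                             n_steps=5)
    eV, loc, lat = max_volumetric_strain(traj)
    assert eV > 0.0
    assert lat > 60.0


def test_mesh_convergence_of_peak_volumetric_strain(axisym_coarse,
                                                    axisym_default):
    """Peak nuclear volumetric strain changes < 3 % between the coarse
    axisymmetric mesh and the desk-resolution one (half the edge length)."""
    prog = BoundaryProgram("uniform_radial", 1.0, 4.0, volume_factor=1.3)
    peaks = []
    for mesh in (axisym_coarse, axisym_default):
        traj = solve_quasistatic(mesh, MAT, prog, n_steps=5)
        peaks.append(max_volumetric_strain(traj)[0])
    assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.03
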