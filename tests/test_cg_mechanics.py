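import numpy as np
import pytest
from scipy.integrate import quad

from elastohydro import cg_mechanics as cg
from elastohydro.assembly import (
    Assembly,
    Attachment,
    Filament,
    Structure,
    build_spherical_body,
)
from elastohydro.rotations import directors_from_generator, exp_map, rotation_matrix
from elastohydro.solver import GoverningSystem


def semicircle_directors(N):
    # midpoint-sampled tangent angles of an exact semicircle of length 1
    theta = (np.arange(N) + 0.5) * np.pi / N
    return np.array(
        [directors_from_generator(0.5 * t * np.array([0, 1, 0])) for t in theta]
    )


def twisted_directors(N, tau, ds):
    # d3 fixed along z, d1/d2 rotating about z at rate tau per arclength
    out = np.empty((N, 3, 3))
    for i in range(N):
        out[i] = directors_from_generator(0.5 * tau * i * ds * np.array([0, 0, 1]))
    return out


class TestCurvatures:
    def test_straight_zero(self):
        directors = np.broadcast_to(np.eye(3), (6, 3, 3))
        np.testing.assert_allclose(
            cg.curvatures_from_directors(directors, 0.1), 0, atol=1e-15
        )

    def test_semicircle_second_order_convergence(self):
        errs = []
        for N in (10, 20, 40):
            kap = cg.curvatures_from_directors(semicircle_directors(N), 1.0 / N)
            errs.append(np.abs(np.abs(kap[:, 1]).max() - np.pi))
        # |kappa| -> pi with second-order error decay
        assert errs[-1] < 1e-2
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_pure_twist(self):
        tau, N, ds = 1.3, 30, 1.0 / 30
        kap = cg.curvatures_from_directors(twisted_directors(N, tau, ds), ds)
        np.testing.assert_allclose(kap[:, 2], tau, atol=1e-3)
        np.testing.assert_allclose(kap[:, :2], 0, atol=1e-12)


class TestBendingMoments:
    def test_zero_at_preferred_shape(self):
        N = 12
        directors = semicircle_directors(N)
        kap_actual = cg.curvatures_from_directors(directors, 1.0 / N)
        s_j = (np.arange(1, N)) * (1.0 / N)

        def kappa0(s, t):
            j = int(np.argmin(np.abs(s_j - s)))
            return tuple(kap_actual[j])

        fil = Filament(N=N, n=1, preferred_curvature=kappa0)
        m = cg.bending_moments(fil, directors, 0.0)
        np.testing.assert_allclose(m, 0, atol=1e-12)

    def test_semicircle_magnitude(self):
        N = 80
        fil = Filament(N=N, n=1, Eb=2.0)
        m = cg.bending_moments(fil, semicircle_directors(N), 0.0)
        np.testing.assert_allclose(
            np.linalg.norm(m, axis=1), 2.0 * np.pi, rtol=1e-3
        )

    def test_equivariance_under_global_rotation(self, rng):
        N = 9
        directors = semicircle_directors(N)
        R = rotation_matrix(exp_map(rng.normal(size=3)))
        fil = Filament(N=N, n=1)
        m1 = cg.bending_moments(fil, directors, 0.0)
        m2 = cg.bending_moments(fil, np.einsum("ab,jbc->jac", R, directors), 0.0)
        np.testing.assert_allclose(m2, m1 @ R.T, atol=1e-12)


class TestActiveMomentIntegral:
    def test_zero_without_drive(self):
        fil = Filament(N=5, n=1)
        directors = np.broadcast_to(np.eye(3), (5, 3, 3))
        np.testing.assert_array_equal(
            cg.active_moment_integral(fil, directors, 1.0), 0
        )

    def test_closed_form_constant_d2(self):
        # m_a = 12 k cos(k s - t) d2 on a straight filament (d2 = e_y):
        # integral from s_j to L is 12 [sin(kL - t) - sin(k s_j - t)] e_y
        k, t, N = 2 * np.pi, 0.7, 16

        def m_a(s, tt):
            return (0.0, 12.0 * k * np.cos(k * s - tt), 0.0)

        fil = Filament(N=N, n=1, active_moment=m_a)
        directors = np.broadcast_to(np.eye(3), (N, 3, 3))
        result = cg.active_moment_integral(fil, directors, t)
        s_j = fil.joint_arclengths()
        expected = 12.0 * (np.sin(k - t) - np.sin(k * s_j - t))
        np.testing.assert_allclose(result[:, 1], expected, atol=1e-8)
        np.testing.assert_allclose(result[:, [0, 2]], 0, atol=1e-15)

    def test_quadrature_matches_adaptive_oracle(self):
        def m_a(s, tt):
            return (np.exp(-2 * s) * np.sin(5 * s), 0.0, 0.0)

        N = 10
        fil = Filament(N=N, n=1, active_moment=m_a)
        directors = np.broadcast_to(np.eye(3), (N, 3, 3))
        result = cg.active_moment_integral(fil, directors, 0.0)
        for j, s_j in enumerate(fil.joint_arclengths()):
            oracle, _ = quad(lambda s: np.exp(-2 * s) * np.sin(5 * s), s_j, 1.0)
            assert abs(result[j, 0] - oracle) < 1e-8


class TestAssembleMF:
    def test_shape_body_plus_filament(self, body_with_filament):
        fil, asm, state = body_with_filament
        MF = cg.assemble_MF(asm, asm.frames(state))
        assert MF.shape == (3 * fil.N + 3, 6 * asm.n_spheres)

    def test_brute_force_oracle(self, body_with_filament, rng):
        fil, asm, state = body_with_filament
        frames = asm.frames(state)
        M = asm.n_spheres
        F = rng.normal(size=(M, 3))
        T = rng.normal(size=(M, 3))
        MF = cg.assemble_MF(asm, frames)
        got = MF @ np.concatenate([F.ravel(), T.ravel()])
        frame = frames[0]
        nb = asm.structures[0].n_body_spheres
        rows = [F.sum(0), (np.cross(frame.positions - frame.x_b, F) + T).sum(0)]
        ff = frame.filaments[0]
        for j in range(2, fil.N + 1):
            idx = nb + np.arange((j - 1) * fil.n, fil.n_spheres)
            rows.append(
                (np.cross(frame.positions[idx] - ff.endpoints[j - 1], F[idx]) + T[idx]).sum(0)
            )
        np.testing.assert_allclose(got, np.concatenate(rows), atol=1e-12)

    def test_free_solid_body_six_rows(self):
        body = build_spherical_body(0.4, 20)
        asm = Assembly([Structure(body=body)])
        MF = cg.assemble_MF(asm, asm.frames(np.zeros(6)))
        assert MF.shape == (6, 6 * 20)

    def test_moment_rows_ignore_body_spheres(self, body_with_filament):
        fil, asm, state = body_with_filament
        MF = cg.assemble_MF(asm, asm.frames(state))
        nb = asm.structures[0].n_body_spheres
        m = asm.n_spheres
        np.testing.assert_array_equal(MF[6:, : 3 * nb], 0)
        np.testing.assert_array_equal(MF[6:, 3 * m : 3 * m + 3 * nb], 0)

    def test_block_diagonal_across_structures(self):
        fils = [Filament(N=3, n=1) for _ in range(2)]
        asm = Assembly([Structure(attachments=[Attachment(f)]) for f in fils])
        state = np.zeros(asm.state_size)
        state[asm.state_offsets[1]] = 2.0  # separate the filaments
        MF = cg.assemble_MF(asm, asm.frames(state))
        m = asm.n_spheres
        rows0 = slice(0, asm.state_offsets[1])
        cols1_F = slice(3 * 3, 3 * m)
        np.testing.assert_array_equal(MF[rows0, cols1_F], 0)


class TestAssembleK:
    def test_straight_filament_zero(self, rng):
        fil = Filament(N=6, n=1)
        asm = Assembly([Structure(attachments=[Attachment(fil)])])
        K = cg.assemble_K(asm, asm.frames(np.zeros(asm.state_size)), 0.3)
        np.testing.assert_array_equal(K, 0)

    def test_travelling_wave_is_time_periodic(self):
        def kappa0(s, t):
            return (np.sin(2 * np.pi * s - t), 0.0, 0.0)

        fil = Filament(N=6, n=1, preferred_curvature=kappa0)
        asm = Assembly([Structure(attachments=[Attachment(fil)])])
        frames = asm.frames(np.zeros(asm.state_size))
        K1 = cg.assemble_K(asm, frames, 0.4)
        K2 = cg.assemble_K(asm, frames, 0.4 + 2 * np.pi)
        np.testing.assert_allclose(K1, K2, atol=1e-12)
        assert np.max(np.abs(K1)) > 0

    def test_equilibrium_at_preferred_shape(self):
        # if kappa0 equals the state's actual curvature, K = 0 and the
        # solved velocities vanish identically
        N = 8
        directors = semicircle_directors(N)
        kap = cg.curvatures_from_directors(directors, 1.0 / N)
        s_j = np.arange(1, N) / N

        def kappa0(s, t):
            return tuple(kap[int(np.argmin(np.abs(s_j - s)))])

        fil = Filament(N=N, n=1, preferred_curvature=kappa0)
        asm = Assembly([Structure(attachments=[Attachment(fil)])])
        state = np.zeros(asm.state_size)
        theta = (np.arange(N) + 0.5) * np.pi / N  # same angles as the oracle
        state[3:6] = 0.5 * theta[0] * np.array([0, 1.0, 0])
        for i in range(1, N):
            state[6 + 3 * (i - 1) : 9 + 3 * (i - 1)] = (
                0.5 * theta[i] * np.array([0, 1.0, 0])
            )
        system = GoverningSystem(asm, eta=81.0, overlap_corrected=True)
        xdot = system.rhs(0.0, state)
        np.testing.assert_allclose(xdot, 0, atol=1e-10)
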