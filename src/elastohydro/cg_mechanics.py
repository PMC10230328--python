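"""Coarse-grained momentum balance: the operator ``M_F`` and right side ``K``.

Row layout per structure (matching the state layout):

* 3 force-balance rows   ``sum_i F_i = 0``
* 3 torque-balance rows  ``sum_i ((y_i - x_b) x F_i + T_i) = 0``
* per filament, 3 rows per interior joint j = 2..N:
  ``sum_{spheres in segments >= j} ((y - x_j) x F + T) = -m_j - int_{s_j}^{L} m_a ds``

Fixed-body structures (walls) drop the global balance rows: the wall
absorbs linear and angular momentum.  Columns span the *global* force then
torque vector ``[F_1..F_M, T_1..T_M]``; blocks outside a structure's own
spheres are zero, making ``M_F`` block-diagonal across structures.
"""

from __future__ import annotations

import numpy as np

from .assembly import Assembly, Filament
from .rotations import cross_matrix

__all__ = [
    "curvatures_from_directors",
    "joint_frames",
    "bending_moments",
    "active_moment_integral",
    "assemble_MF",
    "assemble_K",
]

# fixed-order Gauss-Legendre nodes/weights on [0, 1] for per-segment drives
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(4)
_GL_NODES = 0.5 * (_GL_NODES + 1.0)
_GL_WEIGHTS = 0.5 * _GL_WEIGHTS


def joint_frames(directors: np.ndarray) -> np.ndarray:
    """Normalized joint-averaged director bases, shape (N-1, 3, 3).

    The basis at interior joint j averages the director frames of the two
    adjacent segments, which keeps the finite-difference curvatures below
    second order in ``ds`` and frame-covariant.
    """
    avg = 0.5 * (directors[:-1] + directors[1:])
    return avg / np.linalg.norm(avg, axis=1, keepdims=True)


def curvatures_from_directors(directors: np.ndarray, ds: float) -> np.ndarray:
    """Curvatures ``(k1, k2, k3)`` at the N-1 interior joints.

    Joint-centred finite differences of the director basis:
    ``k1 = (Dd2/ds) . dbar3``, ``k2 = (Dd3/ds) . dbar1``,
    ``k3 = (Dd1/ds) . dbar2`` with ``D`` the across-joint difference and
    ``dbar`` the joint-averaged normalized directors.
    """
    directors = np.asarray(directors)
    diff = (directors[1:] - directors[:-1]) / ds
    dbar = joint_frames(directors)
    k1 = np.einsum("ji,ji->j", diff[:, :, 1], dbar[:, :, 2])
    k2 = np.einsum("ji,ji->j", diff[:, :, 2], dbar[:, :, 0])
    k3 = np.einsum("ji,ji->j", diff[:, :, 0], dbar[:, :, 1])
    return np.column_stack([k1, k2, k3])


def bending_moments(filament: Filament, directors: np.ndarray, t: float) -> np.ndarray:
    """Lab-frame constitutive moments ``m_j`` at joints j = 2..N, (N-1, 3).

    ``m_j = Eb (k1 - k1^0) dbar1 + Eb (k2 - k2^0) dbar2 + Et (k3 - k3^0) dbar3``
    with the preferred curvature evaluated at the joint arclengths.
    """
    kappa = curvatures_from_directors(directors, filament.ds)
    if filament.preferred_curvature is not None:
        s_j = filament.joint_arclengths()
        k0 = np.array([filament.preferred_curvature(s, t) for s in s_j], dtype=float)
        kappa = kappa - k0
    dbar = joint_frames(directors)
    stiff = np.array([filament.Eb, filament.Eb, filament.Et])
    return np.einsum("ja,a,jia->ji", kappa, stiff, dbar)


def active_moment_integral(filament: Filament, directors: np.ndarray, t: float) -> np.ndarray:
    """``int_{s_j}^{L} m_a ds`` for every interior joint, (N-1, 3), lab frame.

    The active moment density is given componentwise in the local director
    basis; within segment i the directors are constant, so the integral is
    a per-segment Gauss quadrature accumulated tip-to-base.
    """
    if filament.active_moment is None:
        return np.zeros((filament.N - 1, 3))
    ds = filament.ds
    seg_int = np.zeros((filament.N, 3))
    for i in range(filament.N):
        s0 = i * ds
        comps = sum(
            w * np.asarray(filament.active_moment(s0 + x * ds, t), dtype=float)
            for x, w in zip(_GL_NODES, _GL_WEIGHTS)
        )
        seg_int[i] = ds * (directors[i] @ comps)
    tail = np.cumsum(seg_int[::-1], axis=0)[::-1]  # sum over segments >= i
    return tail[1:]


def assemble_MF(assembly: Assembly, frames) -> np.ndarray:
    """Assemble the momentum-balance operator, shape (state_size, 6M)."""
    m = assembly.n_spheres
    rows = assembly.state_size
    MF = np.zeros((rows, 6 * m))
    eye = np.eye(3)
    for si, (structure, frame) in enumerate(zip(assembly.structures, frames)):
        row0 = assembly.state_offsets[si]
        sph0 = assembly.sphere_offsets[si]
        r = row0
        if not structure.fixed:
            # total force and torque balance over every sphere of the structure
            for k in range(structure.n_spheres):
                cf = 3 * (sph0 + k)
                ct = 3 * m + cf
                MF[r : r + 3, cf : cf + 3] = eye
                MF[r + 3 : r + 6, cf : cf + 3] = cross_matrix(
                    frame.positions[k] - frame.x_b
                )
                MF[r + 3 : r + 6, ct : ct + 3] = eye
            r += 6
        fil_sph0 = sph0 + structure.n_body_spheres
        for a, ff in zip(structure.attachments, frame.filaments):
            fil = a.filament
            for j in range(2, fil.N + 1):  # interior joints
                x_j = ff.endpoints[j - 1]
                for k in range((j - 1) * fil.n, fil.n_spheres):
                    cf = 3 * (fil_sph0 + k)
                    ct = 3 * m + cf
                    MF[r : r + 3, cf : cf + 3] = cross_matrix(ff.positions[k] - x_j)
                    MF[r : r + 3, ct : ct + 3] = eye
                r += 3
            fil_sph0 += fil.n_spheres
    return MF


def assemble_K(assembly: Assembly, frames, t: float) -> np.ndarray:
    """Constitutive right-hand side; zero in the global balance rows."""
    K = np.zeros(assembly.state_size)
    for si, (structure, frame) in enumerate(zip(assembly.structures, frames)):
        r = assembly.state_offsets[si] + (0 if structure.fixed else 6)
        for a, ff in zip(structure.attachments, frame.filaments):
            fil = a.filament
            rhs = -bending_moments(fil, ff.directors, t)
            rhs -= active_moment_integral(fil, ff.directors, t)
            K[r : r + 3 * (fil.N - 1)] = rhs.ravel()
            r += 3 * (fil.N - 1)
    return K
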