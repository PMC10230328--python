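"""Rotne–Prager–Yamakawa (RPY) grand mobility for polydisperse spheres.

The grand mobility ``M_H`` maps forces and torques on every sphere to
linear and angular velocities, ``[V; Omega] = M_H [F; T]``, with the global
ordering ``[F_1..F_M, T_1..T_M]``.  Pair blocks include the
translation–translation, rotation–rotation and translation–rotation
couplings for unequal radii.  An overlap-regularized variant keeps the
matrix positive-definite down to zero separation; the regularized
translation–rotation coupling is obtained by surface-averaging the rotlet
field (rigid rotation inside the torqued sphere) over the receiving
sphere, which yields

    g(d) = -(d - a_i + a_j)^2 (3d^2 - 2d a_i - 6d a_j - a_i^2
            - 2 a_i a_j + 3 a_j^2) / (16 d^2 a_i)

for ``|a_i - a_j| < d < a_i + a_j`` (sphere ``j`` torqued), continuous with
the far-field ``a_j^3/d^2`` at touching and with rigid advection ``d`` when
the receiver sits fully inside the torqued sphere.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "MobilityMatrix",
    "OverlappingSpheresError",
    "MobilitySingularityError",
    "rpy_mobility",
    "apply_inverse_mobility",
    "tracer_velocities",
    "group_mask",
]

# spheres built to touch exactly may round a hair below contact
_CONTACT_RTOL = 1e-9


class OverlappingSpheresError(ValueError):
    """Raised when spheres overlap and the standard RPY variant is in use."""


class MobilitySingularityError(RuntimeError):
    """Cholesky factorization of the mobility failed (matrix not SPD)."""


class MobilityMatrix:
    """Dense grand mobility with a cached symmetric factorization."""

    def __init__(self, matrix: np.ndarray, radii: np.ndarray, eta: float):
        self.matrix = matrix
        self.radii = radii
        self.eta = eta
        self._factor = None

    @property
    def n_spheres(self) -> int:
        return len(self.radii)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """``M_H^{-1} @ rhs`` via Cholesky; ``rhs`` may be a matrix."""
        if self._factor is None:
            try:
                self._factor = cho_factor(self.matrix, lower=True)
            except np.linalg.LinAlgError as exc:
                raise MobilitySingularityError(
                    "mobility factorization failed; likely overlapping spheres "
                    "without the overlap-corrected variant"
                ) from exc
        return cho_solve(self._factor, rhs)


def _pairwise_geometry(positions: np.ndarray):
    dx = positions[:, None, :] - positions[None, :, :]  # r_ij = x_i - x_j
    d = np.linalg.norm(dx, axis=-1)
    d_safe = np.where(d > 0.0, d, 1.0)
    rhat = dx / d_safe[..., None]
    return dx, d, d_safe, rhat


def _regime_masks(d, ai, aj):
    touch = ai + aj
    far = d >= touch * (1.0 - _CONTACT_RTOL)
    inner = d <= np.abs(ai - aj)
    mid = ~far & ~inner
    return far, mid, inner


def _tt_coeffs(d, ai, aj, eta):
    """Isotropic and rhat-dyadic coefficients of the TT pair block."""
    far, mid, inner = _regime_masks(d, ai, aj)
    a2 = ai**2 + aj**2
    c_iso = np.where(far, (1.0 + a2 / (3.0 * d**2)) / (8.0 * np.pi * eta * d), 0.0)
    c_rr = np.where(far, (1.0 - a2 / d**2) / (8.0 * np.pi * eta * d), 0.0)
    pref = 1.0 / (6.0 * np.pi * eta * ai * aj * 32.0 * d**3)
    c_iso = np.where(
        mid, pref * (16.0 * d**3 * (ai + aj) - ((ai - aj) ** 2 + 3.0 * d**2) ** 2), c_iso
    )
    c_rr = np.where(mid, pref * 3.0 * ((ai - aj) ** 2 - d**2) ** 2, c_rr)
    c_iso = np.where(inner, 1.0 / (6.0 * np.pi * eta * np.maximum(ai, aj)), c_iso)
    c_rr = np.where(inner, 0.0, c_rr)
    return c_iso, c_rr


def _rr_coeffs(d, ai, aj, eta):
    far, mid, inner = _regime_masks(d, ai, aj)
    c_iso = np.where(far, -1.0 / (16.0 * np.pi * eta * d**3), 0.0)
    c_rr = np.where(far, 3.0 / (16.0 * np.pi * eta * d**3), 0.0)
    pref = 1.0 / (8.0 * np.pi * eta * ai**3 * aj**3 * 64.0 * d**3)
    A = (
        5.0 * d**6
        - 27.0 * d**4 * (ai**2 + aj**2)
        + 32.0 * d**3 * (ai**3 + aj**3)
        - 9.0 * d**2 * (ai**2 - aj**2) ** 2
        - (ai - aj) ** 4 * (ai**2 + 4.0 * ai * aj + aj**2)
    )
    B = 3.0 * ((ai - aj) ** 2 - d**2) ** 2 * (ai**2 + 4.0 * ai * aj + aj**2 - d**2)
    c_iso = np.where(mid, pref * A, c_iso)
    c_rr = np.where(mid, pref * B, c_rr)
    c_iso = np.where(inner, 1.0 / (8.0 * np.pi * eta * np.maximum(ai, aj) ** 3), c_iso)
    c_rr = np.where(inner, 0.0, c_rr)
    return c_iso, c_rr


def _tr_gamma(d, ai, aj, eta):
    """Coefficient ``gamma`` of ``mu_tr(i<-j) = -gamma [rhat_ij]_x``.

    ``ai`` is the receiving (translating) sphere, ``aj`` the torqued one.
    """
    far, mid, inner = _regime_masks(d, ai, aj)
    gamma = np.where(far, 1.0 / (8.0 * np.pi * eta * d**2), 0.0)
    g = (
        -((d - ai + aj) ** 2)
        * (3.0 * d**2 - 2.0 * d * ai - 6.0 * d * aj - ai**2 - 2.0 * ai * aj + 3.0 * aj**2)
        / (16.0 * d**2 * ai)
    )
    gamma = np.where(mid, g / (8.0 * np.pi * eta * aj**3), gamma)
    # receiver inside torqued sphere: rigid advection; torqued sphere inside
    # receiver: the surface average of the rotlet over an enclosing sphere
    # vanishes identically
    gamma = np.where(
        inner & (aj > ai), d / (8.0 * np.pi * eta * aj**3), gamma
    )
    gamma = np.where(inner & (ai >= aj), 0.0, gamma)
    return gamma


def _check_overlaps(d, ai, aj):
    touch = (ai + aj) * (1.0 - _CONTACT_RTOL)
    off = ~np.eye(d.shape[0], dtype=bool)
    bad = (d < touch) & off
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise OverlappingSpheresError(
            f"spheres {i} and {j} overlap (separation {d[i, j]:.6g} < "
            f"{ai[i, j] + aj[i, j]:.6g}); use overlap_corrected=True"
        )


def _blocks_to_matrix(blocks: np.ndarray) -> np.ndarray:
    """(M, M, 3, 3) pair blocks -> (3M, 3M)."""
    m = blocks.shape[0]
    return blocks.transpose(0, 2, 1, 3).reshape(3 * m, 3 * m)


def rpy_mobility(
    positions,
    radii,
    eta: float = 1.0,
    mask=None,
    overlap_corrected: bool = False,
) -> MobilityMatrix:
    """Assemble the dense 6M x 6M RPY grand mobility.

    Parameters
    ----------
    positions : (M, 3) array of sphere centres.
    radii : (M,) array of sphere radii, all positive.
    eta : fluid viscosity.
    mask : optional (M, M) boolean array; pair couplings with a False entry
        are zeroed (self mobilities always kept).  Used for "reduced
        coupling" runs that switch off cross-structure hydrodynamics.
    overlap_corrected : use the overlap-regularized tensors, which remain
        positive-definite as pair separations go to zero.  With the
        standard variant any overlapping pair raises
        ``OverlappingSpheresError``.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0.0):
        raise ValueError("all sphere radii must be positive")
    m = len(radii)
    _, d, d_safe, rhat = _pairwise_geometry(positions)
    ai = np.broadcast_to(radii[:, None], (m, m))
    aj = np.broadcast_to(radii[None, :], (m, m))
    if not overlap_corrected:
        _check_overlaps(d, ai, aj)

    eye = np.eye(3)
    diag = np.eye(m, dtype=bool)
    rr_dyad = rhat[..., :, None] * rhat[..., None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        d_off = np.where(diag, 1.0, d_safe)
        tt_iso, tt_rr = _tt_coeffs(d_off, ai, aj, eta)
        rr_iso, rr_rr = _rr_coeffs(d_off, ai, aj, eta)
        gamma_tr = _tr_gamma(d_off, ai, aj, eta)
        gamma_rt = _tr_gamma(d_off, aj, ai, eta)  # swapped roles, transposed

    keep = np.ones((m, m), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    pair_keep = (keep & ~diag).astype(float)[..., None, None]

    tt = (tt_iso[..., None, None] * eye + tt_rr[..., None, None] * rr_dyad) * pair_keep
    rrb = (rr_iso[..., None, None] * eye + rr_rr[..., None, None] * rr_dyad) * pair_keep
    crosses = np.zeros((m, m, 3, 3))
    crosses[..., 0, 1] = -rhat[..., 2]
    crosses[..., 0, 2] = rhat[..., 1]
    crosses[..., 1, 0] = rhat[..., 2]
    crosses[..., 1, 2] = -rhat[..., 0]
    crosses[..., 2, 0] = -rhat[..., 1]
    crosses[..., 2, 1] = rhat[..., 0]
    tr = -gamma_tr[..., None, None] * crosses * pair_keep
    rt = -gamma_rt[..., None, None] * crosses * pair_keep

    idx = np.arange(m)
    tt[idx, idx] = eye / (6.0 * np.pi * eta * radii)[:, None, None]
    rrb[idx, idx] = eye / (8.0 * np.pi * eta * radii**3)[:, None, None]

    matrix = np.empty((6 * m, 6 * m))
    matrix[: 3 * m, : 3 * m] = _blocks_to_matrix(tt)
    matrix[: 3 * m, 3 * m :] = _blocks_to_matrix(tr)
    matrix[3 * m :, : 3 * m] = _blocks_to_matrix(rt)
    matrix[3 * m :, 3 * m :] = _blocks_to_matrix(rrb)
    return MobilityMatrix(matrix, radii, eta)


def apply_inverse_mobility(mobility: MobilityMatrix, rhs: np.ndarray) -> np.ndarray:
    """Solve ``M_H X = rhs`` through the cached symmetric factorization."""
    return mobility.solve(rhs)


def group_mask(groups) -> np.ndarray:
    """Mask keeping only couplings between spheres with equal group label."""
    groups = np.asarray(groups)
    return groups[:, None] == groups[None, :]


def tracer_velocities(
    positions,
    radii,
    forces,
    torques,
    tracer_positions,
    tracer_radius: float,
    eta: float = 1.0,
    overlap_corrected: bool = True,
) -> np.ndarray:
    """Advection velocities of force- and torque-free tracer spheres.

    One-way coupling: a force-free, torque-free RPY sphere does not perturb
    the rest of the system, so tracers only read off the flow

        v_t = sum_k mu_tt(t, k) F_k + mu_tr(t, k) T_k.
    """
    positions = np.asarray(positions, dtype=float)
    tracer_positions = np.atleast_2d(np.asarray(tracer_positions, dtype=float))
    radii = np.asarray(radii, dtype=float)
    forces = np.asarray(forces, dtype=float).reshape(-1, 3)
    torques = np.asarray(torques, dtype=float).reshape(-1, 3)

    dx = tracer_positions[:, None, :] - positions[None, :, :]
    d = np.linalg.norm(dx, axis=-1)
    if not overlap_corrected and np.any(d < (tracer_radius + radii) * (1.0 - _CONTACT_RTOL)):
        raise OverlappingSpheresError("tracer overlaps a system sphere")
    d_safe = np.where(d > 0.0, d, 1.0)
    rhat = dx / d_safe[..., None]
    at = np.full_like(d, tracer_radius)
    ak = np.broadcast_to(radii[None, :], d.shape)
    tt_iso, tt_rr = _tt_coeffs(d_safe, at, ak, eta)
    gamma = _tr_gamma(d_safe, at, ak, eta)

    v = tt_iso @ forces + np.einsum("tk,tki,tkj,kj->ti", tt_rr, rhat, rhat, forces)
    # mu_tr contribution: -gamma [rhat]x T = -gamma (rhat x T)
    v -= np.einsum("tk,tki->ti", gamma, np.cross(rhat, torques[None, :, :]))
    return v
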