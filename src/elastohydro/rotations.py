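"""Quaternion / exponential-map rotation algebra.

Conventions
-----------
* Quaternions are scalar-first arrays ``q = (q0, q1, q2, q3)`` and act on
  vectors as an *active* rotation ``v' = q v q^{-1}`` taking reference-frame
  components to the lab frame.
* A rotation can equivalently be stored as a *generator* ``r``, a pure
  3-vector whose quaternion exponential ``exp(r) = [cos|r|, sinc|r| r]``
  encodes a rotation by angle ``2|r|`` about ``r/|r|``.
* Angular velocities are lab-frame throughout: ``q_dot = C(q) w`` and
  ``w = 2 D(r) r_dot``.

All functions accept plain sequences and return ``numpy`` arrays.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "GeneratorSingularityError",
    "quat_from_axis_angle",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "rotation_matrix",
    "exp_map",
    "dmatrix",
    "rescale_generator",
    "directors_from_generator",
    "cmatrix",
    "cross_matrix",
]

_RESCALE_THRESHOLD = np.pi / 2.0
# below this magnitude the sinc-family coefficients switch to Taylor series
_SERIES_CUTOFF = 1e-4


class GeneratorSingularityError(ValueError):
    """Generator magnitude landed on a coordinate singularity |r| = n*pi.

    This signals a missed rescaling event: integration should rescale any
    generator with |r| >= pi/2 between accepted steps.
    """


def _sinc(x: float) -> float:
    """sin(x)/x with a series branch near zero."""
    if abs(x) < _SERIES_CUTOFF:
        x2 = x * x
        return 1.0 - x2 / 6.0 + x2 * x2 / 120.0
    return np.sin(x) / x


def quat_from_axis_angle(axis, theta: float, strict: bool = False) -> np.ndarray:
    """Unit quaternion for a rotation by ``theta`` about ``axis``.

    Parameters
    ----------
    axis : array_like, shape (3,)
        Rotation axis; must be unit length to 1e-9 unless ``strict`` is
        False, in which case it is normalized.
    theta : float
        Rotation angle in radians.
    strict : bool
        If True, a non-unit axis raises ``ValueError`` instead of being
        normalized.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-9:
        if strict or norm == 0.0:
            raise ValueError(f"axis must be unit length, got |axis| = {norm!r}")
        warnings.warn(f"normalizing non-unit axis (|axis| = {norm:.3g})", stacklevel=2)
        axis = axis / norm
    half = 0.5 * theta
    return np.concatenate(([np.cos(half)], np.sin(half) * axis))


def quat_multiply(q1, q2) -> np.ndarray:
    """Hamilton product ``q1 * q2`` (scalar-first)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, v1 = q1[0], q1[1:]
    w2, v2 = q2[0], q2[1:]
    return np.concatenate(
        ([w1 * w2 - v1 @ v2], w1 * v2 + w2 * v1 + np.cross(v1, v2))
    )


def quat_conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.concatenate(([q[0]], -q[1:]))


def rotation_matrix(q) -> np.ndarray:
    """3x3 rotation matrix of the active rotation ``v' = q v q^{-1}``."""
    q0, q1, q2, q3 = np.asarray(q, dtype=float)
    return np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2.0 * (q1 * q2 - q0 * q3),
                2.0 * (q1 * q3 + q0 * q2),
            ],
            [
                2.0 * (q1 * q2 + q0 * q3),
                q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                2.0 * (q2 * q3 - q0 * q1),
            ],
            [
                2.0 * (q1 * q3 - q0 * q2),
                2.0 * (q2 * q3 + q0 * q1),
                q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
            ],
        ]
    )


def quat_rotate(q, v) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion ``q``.

    ``v`` may be shape (3,) or (n, 3); rotation is applied row-wise.
    """
    v = np.asarray(v, dtype=float)
    R = rotation_matrix(q)
    if v.ndim == 1:
        return R @ v
    return v @ R.T


def exp_map(r) -> np.ndarray:
    """Quaternion exponential of a generator: ``[cos|r|, sinc|r| r]``."""
    r = np.asarray(r, dtype=float)
    mag = np.linalg.norm(r)
    return np.concatenate(([np.cos(mag)], _sinc(mag) * r))


def dmatrix(r) -> np.ndarray:
    """Kinematic matrix ``D(r)`` with ``w = 2 D(r) r_dot``.

    Raises
    ------
    GeneratorSingularityError
        If ``|r|`` sits within 1e-9 of ``n*pi`` for integer ``n >= 1``
        (``det D = sinc^2 |r|`` vanishes there); a properly rescaled state
        never reaches this region.
    """
    r = np.asarray(r, dtype=float)
    mag = np.linalg.norm(r)
    n_pi = round(mag / np.pi)
    if n_pi >= 1 and abs(mag - n_pi * np.pi) < 1e-9:
        raise GeneratorSingularityError(
            f"|r| = {mag!r} is within 1e-9 of {n_pi}*pi; rescaling was missed"
        )
    if mag < _SERIES_CUTOFF:
        m2 = mag * mag
        c_cross = 1.0 - m2 / 3.0 + 2.0 * m2 * m2 / 45.0       # sin^2 x / x^2
        c_outer = 2.0 / 3.0 - 2.0 * m2 / 15.0 + 4.0 * m2 * m2 / 315.0
    else:
        c_cross = (np.sin(mag) / mag) ** 2
        c_outer = (mag - np.sin(mag) * np.cos(mag)) / mag**3
    # |r|^2 I - r r^T  is the "outer" part written out in component form
    return (
        np.eye(3)
        + c_cross * cross_matrix(r)
        - c_outer * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    )


def rescale_generator(r) -> np.ndarray:
    """Map ``r -> r - pi * r/|r|`` whenever ``|r| >= pi/2``.

    The returned generator encodes the same rotation (its quaternion is
    ``-exp(r)``) but stays away from the ``|r| = n*pi`` singularities.
    """
    r = np.asarray(r, dtype=float)
    mag = np.linalg.norm(r)
    if mag >= _RESCALE_THRESHOLD:
        return r - np.pi * r / mag
    return r


def directors_from_generator(r) -> np.ndarray:
    """Director basis obtained by rotating the lab canonical basis.

    Returns a 3x3 matrix whose *columns* are ``d1, d2, d3``; equal to the
    rotation matrix of ``exp(r)``.
    """
    return rotation_matrix(exp_map(r))


def cmatrix(q) -> np.ndarray:
    """4x3 matrix ``C(q)`` with ``q_dot = C(q) w`` for lab-frame ``w``."""
    q0, q1, q2, q3 = np.asarray(q, dtype=float)
    return 0.5 * np.array(
        [
            [-q1, -q2, -q3],
            [q0, q3, -q2],
            [-q3, q0, q1],
            [q2, -q1, q0],
        ]
    )


def cross_matrix(a) -> np.ndarray:
    """Matrix form of the cross product: ``cross_matrix(a) @ b == a x b``."""
    a1, a2, a3 = np.asarray(a, dtype=float)
    return np.array(
        [
            [0.0, -a3, a2],
            [a3, 0.0, -a1],
            [-a2, a1, 0.0],
        ]
    )
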