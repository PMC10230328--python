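"""Construction of filaments, sphere-built bodies and articulated structures.

A :class:`Structure` couples one (optional) rigid body with any number of
clamped filaments.  Filaments are chains of ``N`` rigid segments of length
``ds = L/N``, each carrying ``n`` touching spheres on its centreline; the
chain is exactly inextensible because segment endpoints are reconstructed
from the running sum of segment tangents.

State layout (per structure, concatenated into the global state vector):

* free body or free filament: ``[x_b (3), r_b (3), r_2 .. r_N per filament]``
* fixed body (e.g. a wall): ``[r_2 .. r_N per filament]`` only.

For a body-less filament the "body" frame is the first segment
(``x_b = x_1``, ``r_b = r_1``).  Clamped first segments carry no state of
their own: their orientation is the body orientation composed with the
clamp rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .rotations import exp_map, quat_multiply, rotation_matrix

__all__ = [
    "Filament",
    "Body",
    "Attachment",
    "Structure",
    "Assembly",
    "segment_endpoints",
    "build_spherical_body",
    "build_wall",
    "attach_filament",
]

_IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


@dataclass
class Filament:
    """Discretized Kirchhoff filament.

    Parameters
    ----------
    N : number of rigid segments (>= 2).
    n : spheres per segment (>= 1).
    length : total arclength ``L`` (sets ``ds = L/N``).
    Eb, Et : bending and torsional stiffness.
    radius : sphere radius; defaults to ``ds/(2n)`` so spheres touch.
    preferred_curvature : optional ``f(s, t) -> (k1, k2, k3)`` drive,
        components in the local director basis.
    active_moment : optional active moment density ``m_a(s, t) -> (3,)``,
        components in the local director basis.
    """

    N: int
    n: int = 1
    length: float = 1.0
    Eb: float = 1.0
    Et: float = 1.0
    radius: Optional[float] = None
    preferred_curvature: Optional[Callable] = None
    active_moment: Optional[Callable] = None

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("filament needs at least N = 2 segments")
        if self.n < 1:
            raise ValueError("filament needs at least n = 1 sphere per segment")
        if self.radius is None:
            self.radius = self.ds / (2 * self.n)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def ds(self) -> float:
        return self.length / self.N

    @property
    def n_spheres(self) -> int:
        return self.N * self.n

    def joint_arclengths(self) -> np.ndarray:
        """Arclengths ``s_j = (j-1) ds`` of the interior joints j=2..N."""
        return self.ds * np.arange(1, self.N)

    def local_sphere_offsets(self) -> np.ndarray:
        """Sphere centre offsets from the segment start, along the tangent."""
        return (np.arange(1, self.n + 1) - 0.5) * (self.ds / self.n)


@dataclass
class Body:
    """Rigid body made of spheres; offsets are in the body frame."""

    offsets: np.ndarray
    radii: np.ndarray
    fixed: bool = False

    def __post_init__(self):
        self.offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.offsets.shape[0] != self.radii.shape[0]:
            raise ValueError("offsets and radii must have the same length")

    @property
    def n_spheres(self) -> int:
        return self.offsets.shape[0]


@dataclass
class Attachment:
    """A filament clamped to the body frame.

    ``offset`` is the position of the filament base ``x_1`` relative to
    ``x_b`` in the body basis; ``clamp`` is the quaternion orienting the
    first segment relative to the body frame.
    """

    filament: Filament
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    clamp: np.ndarray = field(default_factory=lambda: _IDENTITY_QUAT.copy())

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)
        self.clamp = (
            _IDENTITY_QUAT.copy()
            if self.clamp is None
            else np.asarray(self.clamp, dtype=float)
        )


def segment_endpoints(x1, directors, ds: float) -> np.ndarray:
    """Segment start points ``x_i = x_1 + ds * sum_{j<i} d3_j`` (exact).

    ``directors`` is an (N, 3, 3) stack whose columns are ``d1, d2, d3``.
    """
    d3 = np.asarray(directors)[:, :, 2]
    pts = np.empty((len(d3), 3))
    pts[0] = np.asarray(x1, dtype=float)
    np.cumsum(ds * d3[:-1], axis=0, out=pts[1:])
    pts[1:] += pts[0]
    return pts


@dataclass
class FilamentFrame:
    """Lab-frame geometry of one filament at a given state."""

    x1: np.ndarray            # (3,) base point
    directors: np.ndarray     # (N, 3, 3), columns d1,d2,d3
    endpoints: np.ndarray     # (N, 3) segment start points x_i
    positions: np.ndarray     # (N*n, 3) sphere centres


@dataclass
class StructureFrame:
    """Lab-frame geometry of one structure at a given state."""

    x_b: np.ndarray
    R_b: np.ndarray                 # body rotation matrix
    body_positions: np.ndarray      # (Nbody, 3)
    filaments: list                 # list[FilamentFrame]
    positions: np.ndarray           # (M, 3) body spheres then filament spheres
    radii: np.ndarray


class Structure:
    """One rigid body (possibly absent or fixed) plus clamped filaments."""

    def __init__(
        self,
        body: Optional[Body] = None,
        attachments: Sequence[Attachment] = (),
        fixed_position=None,
        fixed_generator=None,
    ):
        self.body = body
        self.attachments = list(attachments)
        if body is None and len(self.attachments) != 1:
            raise ValueError("a body-less structure must hold exactly one filament")
        self.fixed = body is not None and body.fixed
        self.fixed_position = (
            np.zeros(3) if fixed_position is None else np.asarray(fixed_position, float)
        )
        self.fixed_generator = (
            np.zeros(3) if fixed_generator is None else np.asarray(fixed_generator, float)
        )

    # ---- bookkeeping -------------------------------------------------
    @property
    def n_body_spheres(self) -> int:
        return 0 if self.body is None else self.body.n_spheres

    @property
    def n_spheres(self) -> int:
        return self.n_body_spheres + sum(a.filament.n_spheres for a in self.attachments)

    @property
    def state_size(self) -> int:
        n = 0 if self.fixed else 6
        return n + sum(3 * (a.filament.N - 1) for a in self.attachments)

    def split_state(self, state: np.ndarray):
        """-> (x_b, r_b, [generators (N-1, 3) per filament])."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.state_size,):
            raise ValueError(
                f"state has size {state.size}, expected {self.state_size}"
            )
        if self.fixed:
            x_b, r_b = self.fixed_position, self.fixed_generator
            rest = state
        else:
            x_b, r_b, rest = state[:3], state[3:6], state[6:]
        gens = []
        k = 0
        for a in self.attachments:
            m = 3 * (a.filament.N - 1)
            gens.append(rest[k : k + m].reshape(-1, 3))
            k += m
        return x_b, r_b, gens

    def generators(self, state: np.ndarray) -> np.ndarray:
        """All generator 3-vectors in this structure's state, as (G, 3)."""
        if self.fixed:
            return np.asarray(state, dtype=float).reshape(-1, 3)
        return np.asarray(state, dtype=float)[3:].reshape(-1, 3)

    # ---- geometry ----------------------------------------------------
    def frame(self, state: np.ndarray) -> StructureFrame:
        x_b, r_b, gens = self.split_state(state)
        q_b = exp_map(r_b)
        quats = [np.array([exp_map(r) for r in g]) for g in gens]
        return self.frame_quat(x_b, q_b, quats)

    def frame_quat(self, x_b, q_b, quats) -> StructureFrame:
        """Geometry from explicit quaternions (shared with the quaternion
        integration backend); ``quats`` holds an (N-1, 4) array per
        filament for segments 2..N."""
        R_b = rotation_matrix(q_b)
        if self.body is not None and self.body.n_spheres > 0:
            body_pos = x_b + self.body.offsets @ R_b.T
            body_rad = self.body.radii
        else:
            body_pos = np.zeros((0, 3))
            body_rad = np.zeros(0)

        fil_frames = []
        all_pos = [body_pos]
        all_rad = [body_rad]
        for a, qs in zip(self.attachments, quats):
            fil = a.filament
            x1 = x_b + R_b @ a.offset
            directors = np.empty((fil.N, 3, 3))
            directors[0] = rotation_matrix(quat_multiply(q_b, a.clamp))
            for i in range(1, fil.N):
                directors[i] = rotation_matrix(qs[i - 1])
            endpoints = segment_endpoints(x1, directors, fil.ds)
            offs = fil.local_sphere_offsets()
            pos = (
                endpoints[:, None, :]
                + offs[None, :, None] * directors[:, None, :, 2]
            ).reshape(-1, 3)
            fil_frames.append(FilamentFrame(x1, directors, endpoints, pos))
            all_pos.append(pos)
            all_rad.append(np.full(fil.n_spheres, fil.radius))
        return StructureFrame(
            x_b=np.asarray(x_b, float),
            R_b=R_b,
            body_positions=body_pos,
            filaments=fil_frames,
            positions=np.vstack(all_pos),
            radii=np.concatenate(all_rad),
        )


class Assembly:
    """A collection of structures with global sphere / state indexing."""

    def __init__(self, structures: Sequence[Structure]):
        self.structures = list(structures)
        if not self.structures:
            raise ValueError("assembly needs at least one structure")
        self.state_offsets = np.cumsum([0] + [s.state_size for s in self.structures])
        self.sphere_offsets = np.cumsum([0] + [s.n_spheres for s in self.structures])

    @property
    def state_size(self) -> int:
        return int(self.state_offsets[-1])

    @property
    def n_spheres(self) -> int:
        return int(self.sphere_offsets[-1])

    def split_state(self, state: np.ndarray):
        state = np.asarray(state, dtype=float)
        if state.shape != (self.state_size,):
            raise ValueError(
                f"state has size {state.size}, expected {self.state_size}"
            )
        return [
            state[self.state_offsets[i] : self.state_offsets[i + 1]]
            for i in range(len(self.structures))
        ]

    def frames(self, state: np.ndarray):
        return [
            s.frame(sub) for s, sub in zip(self.structures, self.split_state(state))
        ]

    def generator_offsets(self) -> np.ndarray:
        """Global state offsets of every generator 3-vector (r_b and r_i)."""
        offs = []
        for i, s in enumerate(self.structures):
            base = self.state_offsets[i]
            if s.fixed:
                offs.extend(range(base, self.state_offsets[i + 1], 3))
            else:
                offs.extend(range(base + 3, self.state_offsets[i + 1], 3))
        return np.array(offs, dtype=int)

    def sphere_positions(self, state: np.ndarray):
        """-> (positions (M, 3), radii (M,), structure id (M,))."""
        frames = self.frames(state)
        pos = np.vstack([f.positions for f in frames])
        rad = np.concatenate([f.radii for f in frames])
        sid = np.concatenate(
            [np.full(s.n_spheres, i) for i, s in enumerate(self.structures)]
        )
        return pos, rad, sid


# ---- geometry builders ----------------------------------------------


def build_spherical_body(
    R: float, N_body: int, sphere_radius: Optional[float] = None, fixed: bool = False
) -> Body:
    """Spherical shell of ``N_body`` spheres on a Fibonacci lattice.

    ``N_body = 1`` degenerates to a single sphere of radius ``R`` at the
    centre.  The per-sphere radius defaults to half the expected
    nearest-neighbour distance of the lattice, so neighbours roughly touch.
    """
    if N_body < 1:
        raise ValueError("N_body must be >= 1")
    if N_body == 1:
        return Body(offsets=np.zeros((1, 3)), radii=np.array([R]), fixed=fixed)
    k = np.arange(N_body)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / N_body
    theta = 2.0 * np.pi * k / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    offsets = R * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    if sphere_radius is None:
        # hexagonal-packing estimate of the nearest-neighbour spacing
        sphere_radius = 0.5 * R * np.sqrt(8.0 * np.pi / (np.sqrt(3.0) * N_body))
    return Body(offsets=offsets, radii=np.full(N_body, sphere_radius), fixed=fixed)


def build_wall(nx: int, ny: int, spacing: float) -> Body:
    """Fixed planar monolayer of touching spheres in the z = 0 plane."""
    if nx < 1 or ny < 1:
        raise ValueError("wall needs nx, ny >= 1")
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (ix.ravel() - (nx - 1) / 2.0) * spacing
    y = (iy.ravel() - (ny - 1) / 2.0) * spacing
    offsets = np.column_stack([x, y, np.zeros(nx * ny)])
    return Body(offsets=offsets, radii=np.full(nx * ny, spacing / 2.0), fixed=True)


def attach_filament(structure: Structure, filament: Filament, offset, clamp=None) -> Structure:
    """Return a new structure with one more clamped filament."""
    clamp = _IDENTITY_QUAT.copy() if clamp is None else np.asarray(clamp, float)
    return Structure(
        body=structure.body,
        attachments=structure.attachments + [Attachment(filament, offset, clamp)],
        fixed_position=structure.fixed_position,
        fixed_generator=structure.fixed_generator,
    )
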