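"""Dimensionality reduction: rigid-chain kinematics ``[V; Omega] = Q W``.

The reduced velocity ``W`` stacks, per structure, the body translational
velocity ``x_b_dot``, the body angular velocity ``omega_b`` and the angular
velocities ``omega_i`` of the non-clamped segments (i = 2..N of each
filament) -- the same layout as the structure state, so ``W = D_blk X_dot``.

Sphere velocities follow from the rigid chain:

* body sphere:              ``v = x_b_dot + omega_b x (y - x_b)``
* sphere in segment 1:      rigid with the body (clamped)
* sphere in segment i >= 2: ``v = x_b_dot + omega_b x (x_2 - x_b)
  + sum_{j=2}^{i-1} omega_j x (ds d3_j) + omega_i x (y - x_i)``

and every sphere's angular velocity equals its segment's (or the body's).
Fixed bodies contribute no reduced coordinates: their spheres and clamped
first segments are immobile.
"""

from __future__ import annotations

import numpy as np

from .assembly import Assembly
from .rotations import cross_matrix

__all__ = ["assemble_Q", "reduced_dimension"]


def reduced_dimension(assembly: Assembly) -> int:
    """Number of reduced velocity coordinates (equals the state size)."""
    return assembly.state_size


def assemble_Q(assembly: Assembly, frames) -> np.ndarray:
    """Assemble the reduction operator, shape (6M, state_size).

    Rows 0..3M-1 are sphere linear velocities, rows 3M..6M-1 angular
    velocities, in the global sphere order; block-diagonal across
    structures.
    """
    m = assembly.n_spheres
    Q = np.zeros((6 * m, assembly.state_size))
    eye = np.eye(3)
    for si, (structure, frame) in enumerate(zip(assembly.structures, frames)):
        col0 = assembly.state_offsets[si]
        sph0 = assembly.sphere_offsets[si]
        has_body_dofs = not structure.fixed
        cx, cw = col0, col0 + 3  # x_b_dot and omega_b column blocks
        # body spheres
        for k in range(structure.n_body_spheres):
            rv = 3 * (sph0 + k)
            rw = 3 * m + rv
            if has_body_dofs:
                Q[rv : rv + 3, cx : cx + 3] = eye
                Q[rv : rv + 3, cw : cw + 3] = -cross_matrix(
                    frame.positions[k] - frame.x_b
                )
                Q[rw : rw + 3, cw : cw + 3] = eye
        # filament spheres
        cseg = col0 + (6 if has_body_dofs else 0)  # first omega_2 block
        ksph = sph0 + structure.n_body_spheres
        for a, ff in zip(structure.attachments, frame.filaments):
            fil = a.filament
            ds_d3 = fil.ds * ff.directors[:, :, 2]
            for i in range(1, fil.N + 1):  # segment index
                x_i = ff.endpoints[i - 1]
                for _ in range(fil.n):
                    y = frame.positions[ksph - sph0]
                    rv = 3 * ksph
                    rw = 3 * m + rv
                    if has_body_dofs:
                        Q[rv : rv + 3, cx : cx + 3] = eye
                        if i == 1:
                            Q[rv : rv + 3, cw : cw + 3] = -cross_matrix(y - frame.x_b)
                        else:
                            # body block carries the chain up to x_2
                            x_2 = ff.endpoints[1]
                            Q[rv : rv + 3, cw : cw + 3] = -cross_matrix(x_2 - frame.x_b)
                    if i >= 2:
                        for j in range(2, i):
                            cj = cseg + 3 * (j - 2)
                            Q[rv : rv + 3, cj : cj + 3] = -cross_matrix(ds_d3[j - 1])
                        ci = cseg + 3 * (i - 2)
                        Q[rv : rv + 3, ci : ci + 3] = -cross_matrix(y - x_i)
                        Q[rw : rw + 3, ci : ci + 3] = eye
                    elif has_body_dofs:
                        Q[rw : rw + 3, cw : cw + 3] = eye
                    ksph += 1
            cseg += 3 * (fil.N - 1)
        sph_check = sph0 + structure.n_spheres
        assert ksph == sph_check
    return Q
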