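"""Assembly and stiff integration of the governing elastohydrodynamic ODE.

Exponential-map backend (default): ``M_F M_H^{-1} Q D_blk X_dot = K`` with
``D_blk = blockdiag(I_3, 2 D(r_b), 2 D(r_2), ...)`` so that the reduced
velocity is ``W = D_blk X_dot``.  Generators are rescaled between accepted
integrator steps whenever a magnitude crosses ``pi/2`` (with a small event
margin so that states sitting exactly at the threshold do not re-trigger),
and integration restarts from the rescaled state.

Quaternion backend (cross-validation): solves ``M_F M_H^{-1} Q W = K`` for
the reduced velocity and propagates ``q_dot = C(q) omega`` per rotational
unit; no rescaling is needed but the system is larger and lacks the
built-in unit-norm property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .assembly import Assembly
from .cg_mechanics import assemble_K, assemble_MF
from .hydrodynamics import rpy_mobility
from .reduction import assemble_Q
from .rotations import cmatrix, dmatrix, exp_map, rescale_generator

__all__ = [
    "Nondimensionalization",
    "KinematicConstraint",
    "GoverningSystem",
    "QuaternionBackend",
    "Trajectory",
    "integrate",
]

_RESCALE_EVENT_MARGIN = 0.05 * np.pi


@dataclass
class Nondimensionalization:
    """Stiffness parameter bookkeeping: ``S^4 = L^4 eta omega / Eb``.

    With lengths in units of ``L``, time in units of the drive frequency
    and ``Eb = Et = 1``, the viscosity entering the mobility is ``S^4``.
    """

    S: float

    def __post_init__(self):
        if self.S <= 0:
            raise ValueError("stiffness parameter S must be positive")

    @property
    def eta(self) -> float:
        return self.S**4

    @property
    def elastohydrodynamic_number(self) -> float:
        return 8.0 * np.pi * self.S**4

    def sperm_number4(self, L_over_a: float) -> float:
        """``Sp^4 = (4 pi / (log(L/a) + 0.5)) S^4`` (slender-body drag)."""
        return 4.0 * np.pi / (np.log(L_over_a) + 0.5) * self.S**4

    @classmethod
    def from_sperm_number4(cls, Sp4: float, L_over_a: float):
        return cls((Sp4 * (np.log(L_over_a) + 0.5) / (4.0 * np.pi)) ** 0.25)


@dataclass
class KinematicConstraint:
    """Replace a structure's global balance rows with prescribed rates.

    ``kind = "position"`` replaces the force-balance rows with
    ``x_b_dot = rate(t)``; ``kind = "orientation"`` replaces the
    torque-balance rows with ``r_b_dot = rate(t)``.  For the quaternion
    backend an orientation constraint additionally needs ``omega_rate``,
    the prescribed angular velocity ``omega_b(t)``.
    """

    structure: int
    kind: str
    rate: Callable[[float], np.ndarray]
    omega_rate: Optional[Callable[[float], np.ndarray]] = None

    def __post_init__(self):
        if self.kind not in ("position", "orientation"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")


class GoverningSystem:
    """Exponential-map right-hand side and operator bookkeeping."""

    def __init__(
        self,
        assembly: Assembly,
        eta: float = 1.0,
        mask=None,
        overlap_corrected: bool = False,
        constraints: Sequence[KinematicConstraint] = (),
    ):
        self.assembly = assembly
        self.eta = eta
        self.mask = mask
        self.overlap_corrected = overlap_corrected
        self.constraints = list(constraints)
        self._check_constraints()

    def _check_constraints(self):
        seen = set()
        for c in self.constraints:
            if self.assembly.structures[c.structure].fixed:
                raise ValueError("cannot constrain a fixed structure")
            key = (c.structure, c.kind)
            if key in seen:
                raise ValueError(f"duplicate constraint {key}")
            seen.add(key)

    def _constraint_rows(self, c: KinematicConstraint):
        base = self.assembly.state_offsets[c.structure]
        return (base, base + 3) if c.kind == "position" else (base + 3, base + 6)

    def d_block(self, state: np.ndarray) -> np.ndarray:
        """``W = D_blk X_dot``: identity on translations, 2 D(r) per generator."""
        n = self.assembly.state_size
        D = np.zeros((n, n))
        for i, s in enumerate(self.assembly.structures):
            base = self.assembly.state_offsets[i]
            k = base
            if not s.fixed:
                D[k : k + 3, k : k + 3] = np.eye(3)
                k += 3
            for r in s.generators(state[base : self.assembly.state_offsets[i + 1]]):
                D[k : k + 3, k : k + 3] = 2.0 * dmatrix(r)
                k += 3
        return D

    def operators(self, t: float, state: np.ndarray):
        """Assemble (frames, M_H, M_F, Q, K) at the given state."""
        frames = self.assembly.frames(state)
        pos = np.vstack([f.positions for f in frames])
        rad = np.concatenate([f.radii for f in frames])
        MH = rpy_mobility(
            pos, rad, eta=self.eta, mask=self.mask,
            overlap_corrected=self.overlap_corrected,
        )
        MF = assemble_MF(self.assembly, frames)
        Q = assemble_Q(self.assembly, frames)
        K = assemble_K(self.assembly, frames, t)
        return frames, MH, MF, Q, K

    def _reduced_system(self, t, state, velocity_matrix):
        """L = M_F M_H^{-1} (velocity_matrix), with constraint rows applied."""
        frames, MH, MF, Q, K = self.operators(t, state)
        B = MH.solve(velocity_matrix(Q, state))
        L = MF @ B
        K = K.copy()
        for c in self.constraints:
            lo, hi = self._constraint_rows(c)
            L[lo:hi, :] = 0.0
            L[lo:hi, lo:hi] = np.eye(3)
            K[lo:hi] = np.asarray(c.rate(t), dtype=float)
        return frames, MH, Q, L, K

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        """``X_dot`` from the dense solve of ``L X_dot = K``."""
        _, _, _, L, K = self._reduced_system(
            t, state, lambda Q, s: Q @ self.d_block(s)
        )
        try:
            return np.linalg.solve(L, K)
        except np.linalg.LinAlgError as exc:
            mags = [
                np.linalg.norm(state[o : o + 3])
                for o in self.assembly.generator_offsets()
            ]
            raise RuntimeError(
                f"singular reduced operator at t={t}; generator magnitudes "
                f"max {max(mags):.4f} (singularity at pi = {np.pi:.4f})"
            ) from exc

    def solve_velocities(self, t: float, state: np.ndarray):
        """Full solve returning (X_dot, W, forces, torques) for diagnostics."""
        frames, MH, Q, L, K = self._reduced_system(
            t, state, lambda Q, s: Q @ self.d_block(s)
        )
        xdot = np.linalg.solve(L, K)
        W = self.d_block(state) @ xdot
        FT = np.linalg.solve(MH.matrix, Q @ W)
        m = self.assembly.n_spheres
        return xdot, W, FT[: 3 * m].reshape(-1, 3), FT[3 * m :].reshape(-1, 3)

    def balance_residual(self, t: float, state: np.ndarray) -> float:
        """Relative residual of ``M_F [F; T] = K`` after the solve."""
        frames, MH, MF, Q, K = self.operators(t, state)
        Db = self.d_block(state)
        L = MF @ MH.solve(Q @ Db)
        Kc = K.copy()
        for c in self.constraints:
            lo, hi = self._constraint_rows(c)
            L[lo:hi, :] = 0.0
            L[lo:hi, lo:hi] = np.eye(3)
            Kc[lo:hi] = np.asarray(c.rate(t), dtype=float)
        xdot = np.linalg.solve(L, Kc)
        FT = np.linalg.solve(MH.matrix, Q @ (Db @ xdot))
        resid = MF @ FT - K
        for c in self.constraints:  # constrained rows do not carry balance
            lo, hi = self._constraint_rows(c)
            resid[lo:hi] = 0.0
        scale = max(np.max(np.abs(K)), 1.0)
        return np.max(np.abs(resid)) / scale


@dataclass
class Trajectory:
    """Time series of the integrated state with derived geometry access."""

    t: np.ndarray
    states: np.ndarray  # (nt, state_size)
    assembly: Assembly
    rescale_events: int = 0
    solver_steps: int = 0

    def frames(self, i: int):
        return self.assembly.frames(self.states[i])

    def sphere_positions(self, i: int):
        pos, _, _ = self.assembly.sphere_positions(self.states[i])
        return pos


def _rescale_state(assembly: Assembly, state: np.ndarray) -> np.ndarray:
    state = state.copy()
    for o in assembly.generator_offsets():
        state[o : o + 3] = rescale_generator(state[o : o + 3])
    return state


def integrate(
    system: GoverningSystem,
    state0,
    t_span,
    t_eval=None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "BDF",
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the exponential-map system with between-step rescaling.

    A terminal event fires when any generator magnitude reaches
    ``pi/2 + margin``; every generator with ``|r| >= pi/2`` is then rescaled
    by ``r -> r - pi r/|r|`` and integration restarts.  Output times in
    ``t_eval`` (default: span endpoints) are preserved across restarts.
    """
    assembly = system.assembly
    t0, tf = float(t_span[0]), float(t_span[1])
    if t_eval is None:
        t_eval = np.array([t0, tf])
    t_eval = np.asarray(t_eval, dtype=float)
    gen_offs = assembly.generator_offsets()
    threshold = np.pi / 2.0 + _RESCALE_EVENT_MARGIN

    def rescale_event(t, y):
        mags = np.linalg.norm(y[gen_offs[:, None] + np.arange(3)], axis=1)
        return threshold - np.max(mags)

    rescale_event.terminal = True
    rescale_event.direction = -1

    y = _rescale_state(assembly, np.asarray(state0, dtype=float))
    t = t0
    ts, ys = [], []
    if t_eval[0] == t0:
        ts.append(t0)
        ys.append(y.copy())
    n_events = 0
    n_steps = 0
    while t < tf:
        chunk_eval = t_eval[(t_eval > t) & (t_eval <= tf)]
        sol = solve_ivp(
            system.rhs,
            (t, tf),
            y,
            method=method,
            t_eval=chunk_eval if len(chunk_eval) else None,
            events=rescale_event,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"integration failed at t={t}: {sol.message}")
        n_steps += sol.nfev
        if len(chunk_eval):
            sol_y = np.asarray(sol.y)
            if sol_y.size:
                for tk, yk in zip(sol.t, sol_y.T):
                    ts.append(tk)
                    ys.append(yk.copy())
        if sol.status == 1:  # rescaling event
            t = float(sol.t_events[0][0])
            y = _rescale_state(assembly, sol.y_events[0][0])
            n_events += 1
        else:
            t = tf
            y = sol.y[:, -1] if sol.y.size else y
    return Trajectory(
        t=np.array(ts),
        states=np.array(ys),
        assembly=assembly,
        rescale_events=n_events,
        solver_steps=n_steps,
    )


class QuaternionBackend:
    """Direct quaternion parametrization of the same governing system.

    State layout per structure: ``[x_b (3), q_b (4), q_2..q_N (4 each)]``
    (fixed bodies drop the leading 7 entries).
    """

    def __init__(self, system: GoverningSystem):
        self.system = system
        self.assembly = system.assembly
        sizes = []
        for s in self.assembly.structures:
            n_gen = sum(a.filament.N - 1 for a in s.attachments)
            sizes.append((0 if s.fixed else 7) + 4 * n_gen)
        self.sizes = sizes
        self.offsets = np.cumsum([0] + sizes)

    @property
    def state_size(self) -> int:
        return int(self.offsets[-1])

    def state_from_generators(self, state: np.ndarray) -> np.ndarray:
        out = np.empty(self.state_size)
        for i, s in enumerate(self.assembly.structures):
            sub = self.assembly.split_state(state)[i]
            x_b, r_b, gens = s.split_state(sub)
            k = self.offsets[i]
            if not s.fixed:
                out[k : k + 3] = x_b
                out[k + 3 : k + 7] = exp_map(r_b)
                k += 7
            for g in gens:
                for r in g:
                    out[k : k + 4] = exp_map(r)
                    k += 4
        return out

    def split(self, qstate: np.ndarray):
        """Per structure -> (x_b, q_b, [quats (N-1, 4) per filament])."""
        parts = []
        for i, s in enumerate(self.assembly.structures):
            sub = qstate[self.offsets[i] : self.offsets[i + 1]]
            if s.fixed:
                x_b, q_b = s.fixed_position, exp_map(s.fixed_generator)
                rest = sub
            else:
                x_b, q_b = sub[:3], sub[3:7] / np.linalg.norm(sub[3:7])
                rest = sub[7:]
            quats, k = [], 0
            for a in s.attachments:
                m = 4 * (a.filament.N - 1)
                qs = rest[k : k + m].reshape(-1, 4)
                quats.append(qs / np.linalg.norm(qs, axis=1, keepdims=True))
                k += m
            parts.append((np.asarray(x_b, float), q_b, quats))
        return parts

    def frames(self, qstate: np.ndarray):
        return [
            s.frame_quat(x_b, q_b, quats)
            for s, (x_b, q_b, quats) in zip(self.assembly.structures, self.split(qstate))
        ]

    def rhs(self, t: float, qstate: np.ndarray) -> np.ndarray:
        frames = self.frames(qstate)
        pos = np.vstack([f.positions for f in frames])
        rad = np.concatenate([f.radii for f in frames])
        MH = rpy_mobility(
            pos, rad, eta=self.system.eta, mask=self.system.mask,
            overlap_corrected=self.system.overlap_corrected,
        )
        MF = assemble_MF(self.assembly, frames)
        Q = assemble_Q(self.assembly, frames)
        K = assemble_K(self.assembly, frames, t)
        L = MF @ MH.solve(Q)
        for c in self.system.constraints:
            lo, hi = self.system._constraint_rows(c)
            L[lo:hi, :] = 0.0
            L[lo:hi, lo:hi] = np.eye(3)
            if c.kind == "position":
                K[lo:hi] = np.asarray(c.rate(t), dtype=float)
            else:
                if c.omega_rate is None:
                    raise ValueError(
                        "quaternion backend needs omega_rate for orientation "
                        "constraints"
                    )
                K[lo:hi] = np.asarray(c.omega_rate(t), dtype=float)
        W = np.linalg.solve(L, K)
        out = np.zeros_like(qstate)
        parts = self.split(qstate)
        for i, s in enumerate(self.assembly.structures):
            wbase = self.assembly.state_offsets[i]
            k = self.offsets[i]
            x_b, q_b, quats = parts[i]
            wk = wbase
            if not s.fixed:
                out[k : k + 3] = W[wk : wk + 3]
                out[k + 3 : k + 7] = cmatrix(q_b) @ W[wk + 3 : wk + 6]
                k += 7
                wk += 6
            for qs in quats:
                for q in qs:
                    out[k : k + 4] = cmatrix(q) @ W[wk : wk + 3]
                    k += 4
                    wk += 3
        return out

    def integrate(
        self, state0, t_span, t_eval=None, rtol: float = 1e-6, atol: float = 1e-8
    ):
        """Integrate; ``state0`` is a generator-layout state (converted)."""
        q0 = self.state_from_generators(np.asarray(state0, dtype=float))
        sol = solve_ivp(
            self.rhs, t_span, q0, method="BDF", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"quaternion integration failed: {sol.message}")
        return sol
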