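"""Scenario builders and measurements for the validation and application runs.

Every builder returns a :class:`Scenario` whose defaults are the printed
parameter values of the corresponding validation/application case; all of
them can be overridden.  Scenario drive laws are reconstructed from the
stored parameter dictionary, so configurations round-trip through plain
serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assembly import (
    Assembly,
    Attachment,
    Filament,
    Structure,
    build_spherical_body,
    build_wall,
)
from .hydrodynamics import group_mask, tracer_velocities
from .rotations import dmatrix, quat_from_axis_angle
from .solver import (
    GoverningSystem,
    KinematicConstraint,
    Nondimensionalization,
    Trajectory,
    integrate,
)

__all__ = [
    "Scenario",
    "relaxation_scenario",
    "helical_actuation_scenario",
    "swimmer_scenario",
    "chlamydomonas_scenario",
    "sperm_egg_scenario",
    "cilia_array_scenario",
    "center_of_mass",
    "com_drift",
    "max_joint_curvature",
    "distance_per_period",
    "tip_axis_distance",
    "advect_tracers",
    "PERIOD",
]

PERIOD = 2.0 * np.pi  # drives are sin(ks - t): one beat period in time units


@dataclass
class Scenario:
    """A ready-to-integrate system plus its initial state and metadata."""

    name: str
    system: GoverningSystem
    state0: np.ndarray
    params: dict = field(default_factory=dict)
    period: Optional[float] = None

    @property
    def assembly(self) -> Assembly:
        return self.system.assembly

    def integrate(self, t_span, t_eval=None, **kw) -> Trajectory:
        return integrate(self.system, self.state0, t_span, t_eval=t_eval, **kw)


def _free_filament_assembly(fil: Filament) -> Assembly:
    return Assembly([Structure(attachments=[Attachment(fil)])])


def _semicircle_state(assembly: Assembly, N: int) -> np.ndarray:
    """Generators ``r_i = (theta_i / 2) [0, 1, 0]``, a semicircular arc."""
    state = np.zeros(assembly.state_size)
    theta = np.arange(N) * np.pi / (N - 1)
    state[3:6] = 0.5 * theta[0] * np.array([0.0, 1.0, 0.0])
    for i in range(1, N):
        state[6 + 3 * (i - 1) : 9 + 3 * (i - 1)] = (
            0.5 * theta[i] * np.array([0.0, 1.0, 0.0])
        )
    return state


# ---------------------------------------------------------------------
# validation scenarios
# ---------------------------------------------------------------------


def relaxation_scenario(N: int = 40, n: int = 2, S: float = 3.0) -> Scenario:
    """Free filament bent into a semicircle, relaxing to straight."""
    fil = Filament(N=N, n=n)
    assembly = _free_filament_assembly(fil)
    system = GoverningSystem(
        assembly, eta=Nondimensionalization(S).eta, overlap_corrected=True
    )
    return Scenario(
        name="relax",
        system=system,
        state0=_semicircle_state(assembly, N),
        params=dict(N=N, n=n, S=S),
    )


def helical_actuation_scenario(
    delta0: float = 0.1,
    alpha0: float = 0.2618,
    S: float = 1.0,
    N: int = 20,
    n: int = 1,
) -> Scenario:
    """Filament with its base driven around the z-axis.

    The force-free rows become ``x_1_dot = -delta0 [sin t, cos t, 0]`` and
    the torque-free rows ``r_1_dot = (alpha0 / 2) [cos t, -sin t, 0]``; the
    base then traces a circle of radius ``delta0`` while tilted by
    ``alpha0`` from the rotation axis.
    """
    fil = Filament(N=N, n=n)
    assembly = _free_filament_assembly(fil)
    state0 = np.zeros(assembly.state_size)
    state0[:3] = [delta0, 0.0, 0.0]
    r0 = 0.5 * alpha0 * np.array([0.0, 1.0, 0.0])
    state0[3:6] = r0
    for i in range(1, N):
        state0[6 + 3 * (i - 1) : 9 + 3 * (i - 1)] = r0

    def base_velocity(t):
        return -delta0 * np.array([np.sin(t), np.cos(t), 0.0])

    def base_generator_rate(t):
        return 0.5 * alpha0 * np.array([np.cos(t), -np.sin(t), 0.0])

    def base_omega(t):
        r = 0.5 * alpha0 * np.array([np.sin(t), np.cos(t), 0.0])
        return 2.0 * dmatrix(r) @ base_generator_rate(t)

    constraints = [
        KinematicConstraint(0, "position", base_velocity),
        KinematicConstraint(0, "orientation", base_generator_rate, base_omega),
    ]
    system = GoverningSystem(
        assembly,
        eta=Nondimensionalization(S).eta,
        overlap_corrected=True,
        constraints=constraints,
    )
    return Scenario(
        name="helix",
        system=system,
        state0=state0,
        params=dict(delta0=delta0, alpha0=alpha0, S=S, N=N, n=n),
        period=PERIOD,
    )


def _swimmer_curvature(K0_plateau: float, k: float, phase: float):
    def kappa0(s, t):
        K0 = K0_plateau if s <= 0.5 else 2.0 * K0_plateau * (1.0 - s)
        return (-K0 * np.sin(k * s - t + phase), 0.0, 0.0)

    return kappa0


def swimmer_scenario(
    mode: str = "single",
    phase: str = "in",
    l: float = 0.5,
    k: float = 2.0 * np.pi / 1.6,
    K0: float = 8.25,
    S: float = 22.6**0.25,
    N: int = 16,
    n: int = 1,
    initial_state: Optional[np.ndarray] = None,
) -> Scenario:
    """Undulatory swimmer(s) driven by a piecewise travelling curvature wave.

    ``K0(s)`` plateaus at 8.25 for ``s <= L/2`` and decays linearly to zero
    at the tip; the default wavenumber corresponds to an undulation
    wavelength of 1.6 L, inside the observed range of the nematode gait
    the drive derives from (the wavenumber itself is a free parameter).  In
    ``pair`` mode two copies beat ``in`` phase or in ``anti`` phase,
    separated by ``l`` along the beat plane normal to swimming.
    """
    if mode not in ("single", "pair"):
        raise ValueError("mode must be 'single' or 'pair'")
    eta = Nondimensionalization(S).eta
    if mode == "single":
        fil = Filament(N=N, n=n, preferred_curvature=_swimmer_curvature(K0, k, 0.0))
        assembly = _free_filament_assembly(fil)
        state0 = np.zeros(assembly.state_size)
        if initial_state is not None:
            state0 = np.asarray(initial_state, dtype=float).copy()
    else:
        phase2 = 0.0 if phase == "in" else np.pi
        fils = [
            Filament(N=N, n=n, preferred_curvature=_swimmer_curvature(K0, k, p))
            for p in (0.0, phase2)
        ]
        assembly = Assembly(
            [Structure(attachments=[Attachment(f)]) for f in fils]
        )
        single = np.zeros(assembly.state_size // 2)
        if initial_state is not None:
            single = np.asarray(initial_state, dtype=float).copy()
        state0 = np.concatenate([single, single])
        # separate along y (beat plane is y-z, swimming along z)
        half = assembly.state_size // 2
        state0[1] -= 0.5 * l
        state0[half + 1] += 0.5 * l
    system = GoverningSystem(assembly, eta=eta, overlap_corrected=True)
    return Scenario(
        name="swim",
        system=system,
        state0=state0,
        params=dict(mode=mode, phase=phase, l=l, k=k, K0=K0, S=S, N=N, n=n),
        period=PERIOD,
    )


# ---------------------------------------------------------------------
# application scenarios
# ---------------------------------------------------------------------


def chlamydomonas_scenario(
    R: float = 0.35,
    theta_deg: float = 11.5,
    kappa1_pair=(0.0, 0.0),
    coupling: str = "full",
    N_body: int = 184,
    N: int = 15,
    n: int = 1,
    S: float = 3.0,
    amplitude: float = 4.0,
) -> Scenario:
    """Bi-flagellate puller: spherical shell body plus two clamped flagella.

    Both flagella carry the in-plane drive ``+/- amplitude (1 + sin(2 pi s
    - t)) d2`` (opposite signs give mirror-symmetric beats in the x-z
    plane) plus optional constant out-of-plane components ``kappa1_pair``
    along ``d1``.  ``coupling='reduced'`` zeroes all hydrodynamic coupling
    between body and flagella and between the flagella.
    """
    if coupling not in ("full", "reduced"):
        raise ValueError("coupling must be 'full' or 'reduced'")
    theta = np.deg2rad(theta_deg)
    body = build_spherical_body(R, N_body)

    def make_drive(sign, kappa1):
        def kappa0(s, t):
            return (kappa1, sign * amplitude * (1.0 + np.sin(2.0 * np.pi * s - t)), 0.0)

        return kappa0

    attachments = []
    for sign, kappa1 in zip((+1.0, -1.0), kappa1_pair):
        fil = Filament(N=N, n=n, preferred_curvature=make_drive(sign, kappa1))
        tilt = quat_from_axis_angle([0.0, 1.0, 0.0], sign * theta)
        offset = R * np.array([sign * np.sin(theta), 0.0, np.cos(theta)])
        attachments.append(Attachment(fil, offset=offset, clamp=tilt))
    structure = Structure(body=body, attachments=attachments)
    assembly = Assembly([structure])

    mask = None
    if coupling == "reduced":
        groups = np.concatenate(
            [
                np.zeros(body.n_spheres, dtype=int),
                np.full(attachments[0].filament.n_spheres, 1),
                np.full(attachments[1].filament.n_spheres, 2),
            ]
        )
        mask = group_mask(groups)
    system = GoverningSystem(
        assembly,
        eta=Nondimensionalization(S).eta,
        mask=mask,
        overlap_corrected=True,
    )
    return Scenario(
        name="chlamy",
        system=system,
        state0=np.zeros(assembly.state_size),
        params=dict(
            R=R, theta_deg=theta_deg, kappa1_pair=tuple(kappa1_pair),
            coupling=coupling, N_body=N_body, N=N, n=n, S=S, amplitude=amplitude,
        ),
        period=PERIOD,
    )


def sperm_egg_scenario(
    theta_deg: float = 10.0,
    separation: float = 5.0,
    head_radius: float = 0.2,
    egg_radius: float = 1.0,
    N: int = 16,
    n: int = 1,
    S: float = 6.0,
    k: float = 2.0 * np.pi,
    amplitude_factor: float = 12.0,
    egg: bool = True,
    egg_spheres: int = 42,
) -> Scenario:
    """Sperm (spherical head + active filament) scattering off a free egg.

    The flagellum carries the active moment density ``m_a = 12 k cos(k s -
    t) d2`` instead of a preferred curvature.  The egg is a free rigid
    shell of ``egg_spheres`` spheres with radius ``egg_radius``, placed on
    the z-axis; ``theta_deg`` tilts the sperm's swimming axis away from z.

    The egg must be a sphere composite: in a pure mobility formulation a
    *single* force- and torque-free sphere exerts no influence on the rest
    of the flow, so a one-sphere egg would be hydrodynamically invisible
    to the sperm.  A shell carries internal rigid-body constraint forces
    (summing to zero) that scatter the flow and slow the swimmer down.
    """
    def m_a(s, t):
        return (0.0, amplitude_factor * k * np.cos(k * s - t), 0.0)

    fil = Filament(N=N, n=n, active_moment=m_a)
    head = build_spherical_body(head_radius, 1)
    # flagellum points along -d3 of the head frame: clamp flips the tangent
    flip = quat_from_axis_angle([0.0, 1.0, 0.0], np.pi)
    sperm = Structure(
        body=head,
        attachments=[Attachment(fil, offset=[0.0, 0.0, -head_radius], clamp=flip)],
    )
    structures = [sperm]
    if egg:
        structures.append(Structure(body=build_spherical_body(egg_radius, egg_spheres)))
    assembly = Assembly(structures)
    state0 = np.zeros(assembly.state_size)
    theta = np.deg2rad(theta_deg)
    # tilt the whole sperm away from the z-axis about y; free segments must
    # also carry the clamp flip so every tangent points along the flagellum
    state0[3:6] = 0.5 * theta * np.array([0.0, 1.0, 0.0])
    seg_rot = 0.5 * (theta + np.pi) * np.array([0.0, 1.0, 0.0])
    for i in range(1, N):
        state0[6 + 3 * (i - 1) : 9 + 3 * (i - 1)] = seg_rot
    if egg:
        state0[assembly.state_offsets[1] : assembly.state_offsets[1] + 3] = [
            0.0, 0.0, separation,
        ]
    system = GoverningSystem(
        assembly, eta=Nondimensionalization(S).eta, overlap_corrected=True
    )
    return Scenario(
        name="sperm-egg",
        system=system,
        state0=state0,
        params=dict(
            theta_deg=theta_deg, separation=separation, head_radius=head_radius,
            egg_radius=egg_radius, N=N, n=n, S=S, k=k,
            amplitude_factor=amplitude_factor, egg=egg, egg_spheres=egg_spheres,
        ),
        period=PERIOD,
    )


def cilia_array_scenario(
    rows: int = 5,
    cols: int = 5,
    N: int = 7,
    n: int = 1,
    S: float = 2.0,
    spacing: float = 0.4,
    wall_margin: int = 2,
    amplitude: float = 5.0,
    wall_sphere_diameter: Optional[float] = None,
) -> Scenario:
    """Cilia grid on a sphere-built wall, beating with a metachronal wave.

    Cilium in row i carries ``kappa0 = (1 + amplitude sin(1.5 pi s - t +
    phi_i)) d1`` with ``phi_i = (i - 1)/rows * 2 pi``: the phase advances
    across rows so the wave travels in +y.  Cilia beat in the y-z plane.
    """
    ds = 1.0 / N
    # wall spheres default to the cilia sphere diameter; a coarser wall
    # (larger diameter) cuts cost with little effect on the blocked flow
    wall_spacing = wall_sphere_diameter if wall_sphere_diameter else ds / n
    per_cell = max(1, int(round(spacing / wall_spacing)))
    wall_spacing = spacing / per_cell
    nx = per_cell * (cols - 1) + 2 * wall_margin + 1
    ny = per_cell * (rows - 1) + 2 * wall_margin + 1
    wall = build_wall(nx, ny, wall_spacing)
    structure = Structure(body=wall)

    def make_drive(phi):
        def kappa0(s, t):
            return (1.0 + amplitude * np.sin(1.5 * np.pi * s - t + phi), 0.0, 0.0)

        return kappa0

    # cilia stand on top of the wall, tangent along +z; the clamp turns the
    # material frame so the positive curvature bias bends cilia toward +y,
    # matching the documented transport direction of the metachronal wave
    clamp = quat_from_axis_angle([0.0, 0.0, 1.0], np.pi)
    x0 = -(cols - 1) * spacing / 2.0
    y0 = -(rows - 1) * spacing / 2.0
    for i in range(rows):
        phi = i / rows * 2.0 * np.pi
        for j in range(cols):
            fil = Filament(N=N, n=n, preferred_curvature=make_drive(phi))
            offset = [x0 + j * spacing, y0 + i * spacing, wall_spacing / 2.0]
            structure = Structure(
                body=structure.body,
                attachments=structure.attachments
                + [Attachment(fil, offset=offset, clamp=clamp)],
            )
    assembly = Assembly([structure])
    system = GoverningSystem(
        assembly, eta=Nondimensionalization(S).eta, overlap_corrected=True
    )
    # free segments start aligned with the clamped first segment
    state0 = np.tile(0.5 * np.pi * np.array([0.0, 0.0, 1.0]), assembly.state_size // 3)
    return Scenario(
        name="cilia",
        system=system,
        state0=state0,
        params=dict(
            rows=rows, cols=cols, N=N, n=n, S=S, spacing=spacing,
            wall_margin=wall_margin, amplitude=amplitude,
            wall_sphere_diameter=wall_sphere_diameter,
        ),
        period=PERIOD,
    )


# ---------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------


def center_of_mass(assembly: Assembly, state: np.ndarray) -> np.ndarray:
    pos, _, _ = assembly.sphere_positions(state)
    return pos.mean(axis=0)


def com_drift(traj: Trajectory) -> float:
    """Maximum displacement of the sphere centroid from its initial value."""
    ref = center_of_mass(traj.assembly, traj.states[0])
    return max(
        float(np.linalg.norm(center_of_mass(traj.assembly, s) - ref))
        for s in traj.states
    )


def max_joint_curvature(traj: Trajectory, i: int = -1) -> float:
    """Largest curvature magnitude over all filament joints at sample i."""
    from .cg_mechanics import curvatures_from_directors

    worst = 0.0
    for structure, frame in zip(
        traj.assembly.structures, traj.assembly.frames(traj.states[i])
    ):
        for a, ff in zip(structure.attachments, frame.filaments):
            kap = curvatures_from_directors(ff.directors, a.filament.ds)
            worst = max(worst, float(np.abs(kap).max()))
    return worst


def distance_per_period(traj: Trajectory, period: float, structure: int = 0) -> float:
    """Displacement of a structure's sphere centroid over the final period."""
    t_end = traj.t[-1]
    i_end = len(traj.t) - 1
    i_start = int(np.argmin(np.abs(traj.t - (t_end - period))))
    lo = traj.assembly.sphere_offsets[structure]
    hi = traj.assembly.sphere_offsets[structure + 1]
    p0 = traj.assembly.sphere_positions(traj.states[i_start])[0][lo:hi].mean(0)
    p1 = traj.assembly.sphere_positions(traj.states[i_end])[0][lo:hi].mean(0)
    return float(np.linalg.norm(p1 - p0))


def tip_axis_distance(traj: Trajectory, samples=None) -> float:
    """Distance of the filament free tip from the z-axis, time-averaged."""
    idx = range(len(traj.t)) if samples is None else samples
    vals = []
    for i in idx:
        frame = traj.assembly.frames(traj.states[i])[0]
        ff = frame.filaments[0]
        fil = traj.assembly.structures[0].attachments[0].filament
        tip = ff.endpoints[-1] + fil.ds * ff.directors[-1][:, 2]
        vals.append(np.hypot(tip[0], tip[1]))
    return float(np.mean(vals))


def advect_tracers(
    scenario: Scenario,
    traj: Trajectory,
    tracer_positions,
    tracer_radius: float = 0.01,
    n_periods: int = 1,
    steps_per_sample: int = 1,
) -> np.ndarray:
    """Advect passive tracers through a stored (periodic) trajectory.

    Forces and torques are recomputed at every stored sample; between
    samples the sphere positions and forces are linearly interpolated and
    tracers advance with midpoint (RK2) steps -- one-way RPY coupling.
    Returns the tracer position history, shape
    (n_samples_total + 1, n_tracers, 3).
    """
    system = scenario.system
    assembly = scenario.assembly
    ts = traj.t
    samples = []
    for i, state in enumerate(traj.states):
        pos, rad, _ = assembly.sphere_positions(state)
        _, _, forces, torques = system.solve_velocities(ts[i], state)
        samples.append((pos, rad, forces, torques))

    def field(i, frac):
        p0, rad, f0, t0 = samples[i]
        p1, _, f1, t1 = samples[i + 1]
        w = frac
        return (
            (1 - w) * p0 + w * p1,
            rad,
            (1 - w) * f0 + w * f1,
            (1 - w) * t0 + w * t1,
        )

    def vel(i, frac, x):
        pos, rad, forces, torques = field(i, frac)
        return tracer_velocities(
            pos, rad, forces, torques, x, tracer_radius, eta=system.eta
        )

    x = np.atleast_2d(np.asarray(tracer_positions, dtype=float)).copy()
    history = [x.copy()]
    for _ in range(n_periods):
        for i in range(len(ts) - 1):
            dt = (ts[i + 1] - ts[i]) / steps_per_sample
            for step in range(steps_per_sample):
                f0 = step / steps_per_sample
                fm = (step + 0.5) / steps_per_sample
                xm = x + 0.5 * dt * vel(i, f0, x)
                x = x + dt * vel(i, fm, xm)
            history.append(x.copy())
    return np.array(history)
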