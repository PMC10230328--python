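# elastohydro

Coarse-grained three-dimensional elastohydrodynamics of Kirchhoff filaments
and sphere-built rigid micro-structures in Stokes flow.

Filaments are chains of rigid, inextensible segments carrying touching
spheres; arbitrary solid bodies (spherical shells, walls, heads) are built
from spheres too. All spheres couple non-locally through the
Rotne–Prager–Yamakawa (RPY) grand mobility (standard or
overlap-regularized). Momentum balance over the coarse segments eliminates
contact forces, and rotations are tracked by the exponential map of
quaternions (with a direct quaternion backend for cross-validation),
yielding a stiff ODE system

    M_F · M_H⁻¹ · Q · D · dX/dt = K

integrated with SciPy's BDF solver, with automatic generator rescaling to
dodge coordinate singularities.

## Layout

| module | contents |
| --- | --- |
| `elastohydro.rotations` | quaternion / exponential-map algebra, `D`, `C`, cross matrices |
| `elastohydro.assembly` | filaments, sphere bodies, clamped structures, geometry from state |
| `elastohydro.cg_mechanics` | curvatures, constitutive moments, operator `M_F`, right side `K` |
| `elastohydro.hydrodynamics` | RPY grand mobility (+ overlap variant), inversion, tracers |
| `elastohydro.reduction` | rigid-chain reduction operator `Q` |
| `elastohydro.solver` | governing system, kinematic constraints, both integration backends |
| `elastohydro.experiments` | scenario builders (relaxation, helical actuation, undulatory swimmers, bi-flagellate, sperm–egg, cilia array) and measurements |
| `elastohydro.cli_io` | YAML configs, trajectory persistence, CLI |

All quantities are dimensionless: lengths in filament lengths `L`, time in
inverse drive frequency, bending stiffness 1; the stiffness parameter `S`
enters as viscosity `S⁴`.

## CLI

```bash
elastohydro relax  --tend 20 --nout 21 --out relax.csv
elastohydro swim   --tend 40 --param N=16 --out swim.csv
elastohydro helix  --param delta0=0.1 --param alpha0=0.2618 --out helix.csv
elastohydro cilia  --param rows=3 --param cols=3 --out cilia.csv
```

Subcommands: `relax`, `helix`, `swim`, `chlamy`, `sperm-egg`, `cilia`.
`--param KEY=VALUE` overrides any scenario parameter; `--config c.yaml`
loads a YAML `RunConfig` (unknown keys are rejected). Trajectories are
written as columnar CSV (or `.npz`) with a JSON metadata sidecar.

## Python API sketch

```python
import numpy as np
from elastohydro.assembly import Assembly, Attachment, Filament, Structure
from elastohydro.solver import GoverningSystem, integrate

fil = Filament(N=16, n=1, preferred_curvature=lambda s, t: (-8.0*np.sin(2*np.pi*s - t), 0, 0))
asm = Assembly([Structure(attachments=[Attachment(fil)])])
system = GoverningSystem(asm, eta=22.6, overlap_corrected=True)
traj = integrate(system, np.zeros(asm.state_size), (0, 12*np.pi))
positions, radii, structure_id = asm.sphere_positions(traj.states[-1])
```
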