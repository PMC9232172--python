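# epivertex

A 2D vertex-dynamics model of epithelial cell competition: a proliferating
cluster of "abnormal" cells inside a normal tissue is squeezed by elevated
actomyosin contractility (a mu-fold line tension) on the interface between
the two populations, and is eliminated — or not — through T2 removals of
mechanically collapsing cells.  The package couples the simulation with its
closed-form theory: the hexagonal ground state and elastic moduli (K, G),
the cluster-level force-balance cubic with its saddle-node (critical
density rho2 and contractility mu2*Lambda), the mechanical homeostatic
density rho1 measured in fixed-wall proliferation runs, and the
Lambda*(mu-1)/sqrt(N_theta) scaling of the elimination phase diagram.

## Layout

| module | contents |
|---|---|
| `epivertex.mesh_core` | polygonal tissue mesh, hexagonal builder, validation, text snapshots |
| `epivertex.mechanics` | energy U = sum (A-A0)^2/2 + sum Lambda*l + sum (Gamma/2) L^2, analytic forces, Euler stepping |
| `epivertex.topology_events` | T1 reconnection, T2 removal, division surgery, event resolution |
| `epivertex.cell_cycle` | clocks with +/-20% jitter, mitotic target-area growth, doubling/adder triggers |
| `epivertex.experiments` | scenario 1/2 drivers, fixed-wall (rho1), contractility sweeps, relative-growth sweeps |
| `epivertex.observables` | densities, rho_bar, outcome classification, side distributions, cell stress, Hill fits |
| `epivertex.theory` | ground state, K/G, force-balance cubic, rho2/mu2, scenario-2 calibration, rho_MCE, scaling variable |
| `epivertex.interface` | YAML config, CLI, fixtures, run manifests |

The inner loop is compiled with numba when available (a pure-Python
fallback runs the identical code); topological surgery happens at the
Python level between integration chunks.

## CLI

```sh
epivertex theory --lam 0.12 --gamma 0.04 --n-cells 100     # closed-form table
epivertex simulate run.yaml --out-prefix out/run           # one trajectory
epivertex sweep run.yaml --mu 4 --mu 6 --mu 8 --runs 5     # phase diagram
epivertex fixed-wall run.yaml                              # rho1 estimate
epivertex fixtures rosette7                                # test meshes
```

A minimal configuration file:

```yaml
lambda: 0.12        # line tension (both cell types)
gamma: 0.04         # perimeter elasticity
mu: 6.0             # interfacial contractility factor (>= 1)
dt: 0.002
scenario: 1         # 1 | 2 | fixed_wall
N_theta: 10
tissue_size: 199
tau_abnormal: 5.0
tau_normal: inf
t_end_cycles: 100
seed: 1
```

## Conventions

* Nondimensional units of the energy function: preferred cell area = 1.
* Cell loops are counter-clockwise; interior edges carry exactly two cells.
* T1/T2 thresholds are fractions (default 0.01) of the analytic normal
  ground-state edge length / cell area.
* Interfacial line tension between unlike cell types is mu times the
  arithmetic mean of the two types' Lambda.
* Snapshots are versioned plain text and round-trip exactly (`repr` floats).
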