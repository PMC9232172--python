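"""Configuration schema, CLI, fixtures and reproducibility plumbing."""

from __future__ import annotations

import hashlib
import json
import math
import time as _time
from dataclasses import asdict, dataclass, field

import click
import numpy as np
import yaml

from . import theory
from ._version import __version__
from .cell_cycle import CellCycleParams
from .experiments import (
    SimulationConfig,
    run_fixed_wall,
    run_scenario1,
    run_scenario2,
    sweep_contractility,
)
from .mechanics import MechanicalParams
from .mesh_core import ABNORMAL, TissueMesh, build_hexagonal_tissue, validate_mesh, write_snapshot

__all__ = ["load_config", "config_hash", "RunManifest", "make_fixture", "cli"]

_MECH_KEYS = {
    "lambda": "lambda_normal",  # shorthand applying to both cell types
    "lambda_normal": "lambda_normal",
    "lambda_abnormal": "lambda_abnormal",
    "gamma": "gamma_normal",
    "gamma_normal": "gamma_normal",
    "gamma_abnormal": "gamma_abnormal",
    "mu": "mu",
    "theta_t1_rel": "theta_t1_rel",
    "theta_t2_rel": "theta_t2_rel",
    "dt": "dt",
}
_CYCLE_KEYS = {
    "tau_abnormal": "tau_abnormal",
    "tau_normal": "tau_normal",
    "jitter_fraction": "jitter_fraction",
    "growth_rate_b": "growth_rate_b",
    "division_rule": "division_rule",
    "delta_A": "delta_A",
    "orientation_rule": "orientation_rule",
}
_RUN_KEYS = {
    "scenario",
    "N_theta",
    "tissue_size",
    "wall_radius",
    "t_end_cycles",
    "relax_time",
    "sample_dt",
    "failure_threshold",
    "seed",
}
_NOISE_KEYS = {"enabled", "relaxation_time", "amplitude"}


class ConfigError(ValueError):
    pass


def _parse_tau(v):
    if isinstance(v, str) and v.strip().lower() in ("inf", "inf.", "infinity"):
        return math.inf
    return float(v)


def load_config(source) -> SimulationConfig:
    """Build a validated SimulationConfig from a YAML file path or a dict.

    Defaults follow the printed parameter table (dt = 1e-4, b = 10, T1/T2
    thresholds 0.01, tau_A = 5).  Unknown keys are rejected with their path.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    mech_kwargs: dict = {}
    cycle_kwargs: dict = {}
    run_kwargs: dict = {}
    noise = raw.pop("noise", None)
    for key, value in raw.items():
        if key in _MECH_KEYS:
            if key == "lambda":
                mech_kwargs.setdefault("lambda_normal", float(value))
                mech_kwargs.setdefault("lambda_abnormal", float(value))
            elif key == "gamma":
                mech_kwargs.setdefault("gamma_normal", float(value))
                mech_kwargs.setdefault("gamma_abnormal", float(value))
            else:
                mech_kwargs[_MECH_KEYS[key]] = float(value)
        elif key in _CYCLE_KEYS:
            if key in ("tau_abnormal", "tau_normal"):
                cycle_kwargs[key] = _parse_tau(value)
            elif key in ("division_rule", "orientation_rule"):
                cycle_kwargs[key] = str(value)
            else:
                cycle_kwargs[key] = float(value)
        elif key in _RUN_KEYS:
            run_kwargs[key] = value
        else:
            raise ConfigError(f"unknown configuration key: {key!r}")
    if noise is not None:
        if not isinstance(noise, dict) or set(noise) - _NOISE_KEYS:
            raise ConfigError(f"unknown keys under 'noise': {sorted(set(noise) - _NOISE_KEYS)}")
        if noise.get("enabled", False):
            raise ConfigError(
                "Ornstein-Uhlenbeck line-tension noise is an experimental hook; "
                "set noise.enabled to false"
            )
    # mirror single-type shorthands when the paired key is absent
    if "lambda_normal" in mech_kwargs and "lambda_abnormal" not in mech_kwargs:
        mech_kwargs["lambda_abnormal"] = mech_kwargs["lambda_normal"]
    if "gamma_normal" in mech_kwargs and "gamma_abnormal" not in mech_kwargs:
        mech_kwargs["gamma_abnormal"] = mech_kwargs["gamma_normal"]
    try:
        mech = MechanicalParams(**mech_kwargs)
        cycle = CellCycleParams(**cycle_kwargs)
        if "scenario" in run_kwargs and run_kwargs["scenario"] != "fixed_wall":
            run_kwargs["scenario"] = int(run_kwargs["scenario"])
        for k in ("N_theta", "tissue_size", "seed"):
            if k in run_kwargs:
                run_kwargs[k] = int(run_kwargs[k])
        for k in ("wall_radius", "t_end_cycles", "relax_time", "sample_dt", "failure_threshold"):
            if k in run_kwargs and run_kwargs[k] is not None:
                run_kwargs[k] = float(run_kwargs[k])
        return SimulationConfig(mechanics=mech, cycle=cycle, **run_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    code_version: str = __version__
    start_time: float = 0.0
    end_time: float = 0.0
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------- fixtures

_FIXTURES = {}


def _fixture(name):
    def deco(fn):
        _FIXTURES[name] = fn
        return fn

    return deco


@_fixture("rosette7")
def _rosette7(edge_length: float = 0.62) -> TissueMesh:
    return build_hexagonal_tissue(7, edge_length)


@_fixture("patch19")
def _patch19(edge_length: float = 0.62, n_abnormal: int = 7) -> TissueMesh:
    mesh = build_hexagonal_tissue(19, edge_length)
    center = np.mean([mesh.cell_centroid(c) for c in mesh.cell_ids()], axis=0)
    for c in sorted(
        mesh.cell_ids(), key=lambda c: float(np.linalg.norm(mesh.cell_centroid(c) - center))
    )[:n_abnormal]:
        mesh.cells[c].cell_type = ABNORMAL
    return mesh


@_fixture("ring_oracle")
def _ring_oracle(N: int = 19, lam: float = 0.12, gamma: float = 0.04, rings: int = 5) -> TissueMesh:
    """Rotationally symmetric abnormal disk inside a normal annulus."""
    gs = theory.ground_state(lam, gamma)
    need = 1 + 3 * rings * (rings + 1)
    mesh = build_hexagonal_tissue(max(need, 4 * N), gs.l_g)
    center = np.mean([mesh.cell_centroid(c) for c in mesh.cell_ids()], axis=0)
    for c in sorted(
        mesh.cell_ids(), key=lambda c: float(np.linalg.norm(mesh.cell_centroid(c) - center))
    )[:N]:
        mesh.cells[c].cell_type = ABNORMAL
    return mesh


@_fixture("fixed_wall_disk")
def _fixed_wall_disk(n_cells: int = 61, lam: float = 0.12, gamma: float = 0.04) -> TissueMesh:
    gs = theory.ground_state(lam, gamma)
    mesh = build_hexagonal_tissue(n_cells, gs.l_g, "fixed_wall")
    for rec in mesh.cells.values():
        rec.cell_type = ABNORMAL
    return mesh


def make_fixture(name: str, **kwargs) -> TissueMesh:
    """Deterministic small test meshes, by registered name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return _FIXTURES[name](**kwargs)


# ---------------------------------------------------------------------- CLI


@click.group()
def cli():
    """Vertex-dynamics simulations of mechanical cell-cluster elimination."""


def _common_run(config_path, seed, overrides) -> SimulationConfig:
    cfg = load_config(config_path)
    if seed is not None:
        from dataclasses import replace

        cfg = replace(cfg, seed=int(seed))
    return cfg


@cli.command()
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None, help="override the config seed")
@click.option("--out-prefix", default="run", show_default=True)
def simulate(config_path, seed, out_prefix):
    """One simulation run: time series, event log, final mesh snapshot."""
    import pandas as pd

    cfg = _common_run(config_path, seed, {})
    manifest = RunManifest(config_hash=config_hash(cfg), seed=cfg.seed, start_time=_time.time())
    if cfg.scenario == "fixed_wall":
        res = run_fixed_wall(cfg)
        traj = res.trajectory
        click.echo(f"rho1 = {res.rho1:.4f} +/- {res.rho1_std:.4f}")
        if res.warning:
            click.echo(f"warning: {res.warning}")
    else:
        traj = run_scenario1(cfg) if cfg.scenario == 1 else run_scenario2(cfg)
        click.echo(f"outcome: {traj.classify()}  (N_end = {int(traj.n_abnormal[-1])})")
    ts = pd.DataFrame(
        {
            "t": traj.times,
            "N_abnormal": traj.n_abnormal,
            "area_abnormal": traj.area_abnormal,
            "area_total": traj.area_total,
        }
    )
    ts_path = f"{out_prefix}_timeseries.tsv"
    ts.to_csv(ts_path, sep="\t", index=False)
    ev_path = f"{out_prefix}_events.tsv"
    pd.DataFrame(traj.event_log.to_rows()).to_csv(ev_path, sep="\t", index=False)
    snap_path = f"{out_prefix}_final_mesh.txt"
    write_snapshot(traj.final_mesh, snap_path, time=float(traj.times[-1]), params_hash=manifest.config_hash)
    manifest.end_time = _time.time()
    manifest.outputs = [ts_path, ev_path, snap_path]
    manifest.write(f"{out_prefix}_manifest.json")
    click.echo(f"wrote {ts_path}, {ev_path}, {snap_path}")


@cli.command()
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--mu", "mus", type=float, multiple=True, required=True, help="mu grid point (repeat)")
@click.option("--runs", type=int, default=5, show_default=True)
@click.option("--out", default="sweep.tsv", show_default=True)
def sweep(config_path, mus, runs, out):
    """Contractility sweep -> phase-diagram table."""
    import pandas as pd

    cfg = load_config(config_path)
    diagram = sweep_contractility(cfg, list(mus), n_runs=runs)
    pd.DataFrame(diagram.to_rows()).to_csv(out, sep="\t", index=False)
    click.echo(f"wrote {out}")


@cli.command("fixed-wall")
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
def fixed_wall(config_path, seed):
    """Fixed-wall proliferation -> plateau density rho1."""
    cfg = _common_run(config_path, seed, {})
    res = run_fixed_wall(cfg)
    click.echo(f"rho1 = {res.rho1:.5f} +/- {res.rho1_std:.5f}")
    if res.warning:
        click.echo(f"warning: {res.warning}")


@cli.command("theory")
@click.option("--lam", "lam", type=float, required=True)
@click.option("--gamma", type=float, required=True)
@click.option("--n-cells", "N", type=int, default=100, show_default=True)
@click.option("--a0", type=float, default=None, help="onset area for the scenario-2 calibration")
@click.option("--mu", type=float, default=2.0, show_default=True)
def theory_cmd(lam, gamma, N, a0, mu):
    """Closed-form quantities for (Lambda, Gamma, N)."""
    gs = theory.ground_state(lam, gamma)
    k = theory.hexagon_shape_constant()
    n = theory.interfacial_count(N)
    if a0 is None:
        A_N, L_N = gs.A_g, gs.L_g
    else:
        A_N, L_N = theory.scenario2_interface_calibration(a0, lam, gamma, n, k)
    q1, q2 = theory.force_balance_coefficients(A_N, L_N, lam, gamma, mu, n, k)
    click.echo(f"L_g = {gs.L_g:.5f}  A_g = {gs.A_g:.5f}  l_g = {gs.l_g:.5f}")
    click.echo(f"K = {gs.K:.4f}  G = {gs.G:.4f}")
    click.echo(f"k = {k:.5f}  n(N={N}) = {n:.3f}")
    click.echo(f"A_N = {A_N:.5f}  L_N = {L_N:.5f}")
    click.echo(f"q1 = {q1:.6f}  q2(mu={mu}) = {q2:.6f}")
    cp = theory.critical_point(A_N, L_N, lam, gamma, n, k)
    if cp is None:
        click.echo("no bifurcation (q1 <= 0)")
    else:
        click.echo(f"rho2 = {cp[0]:.4f}  mu2*Lambda = {cp[1]:.4f}")
    for i in (3, 4, 5):
        click.echo(f"rho_MCE({i}) = {theory.rho_mce(i, lam, gamma):.4f}")
    click.echo(f"scaling variable Lambda*(mu-1)/sqrt(N) = {theory.scaling_variable(lam, mu, N):.5f}")


@cli.command()
@click.argument("name")
@click.option("--out", default=None, help="snapshot output path")
def fixtures(name, out):
    """Write a registered fixture mesh as a snapshot."""
    mesh = make_fixture(name)
    problems = validate_mesh(mesh)
    if problems:
        raise click.ClickException(f"fixture invalid: {problems}")
    path = out or f"{name}.txt"
    write_snapshot(mesh, path)
    click.echo(f"wrote {path} ({mesh.n_cells} cells, {mesh.n_vertices} vertices)")
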