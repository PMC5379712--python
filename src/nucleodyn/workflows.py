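"""Reproducible seeded runs wiring the generator and analyses together.

Every run writes a ``manifest.json`` listing the preset, the seed, the full
parameter set, a SHA-256 hash of the canonical parameter JSON and the output
files, so a run is replayable from its manifest alone.  Outputs are
byte-identical for identical (preset, seed, overrides).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .io import write_pdb, write_topology, write_trajectory
from .synth import SimulationParams, build_nucleosome_model, make_preset, simulate_trajectory

__all__ = ["RunResult", "run_simulation", "load_manifest", "replay"]


@dataclass
class RunResult:
    outdir: Path
    model_path: Path
    trajectory_path: Path
    topology_path: Path
    manifest_path: Path
    params: SimulationParams


def _params_hash(params: SimulationParams) -> str:
    canonical = json.dumps(asdict(params), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_simulation(
    outdir: str | os.PathLike,
    preset: str = "unmodified",
    seed: int = 0,
    **overrides,
) -> RunResult:
    """Simulate one regime and write model.pdb / traj.trj / topology.yaml."""

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = make_preset(preset, seed=seed, **overrides)
    model, topo = build_nucleosome_model(params)
    traj = simulate_trajectory(model, topo, params)

    model_path = outdir / "model.pdb"
    traj_path = outdir / "traj.trj"
    topo_path = outdir / "topology.yaml"
    write_pdb(model_path, model)
    write_trajectory(traj_path, traj)
    write_topology(topo_path, topo)

    manifest = {
        "package": "nucleodyn",
        "version": __version__,
        "preset": preset,
        "seed": seed,
        "overrides": {k: overrides[k] for k in sorted(overrides)},
        "params": asdict(params),
        "params_sha256": _params_hash(params),
        "outputs": {
            "model": model_path.name,
            "trajectory": traj_path.name,
            "topology": topo_path.name,
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(outdir, model_path, traj_path, topo_path, manifest_path, params)


def load_manifest(outdir: str | os.PathLike) -> dict:
    return json.loads((Path(outdir) / "manifest.json").read_text())


def replay(manifest: dict, outdir: str | os.PathLike) -> RunResult:
    """Re-run a simulation from its manifest alone."""

    return run_simulation(
        outdir,
        preset=manifest["preset"],
        seed=manifest["seed"],
        **manifest.get("overrides", {}),
    )
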