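import numpy as np
import pytest

from nucleodyn.model import AtomRecord, StructureModel, Trajectory
from nucleodyn.synth import SimulationParams, build_nucleosome_model, simulate_trajectory


def make_structure(positions, chain_ids=None, names=None, masses=None, residue_indices=None):
    """Small ad-hoc structure from a coordinate array."""

    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    chain_ids = chain_ids or ["A"] * n
    names = names or ["CA"] * n
    masses = masses if masses is not None else [12.011] * n
    residue_indices = residue_indices if residue_indices is not None else list(range(1, n + 1))
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=names[i],
            element="C",
            mass=masses[i],
            chain_id=chain_ids[i],
            residue_index=residue_indices[i],
            residue_name="ALA",
            position=tuple(positions[i]),
        )
        for i in range(n)
    ]
    return StructureModel(atoms)


def make_trajectory(structure, frames, dt=0.1):
    frames = np.asarray(frames, dtype=float)
    times = (np.arange(len(frames)) + 1) * dt
    return Trajectory(structure, frames, times)


@pytest.fixture(scope="session")
def quiet_params():
    """Small nucleosome with every planted motion switched off."""

    return SimulationParams(
        n_bp=24,
        n_frames=50,
        seed=1,
        core_sigma=0.0,
        entry_breathing_amp=0.0,
        exit_breathing_amp=0.0,
        scissor_amp_deg=0.0,
        groove_amp=0.0,
        dimer_com_shift=0.0,
        cenpc_offset=0.0,
    )


@pytest.fixture(scope="session")
def quiet_system(quiet_params):
    model, topo = build_nucleosome_model(quiet_params)
    traj = simulate_trajectory(model, topo, quiet_params)
    return model, topo, traj
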