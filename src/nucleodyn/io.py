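"""Readers and writers: PDB structures, plain-text trajectories, YAML configs.

The native trajectory format (extension ``.trj``) is deliberately plain
text so fixtures stay human-diffable and no binary dependency is needed::

    # key value            (optional metadata comment lines)
    natoms 3
    nframes 2
    frame 0 time 0.000000
    x y z                  (natoms lines, Angstrom, 6 decimals)
    frame 1 time 0.100000
    ...

Adapters to binary MD formats are intentionally out of scope; any adapter
must produce the same in-memory :class:`~nucleodyn.model.Trajectory`
contract.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import yaml

from .model import (
    AnalysisConfig,
    AtomRecord,
    ModelError,
    NucleosomeTopology,
    StructureModel,
    Trajectory,
)

__all__ = [
    "PDBParseError",
    "ELEMENT_MASSES",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
    "read_analysis_config",
    "write_analysis_config",
]


class PDBParseError(ModelError):
    pass


#: Average atomic masses (Da) attached to atoms at read time.  PDB files
#: carry no masses; center-of-mass operations need them.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
}

_TWO_LETTER = {"FE", "ZN", "MG", "NA", "CL", "SE", "MN", "BR"}


def _infer_element(name: str, record: str) -> str:
    """Infer an element symbol from PDB atom-name columns.

    Standard ATOM records place one-letter elements in column 14, so a name
    like ``" CA "`` is a carbon; HETATM metal names such as ``"FE"``/``"ZN"``
    (and calcium ``"CA"`` starting in column 13) are recognized explicitly.
    """

    stripped = name.strip()
    if not stripped:
        raise PDBParseError("empty atom name")
    bare = "".join(ch for ch in stripped if ch.isalpha()).upper()
    if record == "HETATM" and bare in _TWO_LETTER | {"CA", "K"} and len(stripped) <= 2:
        return bare
    if len(name) >= 2 and name[0] != " " and bare[:2] in _TWO_LETTER:
        return bare[:2]
    return bare[0]


def read_pdb(path: str | os.PathLike) -> StructureModel:
    """Read ATOM/HETATM records of a PDB file into a StructureModel.

    Coordinates are in Angstrom; chain and residue identity are preserved
    exactly.  The element is taken from columns 77-78 when present and
    inferred from the atom-name columns otherwise.  Only the first MODEL of
    a multi-model file is read (use :func:`read_trajectory` for frames).
    """

    atoms: list[AtomRecord] = []
    chains: list[str] = []
    seen_chains: set[str] = set()
    seen_keys: set[tuple[str, int, str]] = set()
    in_second_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                in_second_model = True
                continue
            if in_second_model or rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated {rec} record")
            try:
                serial = int(line[6:11])
                name = line[12:16]
                residue_name = line[17:20].strip() or "UNK"
                chain_id = line[21].strip() or "_"
                residue_index = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed {rec} record: {exc}") from None
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name, rec)
            mass = ELEMENT_MASSES.get(element)
            if mass is None:
                raise PDBParseError(f"line {lineno}: unknown element {element!r}")
            if chain_id not in seen_chains:
                seen_chains.add(chain_id)
                chains.append(chain_id)
            key = (chain_id, residue_index, name.strip())
            if key in seen_keys:
                raise PDBParseError(f"line {lineno}: duplicate atom {key}")
            seen_keys.add(key)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name.strip(),
                    element=element,
                    mass=mass,
                    chain_id=chain_id,
                    residue_index=residue_index,
                    residue_name=residue_name,
                    position=(x, y, z),
                )
            )
    if not atoms:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    return StructureModel(atoms, chains)


def _format_atom_line(a: AtomRecord, pos: np.ndarray) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial % 100000:5d} {name:<4.4s} {a.residue_name:<3.3s} "
        f"{a.chain_id[:1]}{a.residue_index % 10000:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
    )


def write_pdb(
    path: str | os.PathLike,
    model: StructureModel,
    frames: np.ndarray | None = None,
) -> None:
    """Write a StructureModel (optionally multi-MODEL) as a PDB file."""

    with open(path, "w") as fh:
        if frames is None:
            for a, pos in zip(model.atoms, model.coords):
                fh.write(_format_atom_line(a, np.asarray(pos)))
            fh.write("END\n")
        else:
            frames = np.asarray(frames, dtype=float)
            for m, frame in enumerate(frames, start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for a, pos in zip(model.atoms, frame):
                    fh.write(_format_atom_line(a, pos))
                fh.write("ENDMDL\n")
            fh.write("END\n")


def write_trajectory(path: str | os.PathLike, traj: Trajectory) -> None:
    """Write a trajectory in the native plain-text .trj format."""

    with open(path, "w") as fh:
        for key, value in traj.metadata.items():
            if isinstance(value, (str, int, float, bool)):
                fh.write(f"# {key} {value}\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        fh.write(f"nframes {traj.n_frames}\n")
        for f in range(traj.n_frames):
            fh.write(f"frame {f} time {traj.times[f]:.6f}\n")
            np.savetxt(fh, traj.coords[f], fmt="%.6f")


def read_trajectory(path: str | os.PathLike, structure: StructureModel) -> Trajectory:
    """Read a native .trj file against a known structure.

    Raises :class:`ModelError` naming the frame if any frame's atom count
    does not match the structure.
    """

    metadata: dict[str, str] = {}
    natoms = nframes = None
    coords: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split(None, 1)
            if len(parts) == 2:
                metadata[parts[0]] = parts[1]
            continue
        if line.startswith("natoms"):
            natoms = int(line.split()[1])
            continue
        if line.startswith("nframes"):
            nframes = int(line.split()[1])
            continue
        if line.startswith("frame"):
            parts = line.split()
            frame_no = int(parts[1])
            times.append(float(parts[3]))
            if natoms is None:
                raise ModelError("trajectory header missing natoms")
            block = lines[i : i + natoms]
            rows = [b.split() for b in block if b.strip()]
            if len(rows) != natoms or any(len(r) != 3 for r in rows):
                raise ModelError(
                    f"frame {frame_no}: expected {natoms} coordinate triples"
                )
            coords.append(np.array(rows, dtype=float))
            i += natoms
            continue
        raise ModelError(f"unrecognized trajectory line: {line!r}")
    if natoms is not None and natoms != structure.n_atoms:
        raise ModelError(
            f"trajectory atom count {natoms} != structure atom count {structure.n_atoms}"
        )
    if nframes is not None and nframes != len(coords):
        raise ModelError(f"header declares {nframes} frames, found {len(coords)}")
    return Trajectory(structure, np.array(coords), np.array(times), metadata=metadata)


def write_topology(path: str | os.PathLike, topo: NucleosomeTopology) -> None:
    data = {
        "roles": dict(topo.role_map),
        "basepairs": {int(k): int(v) for k, v in topo.basepair_map.items()},
        "dyad_pair": [int(topo.dyad_pair[0]), int(topo.dyad_pair[1])],
        "segments": {
            role: {name: [int(lo), int(hi)] for name, (lo, hi) in segs.items()}
            for role, segs in topo.segments.items()
        },
        "entry_end": topo.entry_end,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_topology(path: str | os.PathLike) -> NucleosomeTopology:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return NucleosomeTopology(
        role_map=dict(data["roles"]),
        basepair_map={int(k): int(v) for k, v in data["basepairs"].items()},
        dyad_pair=tuple(data["dyad_pair"]),
        segments={
            role: {name: tuple(rng) for name, rng in segs.items()}
            for role, segs in data.get("segments", {}).items()
        },
        entry_end=data.get("entry_end", "I5prime"),
    )


def write_analysis_config(path: str | os.PathLike, cfg: AnalysisConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vars(cfg), fh, sort_keys=True)


def read_analysis_config(path: str | os.PathLike) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)
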