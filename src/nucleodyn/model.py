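"""Domain data model for pseudo-atomic nucleosome structures and trajectories.

Conventions used throughout the package:

* coordinates in Angstrom, times in nanoseconds;
* frames are 0-based, residue indices are kept exactly as given by the
  input (1-based for PDB files) and never renumbered;
* chain identity is a short string (one character for PDB round trips).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelError",
    "SelectionError",
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "NucleosomeTopology",
    "Selection",
    "AnalysisConfig",
    "resolve_selection",
    "apply_equilibration",
    "PROTEIN_ROLES",
    "DNA_ROLES",
    "ROLES",
]


class ModelError(ValueError):
    """Invalid structure, trajectory or topology."""


class SelectionError(ModelError):
    """A selection does not resolve to a valid atom list."""


PROTEIN_ROLES = (
    "CENP-A",
    "CENP-A'",
    "H4",
    "H4'",
    "H2A",
    "H2A'",
    "H2B",
    "H2B'",
    "CENP-C",
    "CENP-C'",
)
DNA_ROLES = ("DNA_I", "DNA_J")
ROLES = PROTEIN_ROLES + DNA_ROLES


@dataclass(frozen=True)
class AtomRecord:
    """One pseudo-atom (or real atom) with chain/residue identity.

    ``mass`` is a per-atom mass in Da (monoisotopic or average; the package
    only uses it for mass-weighted centers of mass).
    """

    serial: int
    name: str
    element: str
    mass: float
    chain_id: str
    residue_index: int
    residue_name: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ModelError(f"atom serial must be positive, got {self.serial}")
        if not (self.mass > 0):
            raise ModelError(f"atom {self.serial}: mass must be > 0, got {self.mass}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ModelError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", tuple(float(x) for x in pos))


class StructureModel:
    """An ordered collection of atoms plus the chain order of the file."""

    def __init__(self, atoms: Sequence[AtomRecord], chains: Sequence[str] | None = None):
        self.atoms: list[AtomRecord] = list(atoms)
        if not self.atoms:
            raise ModelError("a StructureModel needs at least one atom")
        if chains is None:
            seen: dict[str, None] = {}
            for a in self.atoms:
                seen.setdefault(a.chain_id, None)
            chains = list(seen)
        self.chains: list[str] = list(chains)
        if len(set(self.chains)) != len(self.chains):
            raise ModelError("chain identifiers must be unique")
        chainset = set(self.chains)
        keys = set()
        for a in self.atoms:
            if a.chain_id not in chainset:
                raise ModelError(f"atom {a.serial}: chain {a.chain_id!r} not in chain list")
            key = (a.chain_id, a.residue_index, a.name)
            if key in keys:
                raise ModelError(f"duplicate atom {key}")
            keys.add(key)
        # flat arrays for fast selection / analysis
        self.coords = np.array([a.position for a in self.atoms], dtype=float)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.chain_ids = np.array([a.chain_id for a in self.atoms])
        self.residue_indices = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.atom_names = np.array([a.name for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ModelError("coordinate array shape mismatch")
        atoms = [replace(a, position=tuple(c)) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms, self.chains)


class Trajectory:
    """Per-frame coordinates (Angstrom) for a fixed StructureModel."""

    def __init__(
        self,
        structure: StructureModel,
        coords: np.ndarray,
        times: np.ndarray,
        metadata: dict | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ModelError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != structure.n_atoms:
            raise ModelError(
                f"trajectory atom count {coords.shape[1]} != structure atom count "
                f"{structure.n_atoms}"
            )
        if coords.shape[0] < 1:
            raise ModelError("trajectory needs at least one frame")
        if times.shape != (coords.shape[0],):
            raise ModelError("times must have one entry per frame")
        if np.any(np.diff(times) <= 0):
            raise ModelError("frame times must be strictly increasing")
        if not np.all(np.isfinite(coords)):
            raise ModelError("trajectory coordinates must be finite")
        self.structure = structure
        self.coords = coords
        self.times = times
        self.metadata = dict(metadata or {})

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def slice_frames(self, start: int, stop: int | None = None) -> "Trajectory":
        return Trajectory(
            self.structure,
            self.coords[start:stop],
            self.times[start:stop],
            metadata=self.metadata,
        )


@dataclass
class NucleosomeTopology:
    """Assignment of chains to nucleosome roles.

    ``basepair_map`` maps strand-I residue indices to their strand-J
    partners (antiparallel, so partner indices decrease as strand-I indices
    increase).  ``segments`` maps a role to named residue-index ranges,
    inclusive on both ends (e.g. the CENP-A C-terminus, alpha2/alpha3 of the
    4-helix bundle, the H2A acidic patch).
    """

    role_map: dict[str, str]
    basepair_map: dict[int, int]
    dyad_pair: tuple[int, int]
    segments: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    entry_end: str = "I5prime"  # which duplex end is the DNA entry side

    def __post_init__(self) -> None:
        for chain, role in self.role_map.items():
            if role not in ROLES:
                raise ModelError(f"unknown role {role!r} for chain {chain!r}")
        for role in DNA_ROLES:
            n = sum(1 for r in self.role_map.values() if r == role)
            if n != 1:
                raise ModelError(f"role {role} must map to exactly one chain, found {n}")
        vals = list(self.basepair_map.values())
        if len(set(vals)) != len(vals):
            raise ModelError("basepair_map must be a bijection")
        keys = sorted(self.basepair_map)
        partner = [self.basepair_map[k] for k in keys]
        if any(b >= a for a, b in zip(partner, partner[1:])):
            raise ModelError("strand-J indices must decrease as strand-I indices increase")
        i, j = self.dyad_pair
        if self.basepair_map.get(i) != j:
            raise ModelError("dyad_pair must be an entry of basepair_map")

    def chain_for_role(self, role: str) -> str:
        for chain, r in self.role_map.items():
            if r == role:
                return chain
        raise SelectionError(f"no chain assigned to role {role!r}")

    def role_of_chain(self, chain: str) -> str | None:
        return self.role_map.get(chain)

    def partner(self, strand_i_residue: int) -> int:
        try:
            return self.basepair_map[strand_i_residue]
        except KeyError:
            raise ModelError(f"residue {strand_i_residue} not in basepair map") from None

    @property
    def n_bp(self) -> int:
        return len(self.basepair_map)

    # Backwards-compatible alias used in a few call sites / configs.
    @property
    def cterm_ranges(self) -> dict[str, dict[str, tuple[int, int]]]:
        return self.segments


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection.

    Any field left at ``None`` matches everything.  ``segment`` names a
    residue range registered in the topology for each selected role (so it
    requires both ``roles`` and a topology).  Resolution order is always
    file order of the structure.
    """

    roles: tuple[str, ...] | None = None
    segment: str | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: tuple[str, ...] | None = None
    chain_ids: tuple[str, ...] | None = None

    def __or__(self, other: "Selection") -> tuple["Selection", ...]:
        return (self, other)


@dataclass
class AnalysisConfig:
    """Analysis parameters shared across the pipeline.

    equilibration_fraction
        Fraction of leading frames dropped before any statistic is
        computed (default 0.6: the last 400 ns of a 1 us run).
    contact_cutoff
        Contact distance cutoff between representative atoms, Angstrom.
    block_count
        Number of contiguous blocks for blocked error estimates.
    end_truncation_bp
        Base pairs dropped from each DNA end for whole-nucleosome PCA.
    animation_scale
        Amplification factor applied to exported mode animations.
    kT
        Energy unit of free-energy landscapes (1.0 means landscapes are in
        units of kT).
    """

    equilibration_fraction: float = 0.6
    contact_cutoff: float = 8.0
    block_count: int = 3
    end_truncation_bp: int = 10
    animation_scale: float = 5.0
    kT: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ModelError("equilibration_fraction must be in [0, 1)")
        if not (self.contact_cutoff > 0):
            raise ModelError("contact_cutoff must be > 0")
        if self.block_count < 2:
            raise ModelError("block_count must be >= 2")
        if self.end_truncation_bp < 0:
            raise ModelError("end_truncation_bp must be >= 0")


def _as_selections(sel) -> tuple[Selection, ...]:
    if isinstance(sel, Selection):
        return (sel,)
    return tuple(sel)


def resolve_selection(
    sel: Selection | Iterable[Selection],
    model: StructureModel,
    topo: NucleosomeTopology | None = None,
) -> np.ndarray:
    """Resolve a selection (or union of selections) to atom indices.

    Returns indices in file order without duplicates.  Raises
    :class:`SelectionError` if a referenced role is unknown or the result is
    empty.
    """

    mask = np.zeros(model.n_atoms, dtype=bool)
    for s in _as_selections(sel):
        sub = np.ones(model.n_atoms, dtype=bool)
        ranges_by_chain: dict[str, tuple[int, int]] | None = None
        if s.roles is not None:
            if topo is None:
                raise SelectionError("role-based selection requires a topology")
            chains = []
            ranges_by_chain = {}
            for role in s.roles:
                if role not in ROLES:
                    raise SelectionError(f"unknown role {role!r}")
                if role not in topo.role_map.values():
                    raise SelectionError(f"role {role!r} not assigned to any chain")
                chain = topo.chain_for_role(role)
                chains.append(chain)
                if s.segment is not None:
                    try:
                        ranges_by_chain[chain] = topo.segments[role][s.segment]
                    except KeyError:
                        raise SelectionError(
                            f"segment {s.segment!r} not defined for role {role!r}"
                        ) from None
            sub &= np.isin(model.chain_ids, chains)
        elif s.segment is not None:
            raise SelectionError("segment selections require roles")
        if s.chain_ids is not None:
            sub &= np.isin(model.chain_ids, list(s.chain_ids))
        if s.residue_range is not None:
            lo, hi = s.residue_range
            sub &= (model.residue_indices >= lo) & (model.residue_indices <= hi)
        if s.atom_names is not None:
            sub &= np.isin(model.atom_names, list(s.atom_names))
        if ranges_by_chain:
            seg = np.zeros(model.n_atoms, dtype=bool)
            for chain, (lo, hi) in ranges_by_chain.items():
                seg |= (
                    (model.chain_ids == chain)
                    & (model.residue_indices >= lo)
                    & (model.residue_indices <= hi)
                )
            sub &= seg
        mask |= sub
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection resolved to no atoms: {sel!r}")
    return idx


def apply_equilibration(traj: Trajectory, cfg: AnalysisConfig) -> Trajectory:
    """Drop the leading equilibration window of a trajectory.

    Removes the first ``floor(equilibration_fraction * n_frames)`` frames;
    the timestamps of retained frames are preserved.  With fraction 0 this
    is the identity.
    """

    drop = int(np.floor(cfg.equilibration_fraction * traj.n_frames))
    if traj.n_frames - drop < 2:
        raise ModelError(
            f"equilibration would leave {traj.n_frames - drop} frame(s); need >= 2"
        )
    if drop == 0:
        return traj
    return traj.slice_frames(drop)
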