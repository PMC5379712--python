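"""Residue-residue contact occupancy over trajectories.

A contact is defined between one representative atom per residue (Calpha
for protein, P for DNA); a residue pair is in contact in a frame when the
representative-atom distance is <= the cutoff (8 A by default), with
distances exactly at the cutoff counting as contacts.  Occupancy is the
fraction of analyzed frames in which the contact is formed: 1 means formed
in every frame, 0 never.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import TimeSeries
from .model import (
    AnalysisConfig,
    ModelError,
    NucleosomeTopology,
    Selection,
    Trajectory,
    apply_equilibration,
    resolve_selection,
)

__all__ = [
    "ContactMap",
    "InterfaceRetention",
    "ContactComparison",
    "contact_occupancy",
    "contact_count_series",
    "interface_retention",
    "compare_contact_maps",
    "representative_selection",
]

REPRESENTATIVE_ATOMS = ("CA", "P")


def representative_selection(*roles: str, segment: str | None = None) -> Selection:
    """Selection of the representative atoms (Calpha/P) for the given roles."""

    return Selection(roles=tuple(roles), segment=segment, atom_names=REPRESENTATIVE_ATOMS)


@dataclass
class ContactMap:
    """Residue x residue occupancy fractions in [0, 1]."""

    row_residues: list[tuple[str, int]]
    col_residues: list[tuple[str, int]]
    occupancy: np.ndarray
    cutoff: float
    n_frames_used: int

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (len(self.row_residues), len(self.col_residues)):
            raise ModelError("occupancy shape does not match residue axes")
        if occ.size and (occ.min() < 0 or occ.max() > 1):
            raise ModelError("occupancy values must lie in [0, 1]")
        self.occupancy = occ

    def transpose(self) -> "ContactMap":
        return ContactMap(
            list(self.col_residues),
            list(self.row_residues),
            self.occupancy.T.copy(),
            self.cutoff,
            self.n_frames_used,
        )


def _residue_labels(traj: Trajectory, topo: NucleosomeTopology, idx: np.ndarray):
    """One representative atom per residue, in file order.

    Raises if any residue in the selection has more than one atom: the
    caller must select representative atoms (Calpha/P), not all atoms.
    Residues lacking a representative atom simply do not appear; for DNA
    termini without a P this is the documented skip-with-warning behavior.
    """

    model = traj.structure
    labels: list[tuple[str, int]] = []
    seen: dict[tuple[str, int], int] = {}
    for i in idx:
        chain = model.chain_ids[i]
        role = (topo.role_of_chain(chain) if topo is not None else None) or chain
        key = (role, int(model.residue_indices[i]))
        if key in seen:
            raise ModelError(
                f"residue {key} has multiple representative atoms in the selection"
            )
        seen[key] = int(i)
        labels.append(key)
    return labels, np.array([seen[k] for k in labels], dtype=int)


def _prepare(traj, topo, sel_a, sel_b, cfg):
    traj = apply_equilibration(traj, cfg)
    idx_a = resolve_selection(sel_a, traj.structure, topo)
    idx_b = resolve_selection(sel_b, traj.structure, topo)
    rows, ia = _residue_labels(traj, topo, idx_a)
    cols, ib = _residue_labels(traj, topo, idx_b)
    return traj, rows, cols, ia, ib


def contact_occupancy(
    traj: Trajectory,
    topo: NucleosomeTopology | None,
    sel_a: Selection,
    sel_b: Selection,
    cfg: AnalysisConfig | None = None,
) -> ContactMap:
    """Occupancy map between two selections over the analyzed window.

    The equilibration window of ``cfg`` is discarded first (pass
    ``equilibration_fraction=0`` if the trajectory is already truncated).
    """

    cfg = cfg or AnalysisConfig()
    traj, rows, cols, ia, ib = _prepare(traj, topo, sel_a, sel_b, cfg)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f, ia], traj.coords[f, ib])
        counts += d <= cfg.contact_cutoff
    return ContactMap(rows, cols, counts / traj.n_frames, cfg.contact_cutoff, traj.n_frames)


def contact_count_series(
    traj: Trajectory,
    topo: NucleosomeTopology | None,
    sel_a: Selection,
    sel_b: Selection,
    cfg: AnalysisConfig | None = None,
) -> TimeSeries:
    """Per-frame count of residue pairs within the cutoff."""

    cfg = cfg or AnalysisConfig()
    traj, _, _, ia, ib = _prepare(traj, topo, sel_a, sel_b, cfg)
    values = np.empty(traj.n_frames, dtype=float)
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f, ia], traj.coords[f, ib])
        values[f] = np.count_nonzero(d <= cfg.contact_cutoff)
    return TimeSeries("contact_count", "pairs", traj.times.copy(), values)


@dataclass
class InterfaceRetention:
    mean_occupancy: float
    stable_pairs: list[tuple[tuple[str, int], tuple[str, int], float]]
    threshold: float


def interface_retention(cmap: ContactMap, threshold: float = 0.5) -> InterfaceRetention:
    """Mean occupancy plus the list of stable contacts (occupancy >= threshold)."""

    stable = [
        (cmap.row_residues[i], cmap.col_residues[j], float(cmap.occupancy[i, j]))
        for i in range(len(cmap.row_residues))
        for j in range(len(cmap.col_residues))
        if cmap.occupancy[i, j] >= threshold
    ]
    return InterfaceRetention(float(cmap.occupancy.mean()), stable, threshold)


@dataclass
class ContactComparison:
    retained: set
    lost: set
    gained: set
    threshold: float


def compare_contact_maps(
    reference: ContactMap, other: ContactMap, threshold: float = 0.5
) -> ContactComparison:
    """Stable-contact bookkeeping between two maps on identical residue axes.

    ``lost`` are pairs stable in ``reference`` but not in ``other`` (e.g.
    CENP-C docking contacts lost upon acetylation); ``gained`` the reverse.
    """

    if (
        reference.row_residues != other.row_residues
        or reference.col_residues != other.col_residues
    ):
        raise ModelError("contact maps have mismatched residue axes")
    ref_stable = {p[:2] for p in interface_retention(reference, threshold).stable_pairs}
    oth_stable = {p[:2] for p in interface_retention(other, threshold).stable_pairs}
    return ContactComparison(
        retained=ref_stable & oth_stable,
        lost=ref_stable - oth_stable,
        gained=oth_stable - ref_stable,
        threshold=threshold,
    )
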