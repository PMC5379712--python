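"""Scalar and time-series geometric observables on nucleosome trajectories.

Covers rigid-body superposition (Kabsch), per-atom RMSF with blocked error
bars, mass-weighted center-of-mass distance distributions between histone
dimers, DNA end-to-pseudo-dyad distances (end "breathing"/unwrapping),
cross-strand groove widths, the alpha2-alpha3 scissoring angle of the
4-helix bundle, and Pearson correlation between series.

Groove-width convention: the width at strand-I residue ``i`` is the
distance between P(i) on strand I and P(basepair(i) + k) on strand J
(k = 3 for the minor, k = 7 for the major groove), minus a constant 5.8 A
phosphate-exclusion diameter, floored at 0.  This is a documented package
convention; no curvilinear helicoidal analysis is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

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
    "TimeSeries",
    "DistributionSummary",
    "RMSFResult",
    "kabsch_rotation",
    "superpose",
    "rmsf",
    "rmsf_per_basepair",
    "com_distance_series",
    "dna_end_to_dyad_series",
    "groove_width_series",
    "scissoring_series",
    "series_correlation",
    "PHOSPHATE_EXCLUSION",
    "GROOVE_OFFSETS",
]

PHOSPHATE_EXCLUSION = 5.8  # Angstrom subtracted from cross-strand P-P distances
GROOVE_OFFSETS = {"minor": 3, "major": 7}


@dataclass
class TimeSeries:
    name: str
    units: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ModelError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ModelError(f"series {self.name!r} contains non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class DistributionSummary:
    mean: float
    variance: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int


def summarize(values: np.ndarray, n_bins: int = 50) -> DistributionSummary:
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins)
    return DistributionSummary(
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)) if values.size > 1 else 0.0,
        bin_edges=edges,
        counts=counts,
        n=int(values.size),
    )


# --------------------------------------------------------------------------
# superposition

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation matrix mapping centered ``mobile`` onto
    centered ``target`` (least-squares, reflections excluded)."""

    H = mobile.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    traj: Trajectory,
    ref_sel: Selection,
    topo: NucleosomeTopology | None = None,
    max_iter: int = 5,
    tol: float = 1e-6,
) -> Trajectory:
    """Rigid-body least-squares fit of every frame onto the time-average.

    Each frame is rotated/translated so the reference-selection atoms best
    match their time-averaged coordinates; the average is recomputed and the
    fit repeated until self-consistent (standard essential-dynamics
    practice).  The fit is mass-unweighted.
    """

    idx = resolve_selection(ref_sel, traj.structure, topo)
    if idx.size < 3:
        raise ModelError("superposition reference needs >= 3 atoms")
    X = traj.coords.copy()
    ref_coords = X[:, idx].mean(axis=0)
    sv = np.linalg.svd(ref_coords - ref_coords.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ModelError("superposition reference atoms are (nearly) collinear")
    prev = None
    for _ in range(max_iter):
        ref = X[:, idx].mean(axis=0)
        ref_centroid = ref.mean(axis=0)
        refc = ref - ref_centroid
        for f in range(X.shape[0]):
            sub = X[f, idx]
            cen = sub.mean(axis=0)
            R = kabsch_rotation(sub - cen, refc)
            X[f] = (X[f] - cen) @ R.T + ref_centroid
        if prev is not None and np.max(np.abs(ref - prev)) < tol:
            break
        prev = ref
    return Trajectory(traj.structure, X, traj.times.copy(), metadata=traj.metadata)


# --------------------------------------------------------------------------
# RMSF

@dataclass
class RMSFResult:
    atom_indices: np.ndarray
    values: np.ndarray  # pooled whole-window RMSF per atom, Angstrom
    block_values: np.ndarray  # (block_count, n_atoms)
    block_sd: np.ndarray  # per-atom SD of the block estimates

    @property
    def block_mean(self) -> np.ndarray:
        return self.block_values.mean(axis=0)


def _rmsf_of(coords: np.ndarray) -> np.ndarray:
    # deviations taken relative to frame 0 first: shift-invariant, and a
    # static trajectory then yields exactly 0 rather than rounding noise
    dev = coords - coords[0]
    dev -= dev.mean(axis=0)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def rmsf(
    traj: Trajectory,
    sel: Selection,
    cfg: AnalysisConfig | None = None,
    topo: NucleosomeTopology | None = None,
) -> RMSFResult:
    """Per-atom RMSF about the time-averaged position, with blocked errors.

    The trajectory must already be superposed.  The analyzed window (after
    discarding the equilibration fraction) is split into ``block_count``
    contiguous blocks; the RMSF is computed per block about the block mean
    and the per-atom standard deviation of the block estimates reported.
    """

    cfg = cfg or AnalysisConfig()
    traj = apply_equilibration(traj, cfg)
    idx = resolve_selection(sel, traj.structure, topo)
    if traj.n_frames < cfg.block_count:
        raise ModelError(
            f"{traj.n_frames} frames is fewer than block_count={cfg.block_count}"
        )
    coords = traj.coords[:, idx]
    pooled = _rmsf_of(coords)
    blocks = np.array_split(np.arange(traj.n_frames), cfg.block_count)
    block_values = np.stack([_rmsf_of(coords[b]) for b in blocks])
    return RMSFResult(
        atom_indices=idx,
        values=pooled,
        block_values=block_values,
        block_sd=block_values.std(axis=0, ddof=1),
    )


def rmsf_per_basepair(
    traj: Trajectory,
    topo: NucleosomeTopology,
    cfg: AnalysisConfig | None = None,
) -> dict[int, float]:
    """DNA RMSF per base pair: the two strands' P-atom values averaged."""

    res = rmsf(
        traj,
        Selection(roles=("DNA_I", "DNA_J"), atom_names=("P",)),
        cfg=cfg,
        topo=topo,
    )
    model = traj.structure
    chain_i = topo.chain_for_role("DNA_I")
    by_atom = dict(zip(res.atom_indices, res.values))
    lookup = {
        (model.chain_ids[i], int(model.residue_indices[i])): i for i in res.atom_indices
    }
    chain_j = topo.chain_for_role("DNA_J")
    out: dict[int, float] = {}
    for i, j in topo.basepair_map.items():
        ai = lookup.get((chain_i, i))
        aj = lookup.get((chain_j, j))
        if ai is None or aj is None:
            continue
        out[i] = float(0.5 * (by_atom[ai] + by_atom[aj]))
    return out


# --------------------------------------------------------------------------
# COM distances

def _com_series(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    masses = traj.structure.masses[idx]
    total = masses.sum()
    if total <= 0:
        raise ModelError("selection has zero total mass")
    return (traj.coords[:, idx] * masses[None, :, None]).sum(axis=1) / total


def com_distance_series(
    traj: Trajectory,
    topo: NucleosomeTopology | None,
    group_a: Selection,
    group_b: Selection,
    n_bins: int = 50,
) -> tuple[TimeSeries, DistributionSummary]:
    """Mass-weighted COM distance between two atom groups, per frame."""

    ia = resolve_selection(group_a, traj.structure, topo)
    ib = resolve_selection(group_b, traj.structure, topo)
    d = np.linalg.norm(_com_series(traj, ia) - _com_series(traj, ib), axis=1)
    series = TimeSeries("com_distance", "Angstrom", traj.times.copy(), d)
    return series, summarize(d, n_bins)


# --------------------------------------------------------------------------
# DNA ends and grooves

def _p_atom(traj: Trajectory, chain: str, resi: int) -> int:
    model = traj.structure
    idx = np.flatnonzero(
        (model.chain_ids == chain)
        & (model.residue_indices == resi)
        & (model.atom_names == "P")
    )
    if idx.size != 1:
        raise ModelError(f"missing P atom for chain {chain} residue {resi}")
    return int(idx[0])


def dna_end_to_dyad_series(
    traj: Trajectory,
    topo: NucleosomeTopology,
    end: str = "entry",
    cfg: AnalysisConfig | None = None,
    n_bins: int = 50,
) -> tuple[TimeSeries, DistributionSummary]:
    """Distance between a terminal base pair's COM and the pseudo-dyad COM.

    ``end='entry'`` is the strand-I 5' terminus side (overridable via the
    topology's ``entry_end``); ``end='exit'`` the opposite terminus.  The
    representative atoms are the P beads of the terminal base pair on both
    strands and of the dyad base pair.
    """

    if end not in ("entry", "exit"):
        raise ModelError(f"end must be 'entry' or 'exit', got {end!r}")
    if cfg is not None:
        traj = apply_equilibration(traj, cfg)
    chain_i = topo.chain_for_role("DNA_I")
    chain_j = topo.chain_for_role("DNA_J")
    residues = sorted(topo.basepair_map)
    first, last = residues[0], residues[-1]
    at_5prime = end == ("entry" if topo.entry_end == "I5prime" else "exit")
    ri = first if at_5prime else last
    rj = topo.basepair_map[ri]
    pair = traj.coords[:, [_p_atom(traj, chain_i, ri), _p_atom(traj, chain_j, rj)]]
    dyad_i, dyad_j = topo.dyad_pair
    dyad = traj.coords[
        :, [_p_atom(traj, chain_i, dyad_i), _p_atom(traj, chain_j, dyad_j)]
    ]
    d = np.linalg.norm(pair.mean(axis=1) - dyad.mean(axis=1), axis=1)
    series = TimeSeries(f"dna_{end}_to_dyad", "Angstrom", traj.times.copy(), d)
    return series, summarize(d, n_bins)


def groove_width_series(
    traj: Trajectory,
    topo: NucleosomeTopology,
    groove: str,
    position: int,
) -> TimeSeries:
    """Cross-strand groove width at a strand-I residue (package convention).

    width(t) = max(|P_I(i) - P_J(basepair(i)+k)| - 5.8 A, 0) with k = 3
    (minor) or 7 (major).
    """

    try:
        k = GROOVE_OFFSETS[groove]
    except KeyError:
        raise ModelError(f"groove must be one of {sorted(GROOVE_OFFSETS)}") from None
    partner = topo.partner(position) + k
    residues = sorted(topo.basepair_map)
    if not residues[0] <= partner <= residues[-1]:
        raise ModelError(
            f"groove offset runs off strand J (residue {partner} outside duplex)"
        )
    ai = _p_atom(traj, topo.chain_for_role("DNA_I"), position)
    aj = _p_atom(traj, topo.chain_for_role("DNA_J"), partner)
    d = np.linalg.norm(traj.coords[:, ai] - traj.coords[:, aj], axis=1)
    width = np.maximum(d - PHOSPHATE_EXCLUSION, 0.0)
    return TimeSeries(f"{groove}_groove_width@{position}", "Angstrom", traj.times.copy(), width)


# --------------------------------------------------------------------------
# scissoring and correlation

def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Dominant principal axis per frame for one bead set (frames, m, 3)."""

    centered = coords - coords.mean(axis=1, keepdims=True)
    axes = np.empty((coords.shape[0], 3))
    for f in range(coords.shape[0]):
        _, _, vt = np.linalg.svd(centered[f], full_matrices=False)
        axes[f] = vt[0]
    # fix sign by continuity with the previous frame
    for f in range(1, coords.shape[0]):
        if np.dot(axes[f], axes[f - 1]) < 0:
            axes[f] = -axes[f]
    return axes


def scissoring_series(
    traj: Trajectory,
    topo: NucleosomeTopology,
    role: str = "CENP-A",
    helix_a: str = "alpha2",
    helix_b: str = "alpha3",
) -> TimeSeries:
    """Angle (degrees) between the principal axes of two helix bead sets."""

    sets = []
    for helix in (helix_a, helix_b):
        sel = Selection(roles=(role,), segment=helix, atom_names=("CA",))
        idx = resolve_selection(sel, traj.structure, topo)
        if idx.size < 4:
            raise ModelError(f"helix {helix!r} of {role} has fewer than 4 residues")
        sets.append(_principal_axes(traj.coords[:, idx]))
    va, vb = sets
    if np.dot(va[0], vb[0]) < 0:  # initial sign: acute crossing at frame 0
        vb = -vb
    cosang = np.clip((va * vb).sum(axis=1), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    return TimeSeries(f"scissor_{helix_a}_{helix_b}", "degrees", traj.times.copy(), angles)


def series_correlation(a: TimeSeries, b: TimeSeries) -> float:
    """Pearson correlation of two raw per-frame series (no smoothing/lag)."""

    if len(a) != len(b):
        raise ModelError("series must have equal length")
    if len(a) < 3:
        raise ModelError("need at least 3 points for a correlation")
    if np.var(a.values) == 0 or np.var(b.values) == 0:
        raise ModelError("correlation undefined for a zero-variance series")
    return float(stats.pearsonr(a.values, b.values).statistic)
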