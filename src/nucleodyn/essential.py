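"""Essential dynamics: PCA over selected atoms, free-energy landscapes,
and amplified mode animations.

Two standard scopes are provided: ``core`` (histone Calpha beads only) and
``nuc`` (histone Calpha plus DNA phosphates with the first and last
``end_truncation_bp`` base pairs of the duplex dropped, so that highly
fluctuating DNA ends do not dominate the leading modes).

The covariance is mass-unweighted and uses the 1/n normalization; the
trajectory must be superposed beforehand.  Eigenvector signs are fixed by
making each mode's largest-magnitude component positive so results are
reproducible across runs and platforms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .io import write_pdb
from .model import (
    AnalysisConfig,
    ModelError,
    NucleosomeTopology,
    Selection,
    StructureModel,
    Trajectory,
    apply_equilibration,
    resolve_selection,
)

__all__ = [
    "PCAResult",
    "FreeEnergyLandscape",
    "scope_selection",
    "pca",
    "free_energy_landscape",
    "export_mode_animation",
]

HISTONE_CORE_ROLES = ("CENP-A", "CENP-A'", "H4", "H4'", "H2A", "H2A'", "H2B", "H2B'")


@dataclass
class PCAResult:
    atom_indices: np.ndarray
    mean: np.ndarray  # (n_atoms, 3)
    eigenvalues: np.ndarray  # Angstrom^2, descending
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    projections: np.ndarray  # (n_frames, n_modes)

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ModelError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ModelError("eigenvalues must be sorted descending")

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)

    def variance_fraction(self, mode: int) -> float:
        """Fraction of total variance carried by 1-based mode number."""

        total = self.eigenvalues.sum()
        return float(self.eigenvalues[mode - 1] / total) if total > 0 else 0.0

    def reconstruct(self, frame_projections: np.ndarray) -> np.ndarray:
        """Invert the projection: coordinates (n_frames, n_atoms, 3)."""

        flat = frame_projections @ self.eigenvectors.T + self.mean.ravel()
        return flat.reshape(len(frame_projections), -1, 3)


def scope_selection(
    scope: str, topo: NucleosomeTopology, cfg: AnalysisConfig
) -> tuple[Selection, ...]:
    """Atom selection for a PCA scope ('core' or 'nuc')."""

    core_roles = tuple(r for r in HISTONE_CORE_ROLES if r in topo.role_map.values())
    core = Selection(roles=core_roles, atom_names=("CA",))
    if scope == "core":
        return (core,)
    if scope == "nuc":
        residues = sorted(topo.basepair_map)
        t = cfg.end_truncation_bp
        lo, hi = residues[0] + t, residues[-1] - t
        if lo > hi:
            raise ModelError("end truncation removes the whole duplex")
        dna = Selection(roles=("DNA_I", "DNA_J"), residue_range=(lo, hi), atom_names=("P",))
        return (core, dna)
    raise ModelError(f"scope must be 'core' or 'nuc', got {scope!r}")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pca(
    traj: Trajectory,
    topo: NucleosomeTopology | None = None,
    sel: Selection | tuple[Selection, ...] | None = None,
    cfg: AnalysisConfig | None = None,
    scope: str | None = None,
) -> PCAResult:
    """PCA of the positional covariance of a superposed trajectory.

    Either pass an explicit selection or a ``scope`` ('core'/'nuc', which
    requires a topology).  Modes up to the covariance rank are returned;
    when the number of frames is smaller than 3N the decomposition runs in
    frame space (Gram matrix) for efficiency, which spans the sampled
    subspace exactly.
    """

    cfg = cfg or AnalysisConfig()
    if scope is not None:
        if topo is None:
            raise ModelError("scope-based PCA requires a topology")
        sel = scope_selection(scope, topo, cfg)
    if sel is None:
        raise ModelError("pca needs a selection or a scope")
    traj = apply_equilibration(traj, cfg)
    if traj.n_frames < 2:
        raise ModelError("PCA needs at least 2 frames")
    idx = resolve_selection(sel, traj.structure, topo)
    X = traj.coords[:, idx].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    n, d = Xc.shape
    rank = min(n - 1, d)
    if d <= n:
        cov = (Xc.T @ Xc) / n
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:rank]
        evals = evals[order]
        evecs = evecs[:, order]
    else:
        gram = (Xc @ Xc.T) / n
        evals_g, U = np.linalg.eigh(gram)
        order = np.argsort(evals_g)[::-1][:rank]
        evals = evals_g[order]
        U = U[:, order]
        scale = np.sqrt(np.maximum(evals * n, 1e-300))
        evecs = Xc.T @ (U / scale)
        norms = np.linalg.norm(evecs, axis=0)
        norms[norms == 0] = 1.0
        evecs /= norms
    evals = np.clip(evals, 0.0, None)
    evecs = _fix_signs(evecs)
    projections = Xc @ evecs
    return PCAResult(
        atom_indices=idx,
        mean=mean.reshape(-1, 3),
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=projections,
    )


@dataclass
class FreeEnergyLandscape:
    """-kT ln(P / P_max) over two mode projections.

    ``free_energy`` is NaN in unsampled bins (flagged by ``sampled``); the
    minimum over sampled bins is exactly 0.
    """

    mode_x: int
    mode_y: int
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray
    sampled: np.ndarray
    kT: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def ruggedness(self) -> float:
        """Mean absolute difference of F between adjacent sampled bins.

        A coarse scalar for comparing how rugged/frustrated two landscapes
        are; larger means more structure at the bin scale.
        """

        F = self.free_energy
        diffs = []
        for dx, dy in ((1, 0), (0, 1)):
            a = F[: F.shape[0] - dx, : F.shape[1] - dy]
            b = F[dx:, dy:]
            ok = ~np.isnan(a) & ~np.isnan(b)
            diffs.append(np.abs(a[ok] - b[ok]))
        alld = np.concatenate(diffs)
        return float(alld.mean()) if alld.size else float("nan")


def free_energy_landscape(
    pcares: PCAResult,
    mode_x: int = 1,
    mode_y: int = 2,
    n_bins: int = 40,
    kT: float = 1.0,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> FreeEnergyLandscape:
    """2D Boltzmann inversion of the projection histogram (modes 1-based).

    ``extent`` optionally fixes the binned region ((xmin, xmax), (ymin,
    ymax)); by default the sampled range is used.
    """

    if n_bins < 5:
        raise ModelError("n_bins must be >= 5")
    for m in (mode_x, mode_y):
        if not 1 <= m <= pcares.n_modes:
            raise ModelError(f"mode {m} out of range (1..{pcares.n_modes})")
        if pcares.eigenvalues[m - 1] <= 0:
            raise ModelError(f"mode {m} has zero variance")
    px = pcares.projections[:, mode_x - 1]
    py = pcares.projections[:, mode_y - 1]
    counts, x_edges, y_edges = np.histogram2d(px, py, bins=n_bins, range=extent)
    sampled = counts > 0
    F = np.full_like(counts, np.nan)
    F[sampled] = kT * (np.log(counts.max()) - np.log(counts[sampled]))
    return FreeEnergyLandscape(mode_x, mode_y, x_edges, y_edges, F, sampled, kT)


def export_mode_animation(
    pcares: PCAResult,
    model: StructureModel,
    mode: int,
    cfg: AnalysisConfig | None = None,
    n_interp: int = 20,
    path: str | os.PathLike | None = None,
) -> np.ndarray:
    """Sinusoidal animation of one mode, amplified for visual clarity.

    Frame k displaces the mean structure by
    ``animation_scale * sqrt(eigenvalue) * sin(2 pi k / n_interp)`` along the
    mode (default scale 5).  Returns the frames (n_interp, n_atoms, 3) and,
    if ``path`` is given, also writes them as a multi-MODEL PDB of the
    selected atoms.
    """

    cfg = cfg or AnalysisConfig()
    if not 1 <= mode <= pcares.n_modes:
        raise ModelError(f"mode {mode} out of range (1..{pcares.n_modes})")
    lam = pcares.eigenvalues[mode - 1]
    vec = pcares.eigenvectors[:, mode - 1].reshape(-1, 3)
    phases = np.sin(2.0 * np.pi * np.arange(n_interp) / n_interp)
    frames = pcares.mean[None] + cfg.animation_scale * np.sqrt(lam) * phases[:, None, None] * vec[None]
    if path is not None:
        sub_atoms = [model.atoms[i] for i in pcares.atom_indices]
        sub_chains = [c for c in model.chains if any(a.chain_id == c for a in sub_atoms)]
        submodel = StructureModel(sub_atoms, sub_chains)
        write_pdb(path, submodel, frames=frames)
    return frames
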