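"""Synthetic pseudo-atomic nucleosome structures and planted-dynamics trajectories.

The generator is a statistical fixture, not a physics simulator: every
dynamic feature is planted with analytically known ground truth so the
analysis modules can be validated by parameter recovery.

A model consists of a 2 x n_bp DNA duplex (one "P" bead per nucleotide)
wound ~1.7 superhelical turns around eight histone chains of Calpha-like
beads arranged as four dimers, optionally plus a CENP-C fragment chain
docked against the CENP-A C-terminal rod.  Trajectory frames are the
reference structure plus

a. i.i.d. isotropic Gaussian bead jitter (SD ``core_sigma``, or
   ``core_sigma_acetyl`` when ``acetyl=True``);
b. sinusoidal rigid displacement of the terminal 10 bp of each DNA end
   along the dyad-to-end direction, with per-end amplitudes (DNA-end
   "breathing");
c. a scalar latent Gaussian series driving both the alpha2-alpha3
   scissoring angle of the 4-helix bundle and a cross-strand minor-groove
   displacement, mixed so their correlation equals ``scissor_groove_rho``;
d. constant offsets: ``dimer_com_shift`` pulls the CENP-A'/H4' dimer
   toward CENP-A/H4 (histone-core compaction), ``cenpc_offset`` pushes the
   CENP-C fragment off the CENP-A C-terminus (interface loss).

All randomness comes from one ``numpy.random.default_rng(seed)`` (PCG64);
the seed is recorded in the trajectory metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import (
    AtomRecord,
    ModelError,
    NucleosomeTopology,
    StructureModel,
    Trajectory,
)

__all__ = [
    "SimulationParams",
    "make_preset",
    "build_nucleosome_model",
    "simulate_trajectory",
    "PRESETS",
]

SUPERHELIX_RADIUS = 41.8  # Angstrom, nucleosomal DNA superhelix
SUPERHELIX_TURNS = 1.7
SUPERHELIX_PITCH = 25.9  # Angstrom rise per superhelical turn
STRAND_SEPARATION = 10.0  # radial offset between the two strand backbones
BREATHING_BP = 10  # terminal base pairs moved as a rigid unit
PROTEIN_BEAD_MASS = 12.011  # carbon; see methods note on masses
DNA_BEAD_MASS = 30.973762  # phosphorus


@dataclass
class SimulationParams:
    """Stated world of the generator.

    Defaults are the *unmodified* regime; :func:`make_preset` returns the
    acetyl regime with the planted contrasts switched on (stronger entry
    breathing, larger coherent scissor/groove motion with rho = 0.82,
    dimer compaction, CENP-C detachment, reduced bead jitter).
    """

    n_bp: int = 146
    n_frames: int = 5000
    frame_dt: float = 0.2  # ns; 5000 frames => 1 us production run
    seed: int = 0
    acetyl: bool = False
    core_sigma: float = 0.35  # Angstrom, per-bead isotropic jitter SD
    core_sigma_acetyl: float = 0.25
    entry_breathing_amp: float = 2.0  # Angstrom
    exit_breathing_amp: float = 1.0
    breathing_period_ns: float = 10.0
    scissor_amp_deg: float = 3.0  # SD of the planted scissoring perturbation
    groove_amp: float = 1.0  # Angstrom SD of the planted groove modulation
    scissor_groove_rho: float = 0.0
    dimer_com_shift: float = 0.0  # Angstrom, CENP-A'/H4' pulled toward CENP-A/H4
    cenpc_offset: float = 0.0  # Angstrom, CENP-C pushed off the C-terminus
    include_cenpc: bool = True
    groove_site: int | None = None  # strand-I residue of the planted groove

    def __post_init__(self) -> None:
        if self.n_bp < 20:
            raise ModelError("n_bp must be >= 20")
        if self.n_frames < 10:
            raise ModelError("n_frames must be >= 10")
        for name in ("core_sigma", "core_sigma_acetyl", "entry_breathing_amp",
                     "exit_breathing_amp", "groove_amp", "scissor_amp_deg"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")
        if abs(self.scissor_groove_rho) > 1:
            raise ModelError("|scissor_groove_rho| must be <= 1")
        if self.frame_dt <= 0:
            raise ModelError("frame_dt must be > 0")

    @property
    def sigma(self) -> float:
        return self.core_sigma_acetyl if self.acetyl else self.core_sigma

    def resolved_groove_site(self) -> int:
        if self.groove_site is not None:
            return self.groove_site
        return max(16, self.n_bp // 3)


PRESETS = {
    "unmodified": {},
    "acetyl": dict(
        acetyl=True,
        entry_breathing_amp=5.0,
        exit_breathing_amp=1.0,
        scissor_amp_deg=10.0,
        groove_amp=3.0,
        scissor_groove_rho=0.82,
        dimer_com_shift=2.0,
        cenpc_offset=6.0,
    ),
}


def make_preset(name: str, **overrides) -> SimulationParams:
    """Build SimulationParams for a named regime ('unmodified' or 'acetyl')."""

    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise ModelError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    base.update(overrides)
    return SimulationParams(**base)


# --------------------------------------------------------------------------
# reference geometry

def _rod(center, direction, n, spacing=1.5) -> np.ndarray:
    center = np.asarray(center, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    return center + offsets[:, None] * d


def _blob(center, n, radius=9.0) -> np.ndarray:
    """Deterministic compact bead cloud (Fibonacci sphere)."""

    center = np.asarray(center, dtype=float)
    k = np.arange(n, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * k
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    shells = radius * (0.55 + 0.45 * ((k % 3) / 2.0))  # three shells, not hollow
    return center + pts * shells[:, None]


def _rotz(points: np.ndarray) -> np.ndarray:
    out = points.copy()
    out[:, 0] *= -1
    out[:, 1] *= -1
    return out


_ALPHA2 = (80, 101)
_ALPHA3 = (105, 126)
_CTERM = (127, 140)
_L1 = (76, 79)
_BUNDLE_HALF_ANGLE = 10.0  # deg; alpha2/alpha3 axes cross at 20 deg


def _cenpa_chain() -> tuple[np.ndarray, np.ndarray]:
    """Reference CENP-A bead positions and residue indices (60..140)."""

    a = math.radians(_BUNDLE_HALF_ANGLE)
    body = _rod((-16.0, 12.0, 8.0), (1.0, 0.2, 0.0), 20)  # residues 60-79 incl. L1
    alpha2 = _rod((0.0, 3.5, 4.0), (math.cos(a), math.sin(a), 0.0), 22)
    loop = _rod((17.0, 2.0, 0.0), (0.0, 1.0, 0.0), 3)  # residues 102-104
    alpha3 = _rod((0.0, 3.5, -4.0), (math.cos(a), -math.sin(a), 0.0), 22)
    cterm = _rod((10.0, -8.0, -10.0), (0.0, -1.0, 0.0), 14)
    coords = np.vstack([body, alpha2, loop, alpha3, cterm])
    residues = np.arange(60, 141)
    return coords, residues


_CHAIN_PLAN = (
    # chain, role, builder key
    ("A", "CENP-A", "cenpa"),
    ("B", "H4", ("blob", (20.0, 16.0, 6.0), 24, 102)),
    ("C", "H2A", ("blob", (-22.0, 8.0, -8.0), 16, 118)),
    ("D", "H2B", ("blob", (-26.0, -6.0, -2.0), 30, 125)),
    ("E", "CENP-A'", "cenpa_prime"),
    ("F", "H4'", ("blob", (-20.0, -16.0, -6.0), 24, 102)),
    ("G", "H2A'", ("blob", (22.0, -8.0, 8.0), 16, 118)),
    ("H", "H2B'", ("blob", (26.0, 6.0, 2.0), 30, 125)),
)


def build_nucleosome_model(params: SimulationParams) -> tuple[StructureModel, NucleosomeTopology]:
    """Deterministic idealized nucleosome: DNA superhelix + 8 histone chains.

    Returns the structure together with a fully populated topology
    (role map, antiparallel base-pair map, central pseudo-dyad pair and the
    named segments used by the analysis modules).
    """

    n = params.n_bp
    atoms: list[AtomRecord] = []
    serial = 1

    def add(chain, resi, name, element, mass, pos, resname):
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                mass=mass,
                chain_id=chain,
                residue_index=int(resi),
                residue_name=resname,
                position=tuple(pos),
            )
        )
        serial += 1

    # histone chains
    for chain, role, spec in _CHAIN_PLAN:
        if spec == "cenpa":
            coords, residues = _cenpa_chain()
        elif spec == "cenpa_prime":
            coords, residues = _cenpa_chain()
            coords = _rotz(coords)
        else:
            _, center, lo, hi = spec
            residues = np.arange(lo, hi + 1)
            coords = _blob(center, len(residues))
        for resi, pos in zip(residues, coords):
            add(chain, resi, "CA", "C", PROTEIN_BEAD_MASS, pos, "ALA")

    # DNA duplex on a superhelix; strand-I residue i (1-based) sits at
    # duplex site i-1, strand-J residue j at site n-j (antiparallel).
    t = np.arange(n) / (n - 1)
    theta = 2.0 * math.pi * SUPERHELIX_TURNS * (t - 0.5)
    z = SUPERHELIX_TURNS * SUPERHELIX_PITCH * (t - 0.5)
    axis = np.stack(
        [SUPERHELIX_RADIUS * np.cos(theta), SUPERHELIX_RADIUS * np.sin(theta), z],
        axis=1,
    )
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    strand_i = axis
    strand_j_sites = axis + STRAND_SEPARATION * radial
    for i in range(1, n + 1):
        add("I", i, "P", "P", DNA_BEAD_MASS, strand_i[i - 1], "DA")
    for j in range(1, n + 1):
        add("J", j, "P", "P", DNA_BEAD_MASS, strand_j_sites[n - j], "DT")

    segments = {
        "CENP-A": {"alpha2": _ALPHA2, "alpha3": _ALPHA3, "cterm": _CTERM, "L1": _L1},
        "CENP-A'": {"alpha2": _ALPHA2, "alpha3": _ALPHA3, "cterm": _CTERM, "L1": _L1},
        "H2A": {"acidic_patch": (86, 92)},
        "H2A'": {"acidic_patch": (86, 92)},
        "H4": {"k79": (75, 83)},
        "H4'": {"k79": (75, 83)},
    }
    role_map = {chain: role for chain, role, _ in _CHAIN_PLAN}
    role_map["I"] = "DNA_I"
    role_map["J"] = "DNA_J"

    if params.include_cenpc:
        # fragment rod parallel to the CENP-A C-terminal rod, 4.5 A away
        coords = _rod((14.5, -8.0, -10.0), (0.0, -1.0, 0.0), 31)
        for resi, pos in zip(range(710, 741), coords):
            add("K", resi, "CA", "C", PROTEIN_BEAD_MASS, pos, "ALA")
        role_map["K"] = "CENP-C"
        segments["CENP-C"] = {"fragment": (710, 740)}

    dyad_i = (n + 1) // 2
    topo = NucleosomeTopology(
        role_map=role_map,
        basepair_map={i: n + 1 - i for i in range(1, n + 1)},
        dyad_pair=(dyad_i, n + 1 - dyad_i),
        segments=segments,
    )
    chains = [c for c, _, _ in _CHAIN_PLAN] + ["I", "J"] + (["K"] if params.include_cenpc else [])
    return StructureModel(atoms, chains), topo


# --------------------------------------------------------------------------
# planted dynamics

def _indices(model: StructureModel, chain: str, lo: int, hi: int) -> np.ndarray:
    return np.flatnonzero(
        (model.chain_ids == chain)
        & (model.residue_indices >= lo)
        & (model.residue_indices <= hi)
    )


def _atom_index(model: StructureModel, chain: str, resi: int) -> int:
    idx = np.flatnonzero((model.chain_ids == chain) & (model.residue_indices == resi))
    if idx.size != 1:
        raise ModelError(f"expected one atom for chain {chain} residue {resi}")
    return int(idx[0])


def simulate_trajectory(
    model: StructureModel,
    topo: NucleosomeTopology,
    params: SimulationParams,
) -> Trajectory:
    """Generate a planted-dynamics trajectory; reproducible from the seed.

    The planted per-frame series (scissor perturbation in degrees, groove
    displacement in Angstrom, per-end breathing displacements) are stored in
    ``Trajectory.metadata['planted']`` for recovery tests.
    """

    n = params.n_bp
    F = params.n_frames
    rng = np.random.default_rng(params.seed)
    ref = model.coords.copy()

    chain_i = topo.chain_for_role("DNA_I")
    chain_j = topo.chain_for_role("DNA_J")

    # (d) constant offsets -------------------------------------------------
    if params.dimer_com_shift:
        prime = np.flatnonzero(np.isin(model.chain_ids, ["E", "F"]))
        anchor = np.flatnonzero(np.isin(model.chain_ids, ["A", "B"]))
        direction = ref[anchor].mean(axis=0) - ref[prime].mean(axis=0)
        direction /= np.linalg.norm(direction)
        ref[prime] += params.dimer_com_shift * direction
    if params.cenpc_offset and "K" in model.chains:
        cenpc = np.flatnonzero(model.chain_ids == "K")
        cterm = _indices(model, "A", *_CTERM)
        direction = ref[cenpc].mean(axis=0) - ref[cterm].mean(axis=0)
        direction /= np.linalg.norm(direction)
        ref[cenpc] += params.cenpc_offset * direction

    times = np.arange(F) * params.frame_dt
    coords = np.broadcast_to(ref, (F,) + ref.shape).copy()

    # (c) coupled scissoring / groove latent -------------------------------
    z = rng.standard_normal(F)
    w = rng.standard_normal(F)
    rho = params.scissor_groove_rho
    latent_groove = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * w
    phi_deg = params.scissor_amp_deg * z
    groove_disp = params.groove_amp * latent_groove

    half = np.radians(phi_deg) / 2.0
    for chain in ("A", "E"):
        for (lo, hi), sign in ((_ALPHA2, +1.0), (_ALPHA3, -1.0)):
            idx = _indices(model, chain, lo, hi)
            centroid = ref[idx].mean(axis=0)
            rel = ref[idx] - centroid
            c = np.cos(sign * half)[:, None]
            s = np.sin(sign * half)[:, None]
            x, y = rel[:, 0], rel[:, 1]
            coords[:, idx, 0] = centroid[0] + c * x[None, :] - s * y[None, :]
            coords[:, idx, 1] = centroid[1] + s * x[None, :] + c * y[None, :]
            # z component is unchanged by a rotation about the z axis

    site = params.resolved_groove_site()
    partner3 = topo.basepair_map[site] + 3
    if partner3 - 2 < 1 or partner3 + 2 > n:
        raise ModelError(f"groove site {site} leaves its strand-J window off the duplex")
    window = range(partner3 - 2, partner3 + 3)
    p_i = ref[_atom_index(model, chain_i, site)]
    p_j = ref[_atom_index(model, chain_j, partner3)]
    u_groove = (p_j - p_i) / np.linalg.norm(p_j - p_i)
    widx = np.array([_atom_index(model, chain_j, r) for r in window])
    coords[:, widx, :] += groove_disp[:, None, None] * u_groove[None, None, :]

    # (b) DNA-end breathing ------------------------------------------------
    dyad_i, dyad_j = topo.dyad_pair
    dyad_com = 0.5 * (
        ref[_atom_index(model, chain_i, dyad_i)] + ref[_atom_index(model, chain_j, dyad_j)]
    )
    omega = 2.0 * math.pi / params.breathing_period_ns
    entry_series = params.entry_breathing_amp * np.sin(omega * times)
    exit_series = params.exit_breathing_amp * np.sin(omega * times + math.pi / 2.0)
    for which, series in (("entry", entry_series), ("exit", exit_series)):
        if which == "entry":
            res_i = range(1, BREATHING_BP + 1)
            res_j = range(n - BREATHING_BP + 1, n + 1)
            tip = 0.5 * (
                ref[_atom_index(model, chain_i, 1)] + ref[_atom_index(model, chain_j, n)]
            )
        else:
            res_i = range(n - BREATHING_BP + 1, n + 1)
            res_j = range(1, BREATHING_BP + 1)
            tip = 0.5 * (
                ref[_atom_index(model, chain_i, n)] + ref[_atom_index(model, chain_j, 1)]
            )
        unit = (tip - dyad_com) / np.linalg.norm(tip - dyad_com)
        idx = np.concatenate(
            [
                [_atom_index(model, chain_i, r) for r in res_i],
                [_atom_index(model, chain_j, r) for r in res_j],
            ]
        ).astype(int)
        coords[:, idx, :] += series[:, None, None] * unit[None, None, :]

    # (a) isotropic bead jitter ---------------------------------------------
    sigma = params.sigma
    if sigma > 0:
        coords += rng.standard_normal(coords.shape) * sigma

    metadata = {
        "seed": params.seed,
        "regime": "acetyl" if params.acetyl else "unmodified",
        "frame_dt_ns": params.frame_dt,
        "planted": {
            "scissor_deg": phi_deg,
            "groove_disp": groove_disp,
            "entry_disp": entry_series,
            "exit_disp": exit_series,
            "rho": rho,
            "groove_site": site,
            "base_scissor_angle_deg": 2 * _BUNDLE_HALF_ANGLE,
        },
    }
    return Trajectory(model, coords, times, metadata=metadata)
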