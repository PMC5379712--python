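import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucleodyn.geometry import (
    PHOSPHATE_EXCLUSION,
    TimeSeries,
    com_distance_series,
    dna_end_to_dyad_series,
    groove_width_series,
    kabsch_rotation,
    rmsf,
    rmsf_per_basepair,
    scissoring_series,
    series_correlation,
    superpose,
)
from nucleodyn.model import (
    AnalysisConfig,
    ModelError,
    NucleosomeTopology,
    Selection,
)
from nucleodyn.synth import SimulationParams, build_nucleosome_model, simulate_trajectory

from conftest import make_structure, make_trajectory

NO_EQUIL = AnalysisConfig(equilibration_fraction=0.0)
ALL_CA = Selection(atom_names=("CA",))


def duplex(n_bp=11, rise=3.4, separation=11.0):
    """Straight rigid DNA ladder: strand I along +x, strand J offset in y."""

    pos, chains, names, residues = [], [], [], []
    for i in range(1, n_bp + 1):
        pos.append([i * rise, 0.0, 0.0])
        chains.append("I")
        names.append("P")
        residues.append(i)
    for j in range(1, n_bp + 1):
        site = n_bp + 1 - j
        pos.append([site * rise, separation, 0.0])
        chains.append("J")
        names.append("P")
        residues.append(j)
    model = make_structure(pos, chain_ids=chains, names=names, residue_indices=residues)
    dyad = (n_bp + 1) // 2
    topo = NucleosomeTopology(
        role_map={"I": "DNA_I", "J": "DNA_J"},
        basepair_map={i: n_bp + 1 - i for i in range(1, n_bp + 1)},
        dyad_pair=(dyad, n_bp + 1 - dyad),
    )
    return model, topo


class TestSuperpose:
    def test_pure_rotations_removed(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(-10, 10, (12, 3))
        frames = np.stack(
            [ref @ Rotation.random(random_state=i).as_matrix().T + i for i in range(6)]
        )
        model = make_structure(ref)
        traj = make_trajectory(model, frames)
        fit = superpose(traj, ALL_CA)
        spread = fit.coords - fit.coords.mean(axis=0)
        assert np.abs(spread).max() < 1e-6

    def test_idempotent_on_aligned(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(-10, 10, (8, 3))
        frames = ref[None] + rng.normal(scale=0.01, size=(5, 8, 3))
        model = make_structure(ref)
        traj = make_trajectory(model, frames)
        once = superpose(traj, ALL_CA)
        twice = superpose(once, ALL_CA)
        np.testing.assert_allclose(once.coords, twice.coords, atol=1e-8)

    def test_kabsch_is_proper_rotation(self):
        tetra = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        R = kabsch_rotation(tetra @ R90.T, tetra)
        assert np.linalg.det(R) == pytest.approx(1.0)
        np.testing.assert_allclose(R @ R90, np.eye(3), atol=1e-12)

    def test_kabsch_matches_scipy(self):
        rng = np.random.default_rng(2)
        P = rng.uniform(-5, 5, (10, 3))
        P -= P.mean(axis=0)
        Q = P @ Rotation.random(random_state=3).as_matrix().T
        ours = kabsch_rotation(Q, P)
        ref, _ = Rotation.align_vectors(P, Q)
        np.testing.assert_allclose(ours, ref.as_matrix(), atol=1e-10)

    def test_collinear_reference_rejected(self):
        model = make_structure([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        traj = make_trajectory(model, np.zeros((3, 3, 3)))
        with pytest.raises(ModelError, match="collinear"):
            superpose(traj, ALL_CA)


class TestRMSF:
    def test_static_is_zero(self):
        model = make_structure(np.random.default_rng(3).uniform(0, 5, (4, 3)))
        traj = make_trajectory(model, np.tile(model.coords, (6, 1, 1)))
        res = rmsf(traj, ALL_CA, NO_EQUIL)
        np.testing.assert_array_equal(res.values, 0.0)

    def test_two_point_alternation(self):
        model = make_structure([[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        frames = np.tile(model.coords, (10, 1, 1))
        frames[1::2, 0, 0] = 2.0  # atom 0 alternates between x=0 and x=2
        traj = make_trajectory(model, frames)
        res = rmsf(traj, ALL_CA, NO_EQUIL)
        assert res.values[0] == pytest.approx(1.0)  # d/2 with d = 2
        assert res.values[1] == 0.0

    def test_fewer_frames_than_blocks(self):
        model = make_structure([[0, 0, 0]])
        traj = make_trajectory(model, np.zeros((2, 1, 3)))
        with pytest.raises(ModelError, match="block"):
            rmsf(traj, ALL_CA, AnalysisConfig(equilibration_fraction=0.0, block_count=3))

    def test_matches_mdanalysis(self):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rms import RMSF as MDARMSF

        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 10, (6, 3))
        frames = ref[None] + rng.normal(scale=0.7, size=(40, 6, 3))
        model = make_structure(ref)
        traj = make_trajectory(model, frames)
        ours = rmsf(traj, ALL_CA, NO_EQUIL).values

        u = mda.Universe.empty(6, trajectory=True)
        u.load_new(frames.astype(np.float32))
        theirs = MDARMSF(u.atoms).run().results.rmsf
        np.testing.assert_allclose(ours, theirs, rtol=1e-4)

    def test_per_basepair_average(self):
        model, topo = duplex()
        traj = make_trajectory(model, np.tile(model.coords, (6, 1, 1)))
        per_bp = rmsf_per_basepair(traj, topo, NO_EQUIL)
        assert set(per_bp) == set(topo.basepair_map)
        assert all(v == 0.0 for v in per_bp.values())


class TestCOMDistance:
    def test_3_4_5_static(self):
        model = make_structure([[0, 0, 0], [3, 4, 0]], chain_ids=["A", "B"])
        traj = make_trajectory(model, np.tile(model.coords, (5, 1, 1)))
        series, summary = com_distance_series(
            traj, None, Selection(chain_ids=("A",)), Selection(chain_ids=("B",))
        )
        np.testing.assert_allclose(series.values, 5.0)
        assert summary.mean == pytest.approx(5.0)
        assert summary.variance == pytest.approx(0.0)

    def test_midpoint_weighting(self):
        model = make_structure(
            [[0, 0, 0], [2, 0, 0], [5, 0, 0]],
            chain_ids=["A", "A", "B"],
            masses=[1.0, 1.0, 7.0],
        )
        traj = make_trajectory(model, np.tile(model.coords, (3, 1, 1)))
        series, _ = com_distance_series(
            traj, None, Selection(chain_ids=("A",)), Selection(chain_ids=("B",))
        )
        np.testing.assert_allclose(series.values, 4.0)

    def test_symmetric_in_group_order(self, quiet_system):
        model, topo, traj = quiet_system
        a = Selection(roles=("CENP-A", "H4"), atom_names=("CA",))
        b = Selection(roles=("CENP-A'", "H4'"), atom_names=("CA",))
        s1, _ = com_distance_series(traj, topo, a, b)
        s2, _ = com_distance_series(traj, topo, b, a)
        np.testing.assert_array_equal(s1.values, s2.values)


class TestDNAEnds:
    def test_straight_duplex_hand_computed(self):
        model, topo = duplex(n_bp=11, rise=3.4, separation=11.0)
        traj = make_trajectory(model, np.tile(model.coords, (4, 1, 1)))
        series, _ = dna_end_to_dyad_series(traj, topo, "entry")
        # entry bp COM is at x = (3.4 + 3.4)/2 (I:1 and J:11 share a site),
        # dyad bp at x = 6*3.4; both at y = 5.5
        expected = abs(6 * 3.4 - 3.4)
        np.testing.assert_allclose(series.values, expected)

    def test_symmetric_static_fixture(self):
        model, topo = duplex(n_bp=11)
        traj = make_trajectory(model, np.tile(model.coords, (4, 1, 1)))
        entry, _ = dna_end_to_dyad_series(traj, topo, "entry")
        exit_, _ = dna_end_to_dyad_series(traj, topo, "exit")
        np.testing.assert_allclose(entry.values, exit_.values)

    def test_planted_breathing_asymmetry(self):
        params = SimulationParams(
            n_bp=40, n_frames=1000, seed=10, core_sigma=0.1,
            entry_breathing_amp=5.0, exit_breathing_amp=1.0,
            scissor_amp_deg=0, groove_amp=0, include_cenpc=False,
        )
        model, topo = build_nucleosome_model(params)
        traj = simulate_trajectory(model, topo, params)
        entry, _ = dna_end_to_dyad_series(traj, topo, "entry")
        exit_, _ = dna_end_to_dyad_series(traj, topo, "exit")
        assert entry.values.var() > exit_.values.var()


class TestGrooveWidth:
    def test_constructed_cross_strand_distance(self):
        # separation chosen so the P-P distance at offset 3 is 11.8 A:
        # Delta-x = 3 * rise, separation = sqrt(11.8^2 - (3*rise)^2)
        rise = 3.0
        sep = np.sqrt(11.8**2 - (3 * rise) ** 2)
        model, topo = duplex(n_bp=11, rise=rise, separation=sep)
        traj = make_trajectory(model, np.tile(model.coords, (3, 1, 1)))
        series = groove_width_series(traj, topo, "minor", position=4)
        np.testing.assert_allclose(series.values, 11.8 - PHOSPHATE_EXCLUSION)
        assert series.values[0] == pytest.approx(6.0)

    def test_invariant_under_rigid_rotation(self):
        model, topo = duplex()
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        frames = np.stack([model.coords, model.coords @ R.T + 3.0])
        traj = make_trajectory(model, frames)
        series = groove_width_series(traj, topo, "minor", position=4)
        assert series.values[0] == pytest.approx(series.values[1])

    def test_offset_runs_off_strand(self):
        model, topo = duplex(n_bp=11)
        traj = make_trajectory(model, np.tile(model.coords, (3, 1, 1)))
        with pytest.raises(ModelError, match="off strand"):
            groove_width_series(traj, topo, "major", position=4)  # partner 8+7 > 11

    def test_unknown_groove(self):
        model, topo = duplex()
        traj = make_trajectory(model, np.tile(model.coords, (3, 1, 1)))
        with pytest.raises(ModelError, match="groove"):
            groove_width_series(traj, topo, "middle", position=4)


class TestScissoring:
    def _line_pair_series(self, angle_deg):
        """Two 5-bead straight lines crossing at the given angle."""

        a = np.radians(angle_deg)
        t = np.arange(5) - 2.0
        line1 = np.stack([t, np.zeros(5), np.zeros(5)], axis=1)
        line2 = np.stack([t * np.cos(a), t * np.sin(a), np.zeros(5)], axis=1) + [0, 5, 0]
        pos = np.vstack([line1, line2])
        model = make_structure(
            pos,
            chain_ids=["A"] * 10,
            residue_indices=list(range(80, 85)) + list(range(105, 110)),
        )
        topo = NucleosomeTopology(
            role_map={"A": "CENP-A", "I": "DNA_I", "J": "DNA_J"},
            basepair_map={1: 2, 2: 1},
            dyad_pair=(1, 2),
            segments={"CENP-A": {"alpha2": (80, 84), "alpha3": (105, 109)}},
        )
        # topology requires DNA chains; give the model two dummy P beads
        dup, _ = duplex(n_bp=2)
        from nucleodyn.model import StructureModel

        merged = StructureModel(model.atoms + dup.atoms)
        traj = make_trajectory(merged, np.tile(merged.coords, (4, 1, 1)))
        return scissoring_series(traj, topo)

    def test_parallel_lines(self):
        series = self._line_pair_series(0.0)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-6)

    def test_perpendicular_lines(self):
        series = self._line_pair_series(90.0)
        np.testing.assert_allclose(series.values, 90.0, atol=1e-6)

    def test_planted_oscillation_recovered(self):
        params = SimulationParams(
            n_bp=20, n_frames=3000, seed=11, core_sigma=0.05,
            entry_breathing_amp=0, exit_breathing_amp=0,
            scissor_amp_deg=5.0, groove_amp=0, include_cenpc=False,
        )
        model, topo = build_nucleosome_model(params)
        traj = simulate_trajectory(model, topo, params)
        series = scissoring_series(traj, topo)
        assert series.values.mean() == pytest.approx(20.0, abs=0.5)
        assert series.values.std() == pytest.approx(5.0, rel=0.10)

    def test_short_helix_rejected(self, quiet_system):
        model, topo, traj = quiet_system
        topo.segments["CENP-A"]["stub"] = (80, 82)
        try:
            with pytest.raises(ModelError, match="fewer than 4"):
                scissoring_series(traj, topo, helix_a="stub")
        finally:
            del topo.segments["CENP-A"]["stub"]


class TestCorrelation:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return TimeSeries("s", "x", np.arange(len(values)) + 1.0, values)

    def test_self_correlation(self):
        a = self._series([1, 2, 3, 4, 2])
        assert series_correlation(a, a) == pytest.approx(1.0)

    def test_anticorrelation(self):
        a = self._series([1, 2, 3, 4, 2])
        b = self._series(-a.values)
        assert series_correlation(a, b) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = self._series([1, 2, 3])
        b = self._series([5, 5, 5])
        with pytest.raises(ModelError, match="zero-variance"):
            series_correlation(a, b)

    def test_length_mismatch(self):
        with pytest.raises(ModelError, match="length"):
            series_correlation(self._series([1, 2, 3]), self._series([1, 2]))
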