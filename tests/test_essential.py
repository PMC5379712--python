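import numpy as np
import pytest

from nucleodyn.essential import (
    PCAResult,
    export_mode_animation,
    free_energy_landscape,
    pca,
    scope_selection,
)
from nucleodyn.io import read_pdb
from nucleodyn.model import AnalysisConfig, ModelError, Selection
from nucleodyn.synth import SimulationParams, build_nucleosome_model, simulate_trajectory

from conftest import make_structure, make_trajectory

NO_EQUIL = AnalysisConfig(equilibration_fraction=0.0)
ALL_CA = Selection(atom_names=("CA",))


def planted_mode_trajectory(n_atoms=40, n_frames=300, amp=3.0, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ref = rng.uniform(-15, 15, (n_atoms, 3))
    v = rng.standard_normal(3 * n_atoms)
    v /= np.linalg.norm(v)
    drive = amp * np.sin(2 * np.pi * np.arange(n_frames) / 50)
    coords = ref[None] + (drive[:, None] * v[None]).reshape(n_frames, n_atoms, 3)
    if jitter:
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    model = make_structure(ref)
    return make_trajectory(model, coords), v


class TestPCA:
    def test_static_trajectory_zero_eigenvalues(self):
        model = make_structure(np.random.default_rng(1).uniform(0, 10, (5, 3)))
        traj = make_trajectory(model, np.tile(model.coords, (10, 1, 1)))
        res = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_planted_mode_recovery(self):
        traj, v = planted_mode_trajectory(jitter=0.02, seed=2)
        res = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        assert abs(np.dot(res.eigenvectors[:, 0], v)) > 0.99
        assert res.variance_fraction(1) > 0.95

    def test_trace_identity(self):
        traj, _ = planted_mode_trajectory(jitter=0.5, seed=3)
        res = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        X = traj.coords.reshape(traj.n_frames, -1)
        total = ((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert abs(res.eigenvalues.sum() - total) / total < 1e-10

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        traj, _ = planted_mode_trajectory(n_atoms=10, n_frames=120, jitter=0.4, seed=4)
        res = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        X = traj.coords.reshape(120, -1)
        sk = sklearn.PCA(n_components=10).fit(X)
        # sklearn uses the 1/(n-1) normalization
        np.testing.assert_allclose(
            res.eigenvalues[:10], sk.explained_variance_ * (119 / 120), rtol=1e-8
        )
        for k in range(3):
            cos = abs(np.dot(res.eigenvectors[:, k], sk.components_[k]))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_gram_path_matches_direct_path(self):
        # more coordinates than frames exercises the frame-space route
        traj, _ = planted_mode_trajectory(n_atoms=50, n_frames=40, jitter=0.3, seed=5)
        res_gram = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        assert res_gram.n_modes == 39
        sub = traj.slice_frames(0, 40)
        X = sub.coords.reshape(40, -1)
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc.T @ Xc / 40)[::-1]
        np.testing.assert_allclose(res_gram.eigenvalues, evals[:39], atol=1e-10)

    def test_projection_of_mean_is_zero(self):
        traj, _ = planted_mode_trajectory(jitter=0.2, seed=6)
        res = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        np.testing.assert_allclose(res.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_reconstruction(self):
        traj, _ = planted_mode_trajectory(n_atoms=20, n_frames=60, jitter=0.3, seed=7)
        res = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        rec = res.reconstruct(res.projections)
        np.testing.assert_allclose(rec, traj.coords, atol=1e-6)

    def test_orthonormal_eigenvectors(self):
        traj, _ = planted_mode_trajectory(n_atoms=15, n_frames=100, jitter=0.3, seed=8)
        res = pca(traj, sel=ALL_CA, cfg=NO_EQUIL)
        gram = res.eigenvectors.T @ res.eigenvectors
        np.testing.assert_allclose(gram, np.eye(res.n_modes), atol=1e-8)

    def test_too_few_frames(self):
        model = make_structure([[0, 0, 0], [1, 0, 0]])
        traj = make_trajectory(model, np.zeros((1, 2, 3)))
        with pytest.raises(ModelError, match="frame"):
            pca(traj, sel=ALL_CA, cfg=NO_EQUIL)


class TestScopes:
    def test_nuc_scope_truncates_ten_bp_per_end(self, quiet_system):
        model, topo, traj = quiet_system  # 24 bp
        cfg = AnalysisConfig(equilibration_fraction=0.0, end_truncation_bp=10)
        sels = scope_selection("nuc", topo, cfg)
        res = pca(traj, topo=topo, sel=sels, cfg=cfg)
        names = model.atom_names[res.atom_indices]
        # (n_bp - 2*10) phosphates per strand
        assert int((names == "P").sum()) == 2 * (24 - 20)

    def test_core_scope_is_histone_calpha_only(self, quiet_system):
        model, topo, traj = quiet_system
        res = pca(traj, topo=topo, scope="core", cfg=NO_EQUIL)
        names = model.atom_names[res.atom_indices]
        assert set(names) == {"CA"}
        chains = set(model.chain_ids[res.atom_indices])
        assert "K" not in chains  # CENP-C is not part of the histone core
        assert "I" not in chains and "J" not in chains

    def test_unknown_scope(self, quiet_system):
        _, topo, traj = quiet_system
        with pytest.raises(ModelError, match="scope"):
            pca(traj, topo=topo, scope="everything", cfg=NO_EQUIL)


class TestFreeEnergyLandscape:
    def _pcares(self, proj):
        proj = np.asarray(proj, dtype=float)
        var = proj.var(axis=0)
        order = np.argsort(var)[::-1]
        return PCAResult(
            atom_indices=np.arange(2),
            mean=np.zeros((2, 3)),
            eigenvalues=var[order],
            eigenvectors=np.eye(6)[:, :2],
            projections=proj[:, order],
        )

    def test_single_occupied_bin(self):
        rng = np.random.default_rng(0)
        proj = rng.normal(0.0, 0.01, (50, 2))  # all mass in the central bin
        fel = free_energy_landscape(
            self._pcares(proj), 1, 2, n_bins=5, extent=((-10, 10), (-10, 10))
        )
        assert fel.sampled.sum() == 1
        assert fel.free_energy[fel.sampled][0] == 0.0
        assert np.isnan(fel.free_energy[~fel.sampled]).all()

    def test_uniform_projections_flat(self):
        rng = np.random.default_rng(1)
        proj = rng.uniform(-1, 1, (200000, 2))
        fel = free_energy_landscape(self._pcares(proj), 1, 2, n_bins=10)
        assert fel.sampled.all()
        assert np.nanmin(fel.free_energy) == 0.0
        # multinomial noise: per-bin count 2000 +- ~45, so F < ~0.12
        assert np.nanmax(fel.free_energy) < 0.2

    def test_unsampled_bins_flagged_not_zero(self):
        rng = np.random.default_rng(2)
        proj = np.concatenate(
            [rng.normal(-5, 0.1, (500, 2)), rng.normal(5, 0.1, (500, 2))]
        )
        fel = free_energy_landscape(self._pcares(proj), 1, 2, n_bins=21)
        assert not fel.sampled.all()
        assert np.isnan(fel.free_energy[~fel.sampled]).all()

    def test_degenerate_mode_rejected(self):
        proj = np.zeros((100, 2))
        proj[:, 0] = np.random.default_rng(3).normal(size=100)
        res = self._pcares(proj)
        with pytest.raises(ModelError, match="zero variance"):
            free_energy_landscape(res, 1, 2)

    def test_min_bins(self):
        rng = np.random.default_rng(4)
        res = self._pcares(rng.normal(size=(100, 2)))
        with pytest.raises(ModelError, match="n_bins"):
            free_energy_landscape(res, 1, 2, n_bins=3)


class TestModeAnimation:
    def _result(self):
        traj, v = planted_mode_trajectory(n_atoms=12, n_frames=100, jitter=0.05, seed=9)
        return traj, pca(traj, sel=ALL_CA, cfg=NO_EQUIL)

    def test_scale_zero_is_static_mean(self):
        traj, res = self._result()
        cfg = AnalysisConfig(equilibration_fraction=0.0, animation_scale=0.0)
        frames = export_mode_animation(res, traj.structure, 1, cfg, n_interp=8)
        for f in frames:
            np.testing.assert_allclose(f, res.mean, atol=1e-12)

    def test_extremes_at_five_sqrt_lambda(self):
        traj, res = self._result()
        cfg = AnalysisConfig(equilibration_fraction=0.0, animation_scale=5.0)
        frames = export_mode_animation(res, traj.structure, 1, cfg, n_interp=8)
        lam = res.eigenvalues[0]
        disp = (frames - res.mean[None]).reshape(8, -1)
        amps = disp @ res.eigenvectors[:, 0]
        assert amps.max() == pytest.approx(5 * np.sqrt(lam), rel=1e-12)
        assert amps.min() == pytest.approx(-5 * np.sqrt(lam), rel=1e-12)

    def test_round_trip_recovers_direction(self, tmp_path):
        traj, res = self._result()
        path = tmp_path / "mode1.pdb"
        frames = export_mode_animation(
            res, traj.structure, 1, NO_EQUIL, n_interp=16, path=path
        )
        model = read_pdb(path)  # first MODEL only; use returned frames for PCA
        assert model.n_atoms == len(res.atom_indices)
        anim = make_trajectory(make_structure(frames[0]), frames)
        res2 = pca(anim, sel=ALL_CA, cfg=NO_EQUIL)
        cos = abs(np.dot(res2.eigenvectors[:, 0], res.eigenvectors[:, 0]))
        assert cos > 0.999

    def test_mode_out_of_range(self):
        _, res = self._result()
        with pytest.raises(ModelError, match="out of range"):
            export_mode_animation(res, None, res.n_modes + 1, NO_EQUIL)
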