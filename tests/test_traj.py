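"""Conformational metrics: superposition, RMSF, RoG, SASA, DCCM, PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepfunnel import synth
from pepfunnel.traj import (
    TrajectoryEnsemble,
    align_ensemble,
    dccm,
    pca_project,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    sasa,
    select,
    superpose_rmsd,
)


def _random_frame(n=20, seed=0):
    return np.random.default_rng(seed).normal(scale=5.0, size=(n, 3))


class TestSuperposition:
    def test_rigid_copy_superposes_to_zero(self):
        a = _random_frame()
        rot = Rotation.random(random_state=1).as_matrix()
        b = a @ rot.T + np.array([3.0, -2.0, 7.0])
        (_, _), rmsd = superpose_rmsd(b, a)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_identical_frames_identity_transform(self):
        a = _random_frame()
        (rot, trans), rmsd = superpose_rmsd(a, a)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self):
        a, b = _random_frame(seed=1), _random_frame(seed=2)
        (rot, _), _ = superpose_rmsd(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_symmetric_and_rigid_invariant(self):
        a, b = _random_frame(seed=3), _random_frame(seed=4)
        _, fwd = superpose_rmsd(a, b)
        _, back = superpose_rmsd(b, a)
        assert fwd == pytest.approx(back)
        rot = Rotation.random(random_state=5).as_matrix()
        _, moved = superpose_rmsd(a @ rot.T + 11.0, b)
        assert moved == pytest.approx(fwd)

    def test_matches_scipy_align_vectors(self):
        """Independent oracle: scipy's Wahba solver on centred coordinates."""
        a, b = _random_frame(seed=6), _random_frame(seed=7)
        (_, _), ours = superpose_rmsd(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        scipy_rmsd = rssd / np.sqrt(a.shape[0])
        assert ours == pytest.approx(scipy_rmsd, abs=1e-8)

    def test_one_displaced_atom_closed_form(self):
        # square corners with one atom pushed radially outward by d: symmetry
        # pins the optimal fit to a pure translation of d/4 along the push
        # direction, giving RMSD^2 = (3/4 d)^2/4 + 3 (d/4)^2/4 = 3 d^2/16
        base = np.array([[1.0, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]])
        for d in (0.01, 0.1, 0.5):
            moved = base.copy()
            moved[0] += d / np.sqrt(2) * np.array([1.0, 1.0, 0.0])
            _, rmsd = superpose_rmsd(moved, base)
            assert rmsd == pytest.approx(d * np.sqrt(3) / 4, rel=1e-9)

    def test_degenerate_selections_rejected(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        collinear = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            superpose_rmsd(collinear, collinear)

    def test_rmsd_series_zero_for_static_trajectory(self):
        ens, _ = synth.gen_trajectory(5, 10, sigma=0.0, seed=0)
        np.testing.assert_allclose(rmsd_series(ens), 0.0, atol=1e-8)


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        ens, _ = synth.gen_trajectory(10, 8, sigma=0.0, seed=0)
        _, values = rmsf(ens, prealigned=True)
        np.testing.assert_allclose(values, 0.0, atol=1e-10)

    def test_isotropic_noise_closed_form(self):
        # per-axis sigma 0.5 -> RMSF = sqrt(3)*0.5 ~ 0.866
        ens, truth = synth.gen_trajectory(2000, 30, sigma=0.5, seed=3)
        _, values = rmsf(ens, prealigned=True)
        np.testing.assert_allclose(values, truth["rmsf"], rtol=0.05)
        assert values.mean() == pytest.approx(np.sqrt(3) * 0.5, rel=0.05)

    def test_planted_double_variance_block(self):
        sigma = np.full(30, 0.4)
        sigma[10:20] = 0.4 * np.sqrt(2)
        ens, truth = synth.gen_trajectory(2000, 30, sigma=sigma, seed=4)
        _, values = rmsf(ens, prealigned=True)
        ratio = values[10:20].mean() / values[:10].mean()
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)

    def test_single_frame_rejected(self):
        ens, _ = synth.gen_trajectory(2, 5, sigma=0.1, seed=0)
        ens_single = TrajectoryEnsemble(
            coords=ens.coords[:1],
            residue_ids=ens.residue_ids,
            residue_names=ens.residue_names,
            atom_names=ens.atom_names,
        )
        with pytest.raises(ValueError):
            rmsf(ens_single)


class TestRadiusOfGyration:
    def test_single_point_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_unit_square_corners(self):
        corners = np.array(
            [[1.0, 1, 0], [1.0, -1, 0], [-1.0, 1, 0], [-1.0, -1, 0]]
        )
        assert radius_of_gyration(corners) == pytest.approx(np.sqrt(2))

    def test_homogeneous_under_scaling(self):
        frame = _random_frame(seed=8)
        assert radius_of_gyration(3.0 * frame) == pytest.approx(
            3.0 * radius_of_gyration(frame)
        )

    def test_mass_weighting_shifts_towards_heavy_atoms(self):
        frame = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        uniform = radius_of_gyration(frame)
        weighted = radius_of_gyration(frame, weights=np.array([9.0, 1.0]))
        assert weighted < uniform


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        total, _ = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4)
        assert total == pytest.approx(4 * np.pi * 3.0**2, rel=1e-3)

    def test_distant_atoms_additive(self):
        frame = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.6, 1.9])
        total, per_atom = sasa(frame, radii)
        iso = [4 * np.pi * (r + 1.4) ** 2 for r in radii]
        np.testing.assert_allclose(per_atom, iso, rtol=1e-3)
        assert total == pytest.approx(sum(iso), rel=1e-3)

    def test_buried_atom_zero(self):
        # small atom at the centre of a much larger sphere
        frame = np.zeros((2, 3))
        frame[0] = [0.1, 0.0, 0.0]
        total, per_atom = sasa(frame, np.array([1.0, 8.0]))
        assert per_atom[0] == 0.0

    def test_quadrature_convergence(self):
        frame = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        radii = np.array([1.7, 1.7])
        coarse, _ = sasa(frame, radii, n_points=960)
        fine, _ = sasa(frame, radii, n_points=1920)
        assert abs(fine - coarse) / fine < 0.005

    def test_duplicate_centres_warn_and_bury(self):
        frame = np.zeros((2, 3))
        with pytest.warns(UserWarning):
            total, per_atom = sasa(frame, np.array([1.5, 1.5]))
        assert per_atom[1] == 0.0
        assert per_atom[0] == pytest.approx(4 * np.pi * 2.9**2, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([-1.0]))
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([1.0]), n_points=50)


class TestDccm:
    def test_common_translation_fully_correlated(self):
        rng = np.random.default_rng(0)
        base = _random_frame(10, seed=1)
        shifts = rng.normal(size=(50, 1, 3))
        ens = TrajectoryEnsemble(
            coords=base[None] + shifts,
            residue_ids=np.arange(1, 11),
            residue_names=np.full(10, "ALA"),
            atom_names=np.full(10, "CA"),
        )
        matrix = dccm(ens, prealigned=True).matrix
        np.testing.assert_allclose(matrix, 1.0, atol=1e-10)

    def test_anti_correlated_pair(self):
        ens, _ = synth.gen_trajectory(
            500, 6, sigma=0.01,
            blocks=[synth.CorrelatedBlock(atoms=(0, 1), amplitude=1.0, signs=(1, -1))],
            seed=5,
        )
        matrix = dccm(ens, prealigned=True).matrix
        assert matrix[0, 1] == pytest.approx(-1.0, abs=0.02)

    def test_correlated_block_recovered(self):
        ens, _ = synth.gen_trajectory(
            500, 12, sigma=0.05,
            blocks=[synth.CorrelatedBlock(atoms=tuple(range(5)), amplitude=1.0)],
            seed=4,
        )
        matrix = dccm(ens, prealigned=True).matrix
        assert matrix[:5, :5].min() > 0.9

    def test_independent_jitter_near_zero_off_diagonal(self):
        frames = 2000
        ens, _ = synth.gen_trajectory(frames, 10, sigma=0.5, seed=6)
        matrix = dccm(ens, prealigned=True).matrix
        off = matrix[~np.eye(10, dtype=bool)]
        assert abs(off.mean()) < 3 / np.sqrt(frames)

    def test_matrix_invariants(self):
        ens, _ = synth.gen_trajectory(100, 8, sigma=0.3, seed=7)
        matrix = dccm(ens, prealigned=True).matrix
        np.testing.assert_allclose(matrix, matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(matrix), 1.0)
        assert matrix.min() >= -1.0 and matrix.max() <= 1.0

    def test_zero_variance_atom_zeroed_with_warning(self):
        ens, _ = synth.gen_trajectory(50, 5, sigma=np.array([0.3, 0.3, 0.0, 0.3, 0.3]),
                                      seed=8)
        with pytest.warns(UserWarning):
            matrix = dccm(ens, prealigned=True).matrix
        assert matrix[2, 2] == 1.0
        np.testing.assert_allclose(np.delete(matrix[2], 2), 0.0)


class TestPca:
    def test_planted_single_mode_dominates(self):
        ens, _ = synth.gen_trajectory(
            500, 12, sigma=0.02,
            blocks=[synth.CorrelatedBlock(atoms=tuple(range(12)), amplitude=1.0)],
            seed=9,
        )
        res = pca_project(ens, prealigned=True)
        assert res.eigenvalues[0] / res.total_variance > 0.9

    def test_orthonormal_eigenvectors_and_trace_identity(self):
        ens, _ = synth.gen_trajectory(60, 10, sigma=0.4, seed=10)
        res = pca_project(ens, prealigned=True)
        gram = res.eigenvectors.T @ res.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance, abs=1e-6)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()  # descending

    def test_projections_centred(self):
        ens, _ = synth.gen_trajectory(60, 10, sigma=0.4, seed=11)
        res = pca_project(ens, prealigned=True)
        np.testing.assert_allclose(res.projections.mean(axis=0), 0.0, atol=1e-10)

    def test_excess_components_rejected(self):
        ens, _ = synth.gen_trajectory(10, 4, sigma=0.1, seed=12)
        with pytest.raises(ValueError):
            pca_project(ens, n_components=13)


class TestEnsemblePlumbing:
    def test_selection_language(self):
        ens, _ = synth.gen_trajectory(5, 20, sigma=0.1, seed=13)
        assert select(ens, "all").sum() == 20
        assert select(ens, "calpha").sum() == 20  # synthetic atoms are all CA
        mask = select(ens, "resid 3 10-12")
        assert sorted(ens.residue_ids[mask]) == [3, 10, 11, 12]
        assert select(ens, "chain A").sum() == 20
        with pytest.raises(ValueError):
            select(ens, "banana 12")

    def test_pdb_round_trip(self, tmp_path):
        ens, _ = synth.gen_trajectory(4, 15, sigma=0.2, seed=14)
        path = tmp_path / "ensemble.pdb"
        ens.to_pdb(path)
        back = TrajectoryEnsemble.from_pdb(path)
        assert back.n_frames == 4 and back.n_atoms == 15
        np.testing.assert_allclose(back.coords, ens.coords, atol=1e-2)  # PDB 3dp
        np.testing.assert_array_equal(back.residue_ids, ens.residue_ids)

    def test_alignment_removes_rigid_drift(self):
        base, _ = synth.gen_trajectory(20, 10, sigma=0.1, seed=15)
        drifted = base.coords + np.arange(20)[:, None, None] * np.array([1.0, 0, 0])
        ens = TrajectoryEnsemble(
            coords=drifted,
            residue_ids=base.residue_ids,
            residue_names=base.residue_names,
            atom_names=base.atom_names,
        )
        aligned = align_ensemble(ens)
        spread = aligned.coords.mean(axis=1)  # per-frame centroid
        assert np.ptp(spread[:, 0]) < 1.0  # x-drift of 19 A collapsed
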