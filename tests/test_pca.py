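"""Essential-dynamics PCA, projections, overlap, elbow K-means."""

import numpy as np
import pytest

from pocketdyn import pca, synthetic
from pocketdyn.core import PocketdynError, Trajectory, select
from pocketdyn.pca import (ConfClusterResult, Projection, elbow_kmeans,
                           fit_pca, flip_pc_sign, interpolate_extremes,
                           pc_overlap, pca_from_matrix, project, reconstruct)


def _traj_from_coords(coords):
    return Trajectory(topology=synthetic.chain_topology(coords.shape[1]),
                      coords=coords, times=np.arange(float(len(coords))))


@pytest.fixture(scope="module")
def mode_system():
    return synthetic.make_harmonic(
        synthetic.HarmonicSpec(n_atoms=30, sigma=0.3, n_frames=2000,
                               mode_amplitude=3.0, rng_seed=7))


@pytest.fixture(scope="module")
def mode_model(mode_system):
    traj = mode_system.trajectory
    sel = select(traj.topology, "all")
    return fit_pca(traj, sel, mass_weighted=True, reference=mode_system.base)


class TestFitPca:
    def test_rank_one_spectrum(self, rng):
        # displacement orthogonal to the rigid-body modes, so the per-frame
        # fit is exactly the identity and the covariance stays rank 1
        base = rng.normal(0, 2, size=(10, 3))
        direction = synthetic._rigid_orthogonalize(
            rng.normal(size=(10, 3)), base)
        coords = base[None] + np.linspace(-2, 2, 50)[:, None, None] * direction
        traj = _traj_from_coords(coords)
        sel = select(traj.topology, "all")
        model = fit_pca(traj, sel, mass_weighted=False, reference=base)
        nonzero = model.eigenvalues > 1e-8 * model.eigenvalues[0]
        assert nonzero.sum() == 1

    def test_trace_identity(self, rng):
        x = rng.normal(size=(500, 24))
        mean, evecs, evals = pca_from_matrix(x)
        y = x - x.mean(0)
        trace = np.trace(y.T @ y / len(x))
        assert abs(evals.sum() - trace) / trace < 1e-10

    def test_mass_weighting_invariance_on_homogeneous_masses(self, rng):
        coords = rng.normal(0, 1, size=(60, 8, 3)) + rng.normal(0, 4, size=(1, 8, 3))
        traj = _traj_from_coords(coords)  # all carbons: equal masses
        sel = select(traj.topology, "all")
        ref = coords[0]
        m1 = fit_pca(traj, sel, mass_weighted=True, reference=ref)
        m2 = fit_pca(traj, sel, mass_weighted=False, reference=ref)
        for j in range(3):
            assert abs(abs(m1.eigenvectors[:, j] @ m2.eigenvectors[:, j]) - 1) < 1e-8

    def test_dual_gram_equals_direct(self, rng):
        """Frame-space (Gram) eigensolve matches the direct covariance path."""
        x = rng.normal(size=(40, 90))
        _, v1, e1 = pca_from_matrix(x)
        import pocketdyn.pca as pmod
        old = pmod.DIRECT_EIG_MAX_DIM
        try:
            pmod.DIRECT_EIG_MAX_DIM = 10  # force the dual route
            _, v2, e2 = pca_from_matrix(x)
        finally:
            pmod.DIRECT_EIG_MAX_DIM = old
        k = min(len(e1), len(e2))
        nz = e1[:k] > 1e-10 * e1[0]
        assert np.abs(e1[:k][nz] - e2[:k][nz]).max() / e1[0] < 1e-8
        dots = np.abs((v1[:, :k][:, nz] * v2[:, :k][:, nz]).sum(0))
        assert np.allclose(dots, 1.0, atol=1e-6)

    def test_zero_variance_input(self, rng):
        coords = np.repeat(rng.normal(0, 2, size=(1, 5, 3)), 4, axis=0)
        traj = _traj_from_coords(coords)
        sel = select(traj.topology, "all")
        model = fit_pca(traj, sel)
        assert np.all(model.eigenvalues < 1e-10)


class TestProjection:
    def test_mean_projects_to_zero(self, mode_model):
        mean_coords = mode_model.mean.reshape(-1, 3)
        proj = project(mode_model, mean_coords, 3, superpose=False)
        assert np.abs(proj.scores).max() < 1e-8

    def test_full_rank_reconstruction(self, mode_system, mode_model):
        traj = mode_system.trajectory
        proj = project(mode_model, traj)
        rec = reconstruct(mode_model, proj.scores)
        # reconstruction returns the superposed frame
        from pocketdyn.superpose import kabsch_fit
        sel = select(traj.topology, "all")
        w = traj.topology.masses[sel.indices]
        for f in (0, 100, 999):
            fitted = kabsch_fit(traj.coords[f], mode_system.base, w).apply(
                traj.coords[f])
            assert np.abs(rec[f] - fitted).max() < 1e-8

    def test_score_covariance_is_diagonal(self, mode_system, mode_model):
        proj = project(mode_model, mode_system.trajectory, 5)
        cov = np.cov(proj.scores.T, bias=True)
        off = np.abs(cov - np.diag(np.diag(cov))).max()
        assert off / np.abs(np.diag(cov)).max() < 1e-6

    def test_planted_mode_recovery(self, mode_system, mode_model):
        v1 = mode_model.eigenvectors[:, 0]
        # eigenvector lives in sqrt(mass)-weighted space; equal masses here
        u = mode_system.mode_vector.ravel()
        assert abs(v1 @ u / np.linalg.norm(u)) > 0.99

    def test_structure_projection_lands_in_ensemble(self, mode_system,
                                                    mode_model):
        """A structure built on the planted mode projects inside the
        sampled PC1 range (the crystal-structure comparison contract)."""
        traj = mode_system.trajectory
        proj = project(mode_model, traj, 3)
        x = mode_system.base + 1.0 * mode_system.mode_vector
        p = project(mode_model, x, 3, source="external structure")
        lo, hi = proj.scores[:, 0].min(), proj.scores[:, 0].max()
        assert lo < p.scores[0, 0] < hi


class TestFlipAndOverlap:
    def test_flip_is_involution_and_targets_one_pc(self):
        proj = Projection(scores=np.array([[1.0, 2.0], [-3.0, 4.0]]))
        once = flip_pc_sign(proj, 1)
        assert np.array_equal(once.scores, [[-1.0, 2.0], [3.0, 4.0]])
        twice = flip_pc_sign(once, 1)
        assert np.array_equal(twice.scores, proj.scores)

    def test_populations_invariant_under_flip(self, rng):
        x = np.concatenate([rng.normal(-10, 1, size=(300, 3)),
                            rng.normal(10, 1, size=(300, 3))])
        r1 = elbow_kmeans(Projection(scores=x), k_max=4, seed=1)
        r2 = elbow_kmeans(flip_pc_sign(Projection(scores=x), 1),
                          k_max=4, seed=1)
        assert sorted(r1.populations) == pytest.approx(sorted(r2.populations))

    def test_self_overlap_is_one(self, mode_model):
        assert pc_overlap(mode_model, mode_model, 1) == pytest.approx(1.0)

    def test_orthogonal_planted_directions(self, rng):
        """Two ensembles varying along orthogonal (rigid-free) directions
        -> PC1 overlap 0."""
        base = rng.normal(0, 2, size=(10, 3))
        d1 = synthetic._rigid_orthogonalize(rng.normal(size=(10, 3)), base)
        d2 = synthetic._rigid_orthogonalize(rng.normal(size=(10, 3)), base)
        v2 = d2.ravel() - (d2.ravel() @ d1.ravel()) * d1.ravel()
        d2 = (v2 / np.linalg.norm(v2)).reshape(10, 3)
        t = np.linspace(-3, 3, 40)[:, None, None]
        m1 = fit_pca(_traj_from_coords(base[None] + t * d1),
                     select(synthetic.chain_topology(10), "all"),
                     mass_weighted=False, reference=base)
        m2 = fit_pca(_traj_from_coords(base[None] + t * d2),
                     select(synthetic.chain_topology(10), "all"),
                     mass_weighted=False, reference=base)
        assert abs(pc_overlap(m1, m2, 1)) < 1e-10

    def test_shared_mode_overlap(self, mode_system, mode_model):
        """Two ensembles sharing the planted collective mode keep PC1
        overlap >= 0.99 (the apo-vs-complex conservation structure)."""
        other = synthetic.make_harmonic(
            synthetic.HarmonicSpec(n_atoms=30, sigma=0.3, n_frames=2000,
                                   mode_amplitude=3.0, rng_seed=13,
                                   mode_vector=mode_system.mode_vector))
        sel = select(other.trajectory.topology, "all")
        m2 = fit_pca(other.trajectory, sel, mass_weighted=True,
                     reference=other.base)
        assert abs(pc_overlap(mode_model, m2, 1)) >= 0.99


class TestInterpolateExtremes:
    def test_endpoints_and_linearity(self, mode_system, mode_model):
        proj = project(mode_model, mode_system.trajectory, 3)
        tr = interpolate_extremes(mode_model, proj, 1, n=100)
        assert tr.n_frames == 100
        j = proj.scores[:, 0]
        lo = reconstruct(mode_model, np.array([[j.min(), 0, 0]]))[0]
        hi = reconstruct(mode_model, np.array([[j.max(), 0, 0]]))[0]
        assert np.abs(tr.coords[0] - lo).max() < 1e-8
        assert np.abs(tr.coords[-1] - hi).max() < 1e-8
        steps = np.sqrt(((np.diff(tr.coords, axis=0)) ** 2).sum(2).mean(1))
        assert steps.max() - steps.min() < 1e-6

    def test_symmetric_range_midpoint_is_mean(self, mode_model):
        proj = Projection(scores=np.array([[-2.0, 0, 0], [2.0, 0, 0]]))
        tr = interpolate_extremes(mode_model, proj, 1, n=101)
        mean_coords = mode_model.mean.reshape(-1, 3)
        assert np.abs(tr.coords[50] - mean_coords).max() < 1e-8

    def test_degenerate_pc_errors(self, mode_model):
        proj = Projection(scores=np.zeros((10, mode_model.n_components)))
        with pytest.raises(PocketdynError, match="degenerate"):
            interpolate_extremes(mode_model, proj, mode_model.n_components,
                                 n=10)


class TestElbowKmeans:
    def test_four_planted_gaussians(self, rng):
        centers = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0], [0, 0, 20]],
                           dtype=float)
        x = np.concatenate([rng.normal(c, 1.0, size=(500, 3))
                            for c in centers])
        res = elbow_kmeans(Projection(scores=x), threshold=0.025, k_max=8,
                           seed=7)
        assert res.k == 4
        assert np.allclose(np.sort(res.populations), 0.25, atol=0.02)
        assert res.populations.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ssr_sst_non_increasing_and_determinism(self, rng):
        x = rng.normal(size=(400, 3))
        r1 = elbow_kmeans(Projection(scores=x), k_max=6, seed=3)
        r2 = elbow_kmeans(Projection(scores=x), k_max=6, seed=3)
        curve = [r1.ssr_sst[k] for k in sorted(r1.ssr_sst)]
        assert all(a >= b - 1e-12 for a, b in zip(curve, curve[1:]))
        assert np.array_equal(r1.labels, r2.labels)

    def test_planted_recovery_agreement(self, rng):
        """>= 10x separation -> adjusted agreement >= 0.95 with truth."""
        from sklearn.metrics import adjusted_rand_score
        truth = np.repeat(np.arange(3), 400)
        centers = np.array([[0, 0, 0], [30, 0, 0], [0, 30, 0]], dtype=float)
        x = np.concatenate([rng.normal(c, 1.0, size=(400, 3))
                            for c in centers])
        res = elbow_kmeans(Projection(scores=x), k_max=6, seed=5)
        assert adjusted_rand_score(truth, res.labels) >= 0.95

    def test_central_frames_belong_to_cluster(self, rng):
        x = np.concatenate([rng.normal(-8, 1, size=(100, 3)),
                            rng.normal(8, 1, size=(100, 3))])
        res = elbow_kmeans(Projection(scores=x), k_max=4, seed=2)
        for c, f in enumerate(res.central_frames):
            assert res.labels[f] == c

    def test_k_max_too_small_errors(self, rng):
        with pytest.raises(PocketdynError):
            elbow_kmeans(Projection(scores=rng.normal(size=(50, 3))),
                         k_max=1)
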