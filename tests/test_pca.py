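import numpy as np
import pytest

from elevator import errors, pca
from elevator.structures import CalphaModel, identity_correspondence
from elevator.synth import ToyElevatorSpec, make_toy_elevator


def _rotate_z(coords, deg):
    t = np.deg2rad(deg)
    R = np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])
    return coords @ R.T


class TestKabsch:
    def test_identity(self, toy_elevator):
        a, _, _ = toy_elevator
        _, r_mask, r_all = pca.kabsch_superpose(a, a)
        assert r_mask == pytest.approx(0.0, abs=1e-12)
        assert r_all == pytest.approx(0.0, abs=1e-12)

    def test_removes_rigid_motion(self, toy_elevator):
        a, _, _ = toy_elevator
        moved = a.with_coords(_rotate_z(a.coords, 90.0) + np.array([5.0, 0.0, 0.0]))
        _, r_mask, r_all = pca.kabsch_superpose(moved, a)
        assert r_all == pytest.approx(0.0, abs=1e-8)

    def test_masked_fit_leaves_core_displacement(self, toy_elevator):
        # closed form: scaffold-masked fit of a rigid core shift d leaves
        # overall rmsd d * sqrt(M_core / M)
        a, b, dom = toy_elevator
        mask = dom.mask(a, "dimer_domain")
        _, r_mask, r_all = pca.kabsch_superpose(b, a, mask)
        m_core = (~mask).sum()
        expected = 5.0 * np.sqrt(m_core / len(a))
        assert r_mask == pytest.approx(0.0, abs=1e-9)
        assert r_all == pytest.approx(expected, rel=1e-9)

    def test_rotation_is_proper(self, toy_elevator):
        a, _, _ = toy_elevator
        # a reflected copy must still come back via a proper rotation
        reflected = a.with_coords(a.coords * np.array([-1.0, 1.0, 1.0]))
        R, _, _ = pca.kabsch_rotation(reflected.coords, a.coords)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_optimality_against_random_rotations(self, toy_elevator):
        a, b, _ = toy_elevator
        _, _, r_opt = pca.kabsch_superpose(b, a)
        rng = np.random.default_rng(7)
        for _ in range(10):
            q = rng.normal(size=(3, 3))
            Q, _ = np.linalg.qr(q)
            if np.linalg.det(Q) < 0:
                Q[:, 0] = -Q[:, 0]
            trial = (b.coords - b.coords.mean(0)) @ Q.T + a.coords.mean(0)
            r_trial = float(np.sqrt(np.mean(np.sum((trial - a.coords) ** 2, axis=1))))
            assert r_opt <= r_trial + 1e-9

    def test_collinear_mask_degenerate(self):
        line = CalphaModel(
            residues=[("A", i + 1, "", "ALA") for i in range(5)],
            coords=np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)]),
        )
        with pytest.raises(errors.DegenerateGeometryError):
            pca.kabsch_superpose(line, line.with_coords(line.coords + 1.0))


class TestBuildEnsemble:
    def test_identical_structures_zero_spread(self, toy_elevator):
        a, _, dom = toy_elevator
        models = {"x": a, "y": a.with_coords(a.coords.copy())}
        table = identity_correspondence(["x", "y"], a)
        ens = pca.build_ensemble(models, table, "x", dom.mask(a, "dimer_domain"))
        assert ens.mean_all_rmsd == pytest.approx(0.0, abs=1e-9)
        assert ens.all_rmsd_sd == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_noise_rmsd_expectation(self, toy_elevator):
        # members = reference + N(0, sigma) per coordinate; the rms of the
        # per-atom displacement is sigma * sqrt(3)
        a, _, dom = toy_elevator
        rng = np.random.default_rng(11)
        sigma = 1.0
        models = {"ref": a}
        for k in range(8):
            models[f"m{k}"] = a.with_coords(
                a.coords + rng.normal(0.0, sigma, a.coords.shape)
            )
        table = identity_correspondence(list(models), a)
        ens = pca.build_ensemble(models, table, "ref", dom.mask(a, "dimer_domain"))
        noisy = [r for sid, r in zip(ens.structure_ids, ens.all_rmsds) if sid != "ref"]
        assert np.mean(noisy) == pytest.approx(np.sqrt(3.0) * sigma, abs=0.12)

    def test_missing_structure_named(self, toy_elevator):
        a, _, dom = toy_elevator
        table = identity_correspondence(["x", "y"], a)
        with pytest.raises(errors.ConsistencyError, match="y"):
            pca.build_ensemble({"x": a}, table, "x", dom.mask(a, "dimer_domain"))


class TestCovariancePCA:
    def test_two_member_ensemble_single_axis(self, toy_elevator):
        a, b, dom = toy_elevator
        models = {"in": a, "out": b}
        table = identity_correspondence(["in", "out"], a)
        ens = pca.build_ensemble(models, table, "in", dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        fr = basis.variance_fractions
        assert fr[0] == pytest.approx(1.0, abs=1e-9)
        assert np.sum(basis.eigenvalues > 1e-9 * basis.eigenvalues[0]) == 1
        diff = (ens.coords[1] - ens.coords[0]).ravel()
        overlap = abs(basis.eigenvectors[0] @ diff) / np.linalg.norm(diff)
        assert overlap == pytest.approx(1.0, abs=1e-9)

    def test_eigenpairs_match_explicit_covariance(self):
        # independent oracle: dense eigendecomposition of C = Xc^T Xc / N
        rng = np.random.default_rng(3)
        N, M = 5, 10
        coords = rng.normal(size=(N, M, 3))
        ens = pca.SuperposedEnsemble(
            structure_ids=[f"s{i}" for i in range(N)],
            coords=coords,
            fit_mask=np.ones(M, dtype=bool),
            reference_id="s0",
        )
        basis = pca.covariance_pca(ens)
        X = coords.reshape(N, -1)
        C = (X - X.mean(0)).T @ (X - X.mean(0)) / N
        w = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(basis.eigenvalues, w[: basis.n_components], atol=1e-10)
        assert np.sum(basis.eigenvalues) == pytest.approx(np.trace(C), rel=1e-8)

    def test_orthonormal_rows(self, toy_elevator):
        a, b, dom = toy_elevator
        rng = np.random.default_rng(5)
        models = {f"m{k}": a.with_coords(a.coords + rng.normal(0, 0.5, a.coords.shape))
                  for k in range(6)}
        table = identity_correspondence(list(models), a)
        ens = pca.build_ensemble(models, table, "m0", dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        G = basis.eigenvectors @ basis.eigenvectors.T
        np.testing.assert_allclose(G, np.eye(basis.n_components), atol=1e-8)

    def test_single_structure_insufficient(self, toy_elevator):
        a, _, dom = toy_elevator
        ens = pca.SuperposedEnsemble(
            structure_ids=["only"],
            coords=a.coords[None],
            fit_mask=dom.mask(a, "dimer_domain"),
            reference_id="only",
        )
        with pytest.raises(errors.InsufficientDataError):
            pca.covariance_pca(ens)


class TestProjection:
    def _two_state_basis(self):
        a, b, dom = make_toy_elevator(ToyElevatorSpec(shift=5.0))
        models = {"in": a, "out": b}
        table = identity_correspondence(["in", "out"], a)
        ens = pca.build_ensemble(models, table, "in", dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        basis = pca.calibrate_signs(basis, ens.coords_of("out"), ens.coords_of("in"))
        return ens, basis

    def test_reference_projects_to_zero(self):
        ens, basis = self._two_state_basis()
        p = pca.project(ens.coords_of("in"), basis, ens.coords_of("in"))
        assert all(abs(v) < 1e-9 for v in p.values())

    def test_two_member_projection_is_distance(self):
        ens, basis = self._two_state_basis()
        p = pca.project(ens.coords_of("out"), basis, ens.coords_of("in"), [1])
        expected = np.linalg.norm(ens.coords_of("out") - ens.coords_of("in"))
        assert p[1] == pytest.approx(expected, rel=1e-9)
        assert p[1] > 0  # calibration pins the outward state positive

    def test_formula_equals_componentwise_dot(self):
        # brute-force oracle on random vectors and an orthonormal basis
        rng = np.random.default_rng(13)
        M = 8
        raw = rng.normal(size=(3 * M, 3))
        Q, _ = np.linalg.qr(raw)
        basis = pca.PCABasis(
            mean=np.zeros(3 * M),
            eigenvectors=Q.T,
            eigenvalues=np.array([3.0, 2.0, 1.0]),
            total_variance=6.0,
        )
        ref = rng.normal(size=(M, 3))
        x = rng.normal(size=(M, 3))
        p = pca.project(x, basis, ref)
        T = (x - ref).ravel()
        for k in range(1, 4):
            brute = sum(Q.T[k - 1][i] * T[i] for i in range(3 * M))
            assert p[k] == pytest.approx(brute, rel=1e-10)

    def test_completeness_reconstruction(self, toy_elevator):
        a, b, dom = toy_elevator
        rng = np.random.default_rng(17)
        models = {f"m{k}": a.with_coords(a.coords + rng.normal(0, 0.5, a.coords.shape))
                  for k in range(5)}
        table = identity_correspondence(list(models), a)
        ens = pca.build_ensemble(models, table, "m0", dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        mean = basis.mean.reshape(-1, 3)
        for i in range(ens.n_structures):
            p = pca.project(ens.coords[i], basis, mean)
            recon = basis.mean + sum(p[k] * basis.eigenvectors[k - 1]
                                     for k in p)
            np.testing.assert_allclose(recon.reshape(-1, 3), ens.coords[i], atol=1e-6)

    def test_frame_mismatch_detected(self):
        ens, basis = self._two_state_basis()
        far = ens.coords_of("in") + 100.0
        with pytest.raises(errors.FrameMismatchError):
            pca.project(far, basis, ens.coords_of("in"), frame_tolerance=5.0)


class TestInterpolation:
    def test_zero_amplitude_is_mean(self):
        a, b, dom = make_toy_elevator(ToyElevatorSpec(shift=5.0))
        models = {"in": a, "out": b}
        table = identity_correspondence(["in", "out"], a)
        ens = pca.build_ensemble(models, table, "in", dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        frame = pca.pc_interpolate(basis, a, 1, [0.0])[0]
        np.testing.assert_allclose(frame.coords.ravel(), basis.mean, atol=1e-12)

    def test_symmetric_amplitudes_span(self):
        a, b, dom = make_toy_elevator(ToyElevatorSpec(shift=5.0))
        models = {"in": a, "out": b}
        table = identity_correspondence(["in", "out"], a)
        ens = pca.build_ensemble(models, table, "in", dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        lo, hi = pca.pc_interpolate(basis, a, 1, [-2.0, 2.0])
        assert np.linalg.norm(hi.coords - lo.coords) == pytest.approx(4.0, rel=1e-9)

    def test_projection_roundtrip(self):
        a, b, dom = make_toy_elevator(ToyElevatorSpec(shift=5.0))
        models = {"in": a, "out": b}
        table = identity_correspondence(["in", "out"], a)
        ens = pca.build_ensemble(models, table, "in", dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        for amp in (-3.0, 0.5, 7.0):
            frame = pca.pc_interpolate(basis, a, 1, [amp])[0]
            p = pca.project(frame.coords, basis, basis.mean.reshape(-1, 3), [1])
            assert p[1] == pytest.approx(amp, abs=1e-9)


class TestRecovery:
    def test_two_state_ensemble_recovers_axis(self):
        # a two-state elevator with small noise must put nearly all the
        # variance on PC1, and PC1 must point along the true displacement
        from elevator.synth import make_ensemble

        a, b, dom = make_toy_elevator(ToyElevatorSpec(shift=5.0))
        models, table = make_ensemble([a, b], n_per_state=4, noise_sigma=0.2, seed=1)
        ref = next(iter(models))
        ens = pca.build_ensemble(models, table, ref, dom.mask(a, "dimer_domain"))
        basis = pca.covariance_pca(ens)
        assert basis.variance_fractions[0] > 0.9
        true_axis = (b.coords - a.coords).ravel()
        overlap = abs(basis.eigenvectors[0] @ true_axis) / np.linalg.norm(true_axis)
        assert overlap > 0.99
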