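"""Trajectory statistics: fitting, covariance, PCA/FCA, VACF spectra."""

import numpy as np
import pytest

from coevodyn import (
    FullCorrelationAnalysis,
    ModeSpec,
    TrajGenSpec,
    Trajectory,
    TrajectoryPCA,
    anharmonicity,
    cosine_content,
    covariance,
    cross_correlation,
    fca,
    filter_along,
    fit_and_center,
    gen_trajectory,
    pca_modes,
    project,
    residue_weights,
    spectrum_peaks,
    vacf,
    vacf_spectrum,
)
from coevodyn.modes import pairwise_mi, total_pairwise_mi
from coevodyn.trajectory import C_CM_PER_PS, CM1_PER_THZ


def _rigid_rotation_traj(n_frames=20, n_res=6, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_res, 3))
    frames = []
    for t in range(n_frames):
        th = 0.1 * t
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        frames.append(base @ R.T + t * np.array([0.5, -0.2, 0.1]))
    return Trajectory(np.array(frames), 0.01, np.arange(1, n_res + 1))


class TestFitAndCenter:
    def test_rigid_motion_removed(self):
        traj = _rigid_rotation_traj()
        fitted = fit_and_center(traj)
        assert fitted.positions.var(axis=0).max() < 1e-10

    def test_known_rotation_recovered(self):
        """90-degree z-rotation + translation of a 4-point toy."""
        base = np.array(
            [[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]]
        )
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        moved = base @ Rz.T + np.array([3.0, -1.0, 2.0])
        traj = Trajectory(np.stack([base, moved]), 0.01, np.arange(1, 5))
        fitted = fit_and_center(traj, reference_frame=0)
        centered = base - base.mean(axis=0)
        assert np.allclose(fitted.positions[1], centered, atol=1e-12)

    def test_idempotent(self):
        traj, _ = gen_trajectory(
            TrajGenSpec(n_res=8, n_frames=50, modes=[], noise_sd=0.05, seed=1)
        )
        once = fit_and_center(traj)
        twice = fit_and_center(once)
        assert np.allclose(once.positions, twice.positions, atol=1e-12)

    def test_collinear_structure_errors(self):
        pos = np.zeros((3, 4, 3))
        pos[:, :, 0] = np.arange(4)  # all points on the x-axis
        with pytest.raises(ValueError, match="collinear"):
            fit_and_center(Trajectory(pos, 0.01, np.arange(1, 5)))


class TestCovariance:
    def test_constant_trajectory_zero(self):
        pos = np.ones((5, 3, 3))
        C = covariance(Trajectory(pos, 0.01, np.arange(1, 4)))
        assert np.allclose(C, 0.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(size=(40, 2, 3))
        traj = Trajectory(pos, 0.01, np.arange(1, 3))
        C = covariance(traj)
        X = pos.reshape(40, 6)
        for i in range(6):
            for j in range(6):
                oracle = np.mean(
                    (X[:, i] - X[:, i].mean()) * (X[:, j] - X[:, j].mean())
                )
                assert C[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_psd(self, planted_traj):
        traj, _ = planted_traj
        C = covariance(fit_and_center(traj))
        assert np.array_equal(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestPCA:
    def test_diagonal_covariance_gives_axes(self):
        C = np.diag([1.0, 5.0, 3.0])
        vals, vecs = pca_modes(C)
        assert np.allclose(vals, [5.0, 3.0, 1.0])
        assert np.allclose(np.abs(vecs), np.eye(3)[:, [1, 2, 0]])

    def test_eigenvalue_sum_equals_trace(self, planted_traj):
        traj, _ = planted_traj
        C = covariance(fit_and_center(traj))
        vals, _ = pca_modes(C)
        assert vals.sum() == pytest.approx(np.trace(C), abs=1e-8)

    def test_planted_subspace_recovered(self):
        """3 planted Gaussian modes (variances 9, 4, 1) over weak noise."""
        rng = np.random.default_rng(3)
        n, d = 5000, 30
        U = np.linalg.qr(rng.normal(size=(d, 3)))[0]
        A = rng.normal(size=(n, 3)) * np.sqrt([9.0, 4.0, 1.0])
        X = A @ U.T + rng.normal(scale=0.1, size=(n, d))
        p = TrajectoryPCA(n_modes=3).fit(X)
        overlap = np.linalg.svd(p.components_ @ U)[1]
        assert overlap.min() >= 0.95

    def test_projection_variance_equals_eigenvalue(self, planted_traj):
        traj, _ = planted_traj
        fitted = fit_and_center(traj)
        C = covariance(fitted)
        vals, vecs = pca_modes(C)
        P = project(fitted, vecs, 5)
        assert np.allclose(P.var(axis=0), vals[:5], atol=1e-8)

    def test_filter_along_reconstructs_single_mode(self):
        spec = TrajGenSpec(
            n_res=10, n_frames=600, dt=0.01,
            modes=[ModeSpec(support=[2, 3, 4], amplitude=0.5, kind="gaussian")],
            noise_sd=0.02, seed=4,
        )
        traj, truth = gen_trajectory(spec)
        fitted = fit_and_center(traj)
        C = covariance(fitted)
        _, vecs = pca_modes(C)
        filt = filter_along(fitted, vecs[:, 0])
        rmsd = np.sqrt(((filt.positions - fitted.positions) ** 2).mean())
        assert rmsd < 2 * 0.02  # residual is noise-sized

    def test_projection_idempotent_on_reconstruction(self, planted_traj):
        traj, _ = planted_traj
        fitted = fit_and_center(traj)
        _, vecs = pca_modes(covariance(fitted))
        filt = filter_along(fitted, vecs[:, 0])
        p1 = project(fitted, vecs, 1)[:, 0]
        p2 = project(filt, vecs, 1)[:, 0]
        assert np.allclose(p1, p2, atol=1e-8)

    def test_asymmetric_input_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            pca_modes(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestCosineContent:
    def test_pure_cosine_is_one(self):
        t = np.arange(2000)
        p = np.cos(np.pi * t / 2000)
        assert cosine_content(p, 1) == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_is_small(self):
        rng = np.random.default_rng(5)
        assert cosine_content(rng.normal(size=5000), 1) < 0.05

    def test_oscillatory_mode_converged_under_reporting_criterion(self):
        """A fast oscillation is far below the 0.005 convergence bound."""
        t = np.arange(5000)
        p = np.cos(2 * np.pi * 40 * t / 5000)
        assert cosine_content(p, 1) < 0.005

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            cosine_content(np.zeros(10), 1)


class TestAnharmonicity:
    def test_gaussian_negentropy_near_zero(self):
        x = np.random.default_rng(6).normal(size=100_000)
        assert anharmonicity(x) == pytest.approx(0.0, abs=0.02)

    def test_uniform_negentropy_closed_form(self):
        x = np.random.default_rng(7).uniform(size=100_000)
        expected = 0.5 * np.log(2 * np.pi * np.e / 12)  # ~0.1765 nats
        assert anharmonicity(x) == pytest.approx(expected, abs=0.02)

    def test_double_well_exceeds_gaussian(self):
        rng = np.random.default_rng(8)
        dw = np.concatenate([rng.normal(-1, 0.2, 5000), rng.normal(1, 0.2, 5000)])
        g = rng.normal(0, dw.std(), 10_000)
        assert anharmonicity(dw) > anharmonicity(g)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError):
            anharmonicity(np.ones(1000))


class TestFCA:
    def test_demixes_rotated_uniform_sources(self):
        rng = np.random.default_rng(9)
        S = rng.uniform(-1, 1, size=(4000, 2))
        th = np.pi / 4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Y = S @ R.T
        f = FullCorrelationAnalysis().fit(Y)
        ang = np.degrees(np.arctan2(f.rotation_[1, 0], f.rotation_[0, 0])) % 90
        err = min(abs(ang - 45.0), abs(ang - 45.0 + 90), abs(ang - 45.0 - 90))
        assert err < 3.0
        mi_before = total_pairwise_mi(Y - Y.mean(0))
        mi_after = total_pairwise_mi(f.transform(Y))
        assert mi_after <= 0.2 * mi_before

    def test_independent_gaussians_near_signed_permutation(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(3000, 3)) * np.array([3.0, 2.0, 1.0])
        f = FullCorrelationAnalysis(tol=1e-3).fit(Y)
        # rotation composed with its anharmonicity reordering must be close
        # to a signed permutation: each column has one dominant entry
        assert np.allclose(
            np.abs(f.rotation_).max(axis=0), 1.0, atol=1e-2
        )

    def test_double_well_outranks_larger_gaussian(self):
        rng = np.random.default_rng(11)
        n = 4000
        dw = np.concatenate(
            [rng.normal(-0.5, 0.1, n // 2), rng.normal(0.5, 0.1, n // 2)]
        )
        rng.shuffle(dw)
        g = rng.normal(0, 2.0, n)  # much larger amplitude
        f = FullCorrelationAnalysis().fit(np.column_stack([g, dw]))
        # most anharmonic output mode is the double-well, despite variance
        z = f.transform(np.column_stack([g, dw]))
        assert abs(np.corrcoef(z[:, 0], dw)[0, 1]) > 0.9
        assert f.anharmonicity_[0] > f.anharmonicity_[1]

    def test_mi_descent_monotone(self, planted_traj):
        traj, _ = planted_traj
        ms = fca(fit_and_center(traj), n_modes=5)
        assert np.all(np.diff(ms.extras["mi_history"]) <= 1e-12)
        assert ms.kind == "FCA"

    def test_modeset_orthonormal(self, planted_traj):
        traj, _ = planted_traj
        ms = fca(fit_and_center(traj), n_modes=5)
        G = ms.vectors.T @ ms.vectors
        assert np.allclose(G, np.eye(5), atol=1e-8)


class TestResidueWeights:
    def test_localized_mode(self):
        v = np.zeros(12)
        v[3:6] = [0.6, 0.8, 0.0]  # all on residue 2
        w = residue_weights(v, [1, 2, 3, 4])
        assert w[2] == pytest.approx(1.0)
        assert w[1] == w[3] == w[4] == 0.0

    def test_uniform_mode(self):
        v = np.full(30, 1 / np.sqrt(30))
        w = residue_weights(v, range(1, 11))
        assert all(np.isclose(x, 0.1) for x in w.values())

    def test_planted_support_recovered(self, planted_traj):
        traj, truth = planted_traj
        ms = fca(fit_and_center(traj), n_modes=5)
        w = residue_weights(ms.vectors[:, 0], traj.residue_ids)
        top2 = sorted(sorted(w, key=w.get, reverse=True)[:2])
        planted = [r + 1 for r in truth["modes"][0]["support"]]
        assert top2 == planted


class TestCrossCorrelation:
    def test_self_correlation_one(self, planted_traj):
        traj, _ = planted_traj
        c = cross_correlation(covariance(fit_and_center(traj)))
        assert np.allclose(np.diag(c), 1.0)

    def test_identical_and_opposite_motion(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(200, 3))
        pos = np.stack([a, a, -a], axis=1)
        c = cross_correlation(covariance(Trajectory(pos, 0.01, [1, 2, 3])))
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)

    def test_planted_block_structure(self):
        """Two coherently moving residue blocks in a larger protein."""
        spec = TrajGenSpec(
            n_res=60, n_frames=2000, dt=0.01,
            modes=[
                ModeSpec(support=[0, 1, 2], amplitude=0.4, kind="gaussian",
                         coherent=True),
                ModeSpec(support=[30, 31, 32], amplitude=0.4, kind="gaussian",
                         coherent=True),
            ],
            noise_sd=0.02, seed=13,
        )
        traj, _ = gen_trajectory(spec)
        c = np.abs(cross_correlation(covariance(fit_and_center(traj))))
        within = [c[0, 1], c[1, 2], c[30, 31], c[31, 32]]
        across = [c[0, 30], c[1, 31], c[2, 32]]
        assert min(within) > 0.8
        assert max(across) < 0.2


class TestVACF:
    def test_constant_velocity_vacf_is_one(self):
        pos = np.cumsum(np.ones((50, 2, 3)), axis=0)
        traj = Trajectory(pos, 0.01, [1, 2], velocities=np.ones((50, 2, 3)))
        _, acf = vacf(traj)
        assert np.allclose(acf, 1.0)

    def test_harmonic_oscillator_matches_cosine(self):
        """Period 0.333 ps -> VACF = cos(2 pi t / T), peak at ~100 cm^-1."""
        period = 1.0 / (100.0 * C_CM_PER_PS)  # ~0.3336 ps
        spec = TrajGenSpec(
            n_res=5, n_frames=4000, dt=0.08,
            modes=[ModeSpec(support=[0, 1, 2, 3, 4], amplitude=0.3,
                            kind="harmonic", wavenumber=100.0)],
            noise_sd=0.0, seed=14,
        )
        traj, _ = gen_trajectory(spec)
        lags, acf = vacf(traj, max_lag=500)
        expected = np.cos(2 * np.pi * lags / period)
        assert np.abs(acf - expected).max() < 1e-3
        wn, inten = vacf_spectrum(acf, traj.dt)
        peak = spectrum_peaks(wn, inten, 1)[0]
        grid_bin = CM1_PER_THZ / (len(acf) * traj.dt)  # VACF grid resolution
        assert abs(peak - 100.0) <= grid_bin

    def test_two_tone_superposition_resolved(self):
        spec = TrajGenSpec(
            n_res=6, n_frames=4000, dt=0.08,
            modes=[
                ModeSpec(support=[0, 1, 2], amplitude=0.3, kind="harmonic",
                         wavenumber=100.0),
                ModeSpec(support=[3, 4, 5], amplitude=0.3, kind="harmonic",
                         wavenumber=150.0, phase=0.7),
            ],
            noise_sd=0.0, seed=15,
        )
        traj, _ = gen_trajectory(spec)
        lags, acf = vacf(traj, max_lag=500)
        wn, inten = vacf_spectrum(acf, traj.dt)
        peaks = sorted(spectrum_peaks(wn, inten, 2))
        grid_bin = CM1_PER_THZ / (len(acf) * traj.dt)
        assert abs(peaks[0] - 100.0) <= grid_bin
        assert abs(peaks[1] - 150.0) <= grid_bin

    def test_noise_spectrum_flat(self):
        rng = np.random.default_rng(16)
        pos = rng.normal(size=(4000, 3, 3))
        traj = Trajectory(pos, 0.01, [1, 2, 3],
                          velocities=rng.normal(size=(4000, 3, 3)))
        _, acf = vacf(traj, max_lag=500)
        wn, inten = vacf_spectrum(acf, traj.dt)
        med = np.median(inten)
        mad = np.median(np.abs(inten - med))
        # flat: the bulk sits within 3 MAD and no bin rises far beyond the
        # noise floor (the extreme of ~1000 magnitude bins is noise-sized)
        assert (np.abs(inten - med) <= 3 * mad).mean() > 0.95
        assert inten.max() <= med + 8 * mad

    def test_nyquist_violation_errors(self):
        spec = TrajGenSpec(
            n_res=3, n_frames=100, dt=0.2,
            modes=[ModeSpec(support=[0], amplitude=0.1, kind="harmonic",
                            wavenumber=100.0)],
            seed=17,
        )
        with pytest.raises(ValueError, match="Nyquist"):
            gen_trajectory(spec)
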