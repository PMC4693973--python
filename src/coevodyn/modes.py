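"""Collective-mode analysis: PCA of the positional covariance, full
correlation analysis (FCA), cosine content and anharmonicity scoring.

PCA diagonalizes the covariance of the fitted trajectory; eigenvalues are the
mean-square fluctuations along each mode, sorted descending. FCA searches the
orthogonal transforms of the top PCA coordinates for the one minimizing the
summed pairwise mutual information of the collective coordinates, then orders
the resulting modes by anharmonicity (negentropy) rather than amplitude —
double-well, two-state modes outrank larger harmonic ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .trajectory import Trajectory


@dataclass
class ModeSet:
    """Orthonormal collective modes with per-mode diagnostics.

    vectors: (3N, k) columns; eigenvalues only for PCA (nm^2); projections
    (n_frames, k); anharmonicity in nats; cosine content in [0, 1].
    """

    kind: str
    vectors: np.ndarray
    projections: np.ndarray
    eigenvalues: np.ndarray | None = None
    anharmonicity: np.ndarray | None = None
    cosine_content: np.ndarray | None = None
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        V = self.vectors
        G = V.T @ V
        if not np.allclose(G, np.eye(G.shape[0]), atol=1e-8):
            raise ValueError("mode vectors must be orthonormal")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude component of each column positive."""
    V = vectors.copy()
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return V


def pca_modes(C: np.ndarray, n_modes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of a covariance matrix, eigenvalues descending.

    Returns (eigenvalues, vectors) with vectors as columns; equal eigenvalues
    keep a stable order by original index; sign fixed deterministically.
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (C + C.T))
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    if n_modes is not None:
        vals, vecs = vals[:n_modes], vecs[:, :n_modes]
    return vals, _fix_signs(vecs)


def project(traj: Trajectory, vectors: np.ndarray, k: int | None = None) -> np.ndarray:
    """Projections of the centered trajectory onto the first k mode vectors."""
    if k is None:
        k = vectors.shape[1]
    if k > vectors.shape[1]:
        raise ValueError("k exceeds the number of modes")
    X = traj.flat()
    return (X - X.mean(axis=0)) @ vectors[:, :k]


def filter_along(traj: Trajectory, vector: np.ndarray) -> Trajectory:
    """Trajectory reconstructed from the mean plus one mode's motion only."""
    X = traj.flat()
    mean = X.mean(axis=0)
    p = (X - mean) @ vector
    filt = mean + np.outer(p, vector)
    return Trajectory(
        filt.reshape(traj.positions.shape), traj.dt, traj.residue_ids
    )


def cosine_content(projection: np.ndarray, mode_index: int = 1) -> float:
    """Cosine content of a principal-component time series.

    c_i = 2 (sum_t cos(i*pi*t/T) p_t)^2 / (T sum_t p_t^2) on the discrete
    grid; near 1 for random-diffusion-like (unconverged) sampling, near 0 for
    oscillatory/converged modes.
    """
    p = np.asarray(projection, dtype=float)
    n = p.size
    if n < 4:
        raise ValueError("series too short")
    denom = np.sum(p * p)
    if denom == 0:
        raise ValueError("zero-variance series")
    t = np.arange(n)
    cosine = np.cos(mode_index * np.pi * t / n)
    return float(2.0 * np.sum(cosine * p) ** 2 / (n * denom))


def anharmonicity(projection: np.ndarray, bins: str | int = "fd") -> float:
    """Negentropy (nats) of a mode's amplitude distribution.

    J = H_gauss(sigma) - H_hist, where H_gauss = 0.5 ln(2*pi*e*sigma^2) and
    H_hist is the histogram differential entropy (Freedman–Diaconis bins by
    default). J ~ 0 for harmonic (Gaussian) modes and grows with bimodality
    or other non-Gaussian structure.
    """
    p = np.asarray(projection, dtype=float)
    if p.size < 100:
        raise ValueError("series too short for a stable entropy estimate")
    sd = p.std()
    if sd == 0:
        raise ValueError("constant series")
    counts, edges = np.histogram(p, bins=bins)
    widths = np.diff(edges)
    probs = counts / counts.sum()
    nz = probs > 0
    h_hist = float(-(probs[nz] * np.log(probs[nz] / widths[nz])).sum())
    h_gauss = 0.5 * np.log(2 * np.pi * np.e * sd * sd)
    return float(h_gauss - h_hist)


def residue_weights(vector: np.ndarray, residue_ids) -> dict[int, float]:
    """Per-residue weighted square displacement of a normalized mode.

    w(res) = sum of the squared x/y/z components of that residue; the weights
    of a unit mode sum to 1.
    """
    v = np.asarray(vector, dtype=float).reshape(-1, 3)
    if len(v) != len(residue_ids):
        raise ValueError("vector length must be 3 * n_residues")
    w = (v * v).sum(axis=1)
    return {int(r): float(x) for r, x in zip(residue_ids, w)}


# ---------------------------------------------------------------------------
# histogram MI estimator used by FCA


def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin index of each sample (0..n_bins-1)."""
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (ranks * n_bins) // x.size


def pairwise_mi(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """Histogram MI (nats) between two series with equal-count marginal bins."""
    n = x.size
    if n_bins is None:
        n_bins = max(2, int(np.ceil(n ** (1 / 3))))
    bx = _quantile_bin(x, n_bins)
    by = _quantile_bin(y, n_bins)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))


def total_pairwise_mi(Y: np.ndarray, n_bins: int | None = None) -> float:
    """Sum of pairwise MI over all coordinate pairs of (n_samples, m) data."""
    m = Y.shape[1]
    return sum(
        pairwise_mi(Y[:, i], Y[:, j], n_bins)
        for i in range(m)
        for j in range(i + 1, m)
    )


class TrajectoryPCA(BaseEstimator, TransformerMixin):
    """PCA of Cα fluctuations (sklearn-style transformer).

    Fits on a (n_frames, 3N) coordinate array (use ``Trajectory.flat()`` of a
    fitted trajectory). Fitted attributes follow sklearn conventions:
    ``components_`` (k, 3N) rows, ``eigenvalues_`` descending, ``mean_``.
    """

    def __init__(self, n_modes: int | None = None):
        self.n_modes = n_modes

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be (n_frames, 3N) with >= 2 frames")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        C = Xc.T @ Xc / X.shape[0]
        vals, vecs = pca_modes(C, self.n_modes)
        self.eigenvalues_ = vals
        self.components_ = vecs.T
        self.total_variance_ = float(np.trace(C))
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, P):
        return self.mean_ + np.asarray(P) @ self.components_

    def mode_set(self, X) -> ModeSet:
        P = self.transform(X)
        cc = np.array(
            [cosine_content(P[:, i], i + 1) for i in range(P.shape[1])]
        )
        anh = np.array([anharmonicity(P[:, i]) for i in range(P.shape[1])])
        return ModeSet(
            kind="PCA",
            vectors=self.components_.T,
            projections=P,
            eigenvalues=self.eigenvalues_,
            anharmonicity=anh,
            cosine_content=cc,
        )


class FullCorrelationAnalysis(BaseEstimator, TransformerMixin):
    """MI-minimizing orthogonal transform of collective coordinates.

    Operates on the top-m PCA projections (n_frames, m). Jacobi-style
    pairwise rotations are swept until the decrease of the summed pairwise
    histogram MI per sweep falls below ``tol``; output coordinates are ordered
    by anharmonicity descending.

    Fitted attributes: ``rotation_`` (m, m orthogonal, already ordered),
    ``anharmonicity_``, ``mi_history_`` (total pairwise MI after each sweep,
    non-increasing), ``converged_``.
    """

    def __init__(
        self,
        tol: float = 1e-3,
        max_sweeps: int = 20,
        n_bins: int | None = None,
        n_angles: int = 120,
    ):
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.n_bins = n_bins
        self.n_angles = n_angles

    def fit(self, Y, y=None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise ValueError("need at least 2 collective coordinates")
        Y = Y - Y.mean(axis=0)
        n, m = Y.shape
        n_bins = self.n_bins or max(2, int(np.ceil(n ** (1 / 3))))
        R = np.eye(m)
        Z = Y.copy()
        # MI is invariant under 90-degree rotations of a pair, so the search
        # interval per pair is [0, pi/2)
        angles = np.linspace(0.0, np.pi / 2, self.n_angles, endpoint=False)[1:]
        history = [total_pairwise_mi(Z, n_bins)]
        converged = False
        def involved_mi(Zc, i, j):
            # all pairwise terms a rotation of (i, j) can change
            tot = pairwise_mi(Zc[:, i], Zc[:, j], n_bins)
            for k in range(m):
                if k != i and k != j:
                    tot += pairwise_mi(Zc[:, i], Zc[:, k], n_bins)
                    tot += pairwise_mi(Zc[:, j], Zc[:, k], n_bins)
            return tot

        for _ in range(self.max_sweeps):
            for i in range(m):
                for j in range(i + 1, m):
                    zi, zj = Z[:, i], Z[:, j]
                    best = pairwise_mi(zi, zj, n_bins)
                    best_t = 0.0
                    for t in angles:
                        c, s = np.cos(t), np.sin(t)
                        mi = pairwise_mi(c * zi + s * zj, -s * zi + c * zj, n_bins)
                        if mi < best:
                            best, best_t = mi, t
                    if best_t != 0.0:
                        c, s = np.cos(best_t), np.sin(best_t)
                        G = np.eye(m)
                        G[i, i] = G[j, j] = c
                        G[i, j] = -s
                        G[j, i] = s
                        Z_new = Z @ G
                        # accept only if the full affected objective drops, so
                        # the total pairwise MI descends monotonically
                        if m == 2 or involved_mi(Z_new, i, j) < involved_mi(Z, i, j):
                            Z = Z_new
                            R = R @ G
            history.append(total_pairwise_mi(Z, n_bins))
            if history[-2] - history[-1] < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("FCA did not converge within max_sweeps; "
                          "returning best transform so far")
        anh = np.array([anharmonicity(Z[:, k]) for k in range(m)])
        order = np.argsort(-anh, kind="stable")
        R = R[:, order]
        # deterministic sign per column
        for k in range(m):
            jmax = np.argmax(np.abs(R[:, k]))
            if R[jmax, k] < 0:
                R[:, k] = -R[:, k]
        self.rotation_ = R
        self.anharmonicity_ = anh[order]
        self.mi_history_ = np.asarray(history)
        self.converged_ = converged
        Zo = Y @ R
        var = Zo.var(axis=0)
        self.mode_variances_ = var
        self.top2_fluctuation_fraction_ = float(var[:2].sum() / var.sum())
        return self

    def transform(self, Y):
        Y = np.asarray(Y, dtype=float)
        return (Y - Y.mean(axis=0)) @ self.rotation_


def fca(
    traj: Trajectory,
    n_modes: int = 10,
    tol: float = 1e-3,
    max_sweeps: int = 20,
) -> ModeSet:
    """End-to-end FCA of a fitted trajectory via its top-``n_modes`` PCA.

    Returns a ModeSet of kind "FCA" whose 3N-space vectors are the PCA
    vectors rotated by the MI-minimizing transform, ordered by anharmonicity;
    ``extras`` carries the top-2 fluctuation fraction (relative to the full
    positional variance) and the MI descent history.
    """
    X = traj.flat()
    n_modes = min(n_modes, X.shape[1], X.shape[0] - 1)
    pca = TrajectoryPCA(n_modes=n_modes).fit(X)
    P = pca.transform(X)
    f = FullCorrelationAnalysis(tol=tol, max_sweeps=max_sweeps).fit(P)
    vectors = pca.components_.T @ f.rotation_
    Z = f.transform(P)
    cc = np.array([cosine_content(Z[:, i], i + 1) for i in range(Z.shape[1])])
    top2 = float(Z.var(axis=0)[:2].sum() / pca.total_variance_)
    return ModeSet(
        kind="FCA",
        vectors=vectors,
        projections=Z,
        anharmonicity=f.anharmonicity_,
        cosine_content=cc,
        converged=f.converged_,
        extras={
            "top2_fluctuation_fraction": top2,
            "mi_history": f.mi_history_,
            "mode_variances": f.mode_variances_,
        },
    )
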