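"""Cα trajectory container, rigid-body fitting, covariance and VACF spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 1 THz in wavenumbers
CM1_PER_THZ = 33.35641
#: speed of light in cm/ps (so wavenumber [cm^-1] * C_CM_PER_PS = frequency [THz])
C_CM_PER_PS = 1.0 / CM1_PER_THZ


@dataclass
class Trajectory:
    """Time-ordered Cα coordinates (nm) with time step dt (ps).

    positions: (n_frames, n_res, 3); velocities optional (nm/ps), derived by
    central differences when absent.
    """

    positions: np.ndarray
    dt: float
    residue_ids: np.ndarray
    velocities: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_res, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.residue_ids) != self.positions.shape[1]:
            raise ValueError("residue_ids length must match residue count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_res(self) -> int:
        return self.positions.shape[1]

    def flat(self) -> np.ndarray:
        """Positions as (n_frames, 3N)."""
        return self.positions.reshape(self.n_frames, -1)

    def get_velocities(self) -> np.ndarray:
        """Velocities; central differences of positions when not supplied."""
        if self.velocities is not None:
            return self.velocities
        v = np.gradient(self.positions, self.dt, axis=0)
        return v


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing ||P R - Q|| for centered P, Q."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def fit_and_center(traj: Trajectory, reference_frame: int = 0) -> Trajectory:
    """Remove rigid-body motion by least-squares superposition.

    Each frame is centered and rotated (Kabsch) onto the centered reference
    frame. Velocities, if present, are rotated with the same per-frame
    rotation.
    """
    if not 0 <= reference_frame < traj.n_frames:
        raise ValueError("reference_frame out of range")
    ref = traj.positions[reference_frame]
    ref = ref - ref.mean(axis=0)
    # a collinear (rank<2) reference leaves the rotation underdetermined
    if np.linalg.matrix_rank(ref, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) reference structure")
    out = np.empty_like(traj.positions)
    vel = traj.velocities
    vout = np.empty_like(vel) if vel is not None else None
    for t in range(traj.n_frames):
        frame = traj.positions[t]
        frame = frame - frame.mean(axis=0)
        R = _kabsch(frame, ref)
        out[t] = frame @ R
        if vel is not None:
            vout[t] = vel[t] @ R
    return Trajectory(out, traj.dt, traj.residue_ids, vout)


def covariance(traj: Trajectory) -> np.ndarray:
    """3N x 3N positional covariance C_ij = <(x_i - <x_i>)(x_j - <x_j>)>.

    <.> is the unweighted mean over frames (population normalization).
    """
    X = traj.flat()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / X.shape[0]
    return 0.5 * (C + C.T)


def cross_correlation(C: np.ndarray) -> np.ndarray:
    """Normalized residue-residue dynamic cross-correlation map.

    c(i,j) = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) from the 3x3 blocks of the
    positional covariance; diagonal 1; zero-variance residues give NaN rows.
    """
    n3 = C.shape[0]
    if n3 % 3:
        raise ValueError("covariance must be 3N x 3N")
    n = n3 // 3
    blocks = C.reshape(n, 3, n, 3)
    dots = np.einsum("iaja->ij", blocks)
    var = np.diag(dots).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = dots / np.sqrt(np.outer(var, var))
    out[var == 0, :] = np.nan
    out[:, var == 0] = np.nan
    ok = var > 0
    out[np.ix_(ok, ok)] = np.clip(out[np.ix_(ok, ok)], -1.0, 1.0)
    idx = np.where(ok)[0]
    out[idx, idx] = 1.0
    return out


def vacf(traj: Trajectory, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Normalized velocity autocorrelation function.

    C_v(tau) = <v_i(t+tau) . v_i(t)> / <v_i(t)^2>, averaged over atoms and
    time origins (FFT-based); C_v(0) = 1. Returns (lags_ps, vacf).
    """
    v = traj.get_velocities()
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames of velocities")
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    flat = v.reshape(n, -1)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(flat, n=nfft, axis=0)
    acf = np.fft.irfft((F * np.conj(F)).real, n=nfft, axis=0)[: max_lag + 1]
    acf = acf.sum(axis=1)
    counts = n - np.arange(max_lag + 1)
    acf = acf / counts
    if acf[0] == 0:
        raise ValueError("zero-velocity trajectory")
    lags = np.arange(max_lag + 1) * traj.dt
    return lags, acf / acf[0]


def vacf_spectrum(
    vacf_values: np.ndarray,
    dt: float,
    window: str = "hann",
    pad_factor: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Vibrational spectrum: windowed Fourier transform of the VACF.

    Returns (wavenumbers_cm1, intensity); frequency f [THz] maps to
    wavenumber via 33.35641 cm^-1/THz. Intensity is the transform magnitude
    (non-negative). A Hann window suppresses truncation ripple; the grid is
    zero-padded ``pad_factor``-fold for peak localization.
    """
    from scipy.signal import get_window

    y = np.asarray(vacf_values, dtype=float)
    if y.size < 2:
        raise ValueError("VACF too short")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if window is not None and window != "none":
        y = y * get_window(window, y.size, fftbins=False)
    nfft = pad_factor * y.size
    spec = np.abs(np.fft.rfft(y, n=nfft))
    freqs_thz = np.fft.rfftfreq(nfft, d=dt)  # dt in ps -> frequency in THz
    return freqs_thz * CM1_PER_THZ, spec


def spectrum_peaks(
    wavenumbers: np.ndarray, intensity: np.ndarray, n_peaks: int = 1
) -> list[float]:
    """Positions (cm^-1) of the strongest local maxima of a spectrum."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(intensity, prominence=0.05 * float(np.max(intensity)))
    if idx.size == 0:
        idx = np.array([int(np.argmax(intensity))])
    order = idx[np.argsort(intensity[idx])[::-1]]
    return [float(wavenumbers[i]) for i in order[:n_peaks]]


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as an NPZ archive with named arrays."""
    arrays = {
        "positions": traj.positions,
        "dt": np.array(traj.dt),
        "residue_ids": traj.residue_ids,
    }
    if traj.velocities is not None:
        arrays["velocities"] = traj.velocities
    np.savez(path, **arrays)


def load_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`save_trajectory`."""
    with np.load(path) as data:
        return Trajectory(
            positions=data["positions"],
            dt=float(data["dt"]),
            residue_ids=data["residue_ids"],
            velocities=data["velocities"] if "velocities" in data else None,
        )
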