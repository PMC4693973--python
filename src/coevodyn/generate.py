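"""Synthetic alignments, trajectories and graphs with planted structure.

The generators provide a download-free test surface with analytically
checkable ground truth: MSAs with tunable per-column conservation, planted
covarying column pairs (bijective-image coupling, so MI(X, f(X)) = H(X) at
full coupling) and star-phylogeny redundancy; trajectories that are sums of
planted harmonic and double-well collective modes plus isotropic noise; and
weighted planted-partition graphs for the network stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AA_LETTERS, GAP, RawAlignment
from .network import ResidueNetwork, build_network
from .trajectory import C_CM_PER_PS, Trajectory


@dataclass
class MsaGenSpec:
    """Specification of a synthetic family alignment.

    conserved_cols: (column, dominant residue letter, dominance p);
    coupled_pairs: (col_i, col_j, coupling rho in [0, 1]);
    phylo_redundancy: (copies per founder, per-site mutation rate) or None.
    """

    n_seq: int = 500
    n_col: int = 30
    background: np.ndarray | None = None
    conserved_cols: list[tuple[int, str, float]] = field(default_factory=list)
    coupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    phylo_redundancy: tuple[int, float] | None = None
    gap_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        bg = self.background
        if bg is not None:
            bg = np.asarray(bg, dtype=float)
            if bg.shape != (20,) or (bg < 0).any() or not np.isclose(bg.sum(), 1):
                raise ValueError("background must be a 20-simplex vector")
        for c, a, p in self.conserved_cols:
            if not 0 <= c < self.n_col or a not in AA_LETTERS or not 0 <= p <= 1:
                raise ValueError(f"invalid conserved column spec {(c, a, p)}")
        conserved = {c: p for c, _, p in self.conserved_cols}
        for i, j, rho in self.coupled_pairs:
            if not (0 <= i < self.n_col and 0 <= j < self.n_col) or i == j:
                raise ValueError(f"invalid coupled pair {(i, j)}")
            if not 0 <= rho <= 1:
                raise ValueError("coupling rho must be in [0, 1]")
            if rho == 1.0 and conserved.get(j) == 1.0:
                raise ValueError(
                    f"column {j} cannot be both fully conserved and fully "
                    f"coupled to column {i}"
                )
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")


def gen_msa(spec: MsaGenSpec) -> tuple[RawAlignment, dict]:
    """Draw a synthetic alignment; returns (alignment, planted-truth record).

    Columns are i.i.d. from the background; a conserved column draws its
    dominant residue with probability p; a coupled pair (i, j, rho) copies a
    fixed bijective image of column i into column j with probability rho.
    With phylo_redundancy, founders are expanded into mutated near-copies
    (star phylogeny). Pure function of (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = (
        np.full(20, 1 / 20)
        if spec.background is None
        else np.asarray(spec.background, dtype=float)
    )
    copies, mut_rate = spec.phylo_redundancy or (0, 0.0)
    n_founders = int(np.ceil(spec.n_seq / (1 + copies)))

    X = rng.choice(20, size=(n_founders, spec.n_col), p=bg)
    for c, a, p in spec.conserved_cols:
        dom = AA_LETTERS.index(a)
        take = rng.random(n_founders) < p
        X[take, c] = dom
    bijections = {}
    for i, j, rho in spec.coupled_pairs:
        perm = rng.permutation(20)
        bijections[(i, j)] = perm
        take = rng.random(n_founders) < rho
        X[take, j] = perm[X[take, i]]

    if copies:
        rows = [X]
        for _ in range(copies):
            mut = X.copy()
            flip = rng.random(X.shape) < mut_rate
            mut[flip] = rng.choice(20, size=int(flip.sum()), p=bg)
            rows.append(mut)
        X = np.vstack(rows)[: spec.n_seq]
    else:
        X = X[: spec.n_seq]

    letters = np.frombuffer(AA_LETTERS.encode(), dtype=np.uint8)
    chars = letters[X]
    if spec.gap_rate > 0:
        gaps = rng.random(X.shape) < spec.gap_rate
        chars = np.where(gaps, np.uint8(ord(GAP)), chars)
    rows = [bytes(r).decode("ascii") for r in chars]
    ids = [f"seq{k}" for k in range(len(rows))]
    truth = {
        "coupled_pairs": [(i, j, rho) for i, j, rho in spec.coupled_pairs],
        "conserved_cols": list(spec.conserved_cols),
        "bijections": {f"{i},{j}": perm.tolist() for (i, j), perm in bijections.items()},
        "n_founders": n_founders,
        "seed": spec.seed,
    }
    return RawAlignment(ids, rows), truth


@dataclass
class ModeSpec:
    """One planted collective mode of a synthetic trajectory."""

    support: list[int]  # residue indices (0-based) carrying the mode
    amplitude: float  # nm (rms for stochastic kinds, half-separation for wells)
    kind: str = "harmonic"  # "harmonic" | "gaussian" | "double_well"
    wavenumber: float = 100.0  # cm^-1, harmonic only
    barrier: float = 3.0  # double-well barrier height (kT-like units)
    phase: float = 0.0
    tau: float = 0.2  # ps, correlation time of the "gaussian" (OU) kind
    coherent: bool = False  # all support residues share one direction


@dataclass
class TrajGenSpec:
    """Specification of a synthetic Cα trajectory."""

    n_res: int = 40
    n_frames: int = 4000
    dt: float = 0.01  # ps
    modes: list[ModeSpec] = field(default_factory=list)
    noise_sd: float = 0.01  # nm
    seed: int = 0

    def validate(self) -> None:
        for m in self.modes:
            if any(not 0 <= r < self.n_res for r in m.support):
                raise ValueError("mode support outside residue range")
            if m.amplitude <= 0:
                raise ValueError("mode amplitude must be positive")
            if m.kind == "harmonic":
                if m.wavenumber <= 0:
                    raise ValueError("wavenumber must be positive")
                nyquist_thz = 1.0 / (2 * self.dt)
                f_thz = m.wavenumber * C_CM_PER_PS
                if f_thz >= nyquist_thz:
                    raise ValueError(
                        f"dt={self.dt} ps cannot resolve {m.wavenumber} cm^-1 "
                        f"({f_thz:.2f} THz >= Nyquist {nyquist_thz:.2f} THz)"
                    )
            elif m.kind == "gaussian":
                if m.tau <= 0:
                    raise ValueError("OU correlation time tau must be positive")
            elif m.kind != "double_well":
                raise ValueError(f"unknown mode kind {m.kind!r}")


def _double_well_series(
    n: int, amplitude: float, barrier: float, rng: np.random.Generator
) -> np.ndarray:
    """Overdamped Langevin sampling of V(x) = barrier * ((x/A)^2 - 1)^2.

    Integrated in the dimensionless coordinate u = x/A (Euler–Maruyama,
    stationary density ~ exp(-V)), then scaled to amplitude; wells sit at
    +-A, barrier height in thermal units sets the hopping rate. Several
    internal substeps per recorded frame give the trajectory many Kramers
    times, so both wells are visited in any realistic window.
    """
    h = 0.01  # dimensionless integrator step
    n_sub = 10  # internal steps per recorded frame
    u = 1.0 if rng.random() < 0.5 else -1.0
    burn = 200
    noise = np.sqrt(2 * h) * rng.standard_normal((n + burn) * n_sub)
    x = np.empty(n)
    k = 0
    for t in range(n + burn):
        for _ in range(n_sub):
            u = u - h * 4 * barrier * u * (u * u - 1) + noise[k]
            k += 1
        if t >= burn:
            x[t - burn] = u
    return amplitude * x


def _ou_series(
    n: int, dt: float, sd: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Ornstein–Uhlenbeck series: Gaussian-amplitude thermal mode.

    Stationary standard deviation ``sd``, correlation time ``tau`` — the
    amplitude statistics of an overdamped harmonic mode in a heat bath.
    """
    rho = np.exp(-dt / tau)
    innov = sd * np.sqrt(1 - rho * rho) * rng.standard_normal(n)
    x = np.empty(n)
    x[0] = sd * rng.standard_normal()
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t]
    return x


def gen_trajectory(spec: TrajGenSpec) -> tuple[Trajectory, dict]:
    """Synthesize a Cα trajectory; returns (trajectory, planted truth).

    positions(t) = base + sum_m a_m(t) u_m + Gaussian noise, with unit mode
    shapes u_m supported on the named residues. Harmonic amplitudes are
    A cos(2 pi c nu t + phi) with analytic velocities; double-well amplitudes
    come from Langevin sampling of a symmetric quartic (finite-difference
    velocities). Pure function of (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, N = spec.n_frames, spec.n_res
    base = rng.normal(scale=1.0, size=(N, 3))
    t = np.arange(n) * spec.dt

    shapes, series, dseries, truth_modes = [], [], [], []
    for m in spec.modes:
        u = np.zeros((N, 3))
        if m.coherent:
            u[m.support] = rng.normal(size=3)
        else:
            u[m.support] = rng.normal(size=(len(m.support), 3))
        u /= np.linalg.norm(u)
        shapes.append(u)
        if m.kind == "harmonic":
            omega = 2 * np.pi * m.wavenumber * C_CM_PER_PS  # rad/ps
            a = m.amplitude * np.cos(omega * t + m.phase)
            da = -m.amplitude * omega * np.sin(omega * t + m.phase)
        elif m.kind == "gaussian":
            a = _ou_series(n, spec.dt, m.amplitude, m.tau, rng)
            da = np.gradient(a, spec.dt)
        else:
            a = _double_well_series(n, m.amplitude, m.barrier, rng)
            da = np.gradient(a, spec.dt)
        series.append(a)
        dseries.append(da)
        truth_modes.append(
            {
                "support": list(m.support),
                "kind": m.kind,
                "amplitude": m.amplitude,
                "wavenumber": m.wavenumber if m.kind == "harmonic" else None,
                "shape": u.ravel().tolist(),
            }
        )

    pos = np.broadcast_to(base, (n, N, 3)).copy()
    vel = np.zeros((n, N, 3))
    for u, a, da in zip(shapes, series, dseries):
        pos += a[:, None, None] * u
        vel += da[:, None, None] * u
    if spec.noise_sd > 0:
        pos += rng.normal(scale=spec.noise_sd, size=pos.shape)
    traj = Trajectory(
        positions=pos,
        dt=spec.dt,
        residue_ids=np.arange(1, N + 1),
        velocities=vel if spec.modes else None,
    )
    return traj, {"modes": truth_modes, "noise_sd": spec.noise_sd, "seed": spec.seed}


def gen_graph(
    block_sizes: list[int],
    p_in: float = 0.9,
    p_out: float = 0.05,
    seed: int = 0,
    w_in: tuple[float, float] = (8.0, 12.0),
    w_out: tuple[float, float] = (6.5, 8.0),
) -> tuple[ResidueNetwork, dict[int, int]]:
    """Weighted planted-partition graph fixture; returns (network, labels).

    Node u is in block b(u); within-block edges appear with probability p_in
    (weights uniform in w_in), cross-block with p_out (weights in w_out).
    Nodes are numbered from 1, like reference residues.
    """
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels: dict[int, int] = {}
    node = 1
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            labels[node] = b
            node += 1
    nodes = sorted(labels)
    edges = []
    for ai, u in enumerate(nodes):
        for v in nodes[ai + 1 :]:
            same = labels[u] == labels[v]
            p, wr = (p_in, w_in) if same else (p_out, w_out)
            if rng.random() < p:
                edges.append((u, v, float(rng.uniform(*wr))))
    scores = {u: 0.0 for u in nodes}
    for u, v, w in edges:
        scores[u] += w
        scores[v] += w
    return build_network(edges, scores), labels
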