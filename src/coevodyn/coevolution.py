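"""Per-column conservation and pairwise coevolution scoring.

Coevolution between two alignment columns is measured as weighted mutual
information (MI, natural log) over pseudocounted amino-acid pair frequencies,
cleaned of entropic/phylogenetic background by a product (APC-style)
correction, and referenced to a null distribution obtained by shuffling
residues within columns of the alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .alignment import GAP_CODE, UNK_CODE, WeightedAlignment

CONSERVATION_MAX = 11.0  # top of the reported scale; rendered "*"


@dataclass
class ColumnProfile:
    """Weighted per-column amino-acid frequencies (21 symbols incl. gap)."""

    freqs: np.ndarray  # (n_cols, 21), rows sum to 1
    eff_count: float  # sum of sequence weights

    def __post_init__(self) -> None:
        s = self.freqs.sum(axis=1)
        # all-missing columns carry an all-zero row (no distribution exists)
        if not np.all(np.isclose(s, 1.0, atol=1e-12) | (s == 0)):
            raise ValueError("column frequencies must sum to 1")
        if (self.freqs < 0).any():
            raise ValueError("negative frequency")


@dataclass
class CoevolutionResult:
    """MI / corrected-MI / z-score matrices plus per-column conservation."""

    mi: np.ndarray
    mi_corrected: np.ndarray
    z: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    conservation: np.ndarray
    n_randomizations: int
    seed: int | None


def column_profile(wa: WeightedAlignment, pseudocount: float = 0.0) -> ColumnProfile:
    """Weighted symbol frequencies per column ('X' excluded, gap counted)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    X = wa.alignment.encoded()
    w = np.asarray(wa.weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero effective count")
    n_cols = X.shape[1]
    freqs = np.full((n_cols, 21), pseudocount, dtype=float)
    for c in range(n_cols):
        col = X[:, c]
        ok = col != UNK_CODE
        freqs[c] += np.bincount(col[ok], weights=w[ok], minlength=21)[:21]
        tot = freqs[c].sum()
        if tot > 0:
            freqs[c] /= tot
    return ColumnProfile(freqs, float(w.sum()))


def conservation_score(
    profile: ColumnProfile, background: np.ndarray | None = None
) -> np.ndarray:
    """Kullback–Leibler conservation per column on the [0, 11] scale.

    Column frequencies are gap-excluded and renormalized, then
    KL(p ‖ background) is rescaled so that a fully conserved column against a
    uniform background scores exactly 11 (rendered "*"). All-gap columns are
    NaN.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    p = profile.freqs[:, :20].copy()
    tot = p.sum(axis=1)
    out = np.full(p.shape[0], np.nan)
    ok = tot > 0
    p[ok] /= tot[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / background), 0.0)
    kl = terms.sum(axis=1)
    out[ok] = np.clip(CONSERVATION_MAX * kl[ok] / np.log(20.0), 0, CONSERVATION_MAX)
    return out


def render_conservation(score: float) -> str:
    """Jalview-style one-character rendering: '*' at the top of the scale."""
    if np.isnan(score):
        return "."
    if score >= CONSERVATION_MAX - 1e-9:
        return "*"
    return str(min(9, int(score)))


def _pair_mi_matrix(
    X: np.ndarray, w: np.ndarray, pseudocount: float, gap_mode: str
) -> np.ndarray:
    """MI (nats) for every column pair of an encoded alignment."""
    n_cols = X.shape[1]
    mi = np.zeros((n_cols, n_cols))
    if gap_mode == "gap_as_symbol":
        n_sym, missing = 21, (UNK_CODE,)
    elif gap_mode == "exclude_pairs":
        n_sym, missing = 20, (GAP_CODE, UNK_CODE)
    else:
        raise ValueError(f"unknown gap_mode: {gap_mode!r}")
    cols_ok = [~np.isin(X[:, c], missing) for c in range(n_cols)]
    for i in range(n_cols):
        xi = X[:, i].astype(np.intp)
        for j in range(i + 1, n_cols):
            ok = cols_ok[i] & cols_ok[j]
            if not ok.any():
                continue
            code = xi[ok] * n_sym + X[ok, j]
            counts = np.bincount(code, weights=w[ok], minlength=n_sym * n_sym)
            counts = counts.reshape(n_sym, n_sym) + pseudocount
            total = counts.sum()
            if total <= 0:
                continue
            p = counts / total
            pi = p.sum(axis=1)
            pj = p.sum(axis=0)
            nz = p > 0
            mi[i, j] = mi[j, i] = float(
                np.sum(p[nz] * np.log(p[nz] / np.outer(pi, pj)[nz]))
            )
    return mi


def weighted_mi(
    wa: WeightedAlignment,
    pseudocount: float = 0.05,
    gap_mode: str = "exclude_pairs",
) -> np.ndarray:
    """Weighted mutual information (nats) between all column pairs.

    MI(i, j) = sum_ab p_ij(a,b) ln[ p_ij(a,b) / (p_i(a) p_j(b)) ] with
    weighted, pseudocounted pair frequencies; the pseudocount is added to
    every cell of the pair-count table before normalization. The diagonal is
    set to 0 by convention. ``exclude_pairs`` drops a sequence from pair
    (i, j) if it is gapped at either column.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    w = np.asarray(wa.weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero effective count")
    if wa.n_cols < 2:
        raise ValueError("need at least 2 columns")
    return _pair_mi_matrix(wa.alignment.encoded(), w, pseudocount, gap_mode)


def background_correction(mi: np.ndarray) -> np.ndarray:
    """Product (APC-style) background correction.

    corrected(i,j) = mi(i,j) − mean_i(mi)·mean_j(mi)/mean_all(mi), with means
    over off-diagonal entries; suppresses shared-ancestry and entropic
    background. May produce negative entries.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    if n < 2:
        return mi.copy()
    off = ~np.eye(n, dtype=bool)
    mean_all = mi[off].mean()
    if mean_all == 0:
        return mi.copy()
    row_mean = (mi.sum(axis=1) - np.diag(mi)) / (n - 1)
    corrected = mi - np.outer(row_mean, row_mean) / mean_all
    np.fill_diagonal(corrected, 0.0)
    return corrected


def _permute_within_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle amino-acid letters within each column; gaps/'X' stay in place."""
    out = X.copy()
    for c in range(X.shape[1]):
        col = X[:, c]
        idx = np.flatnonzero(col < GAP_CODE)
        if idx.size > 1:
            out[idx, c] = col[rng.permutation(idx)]
    return out


def zscore_vs_null(
    wa: WeightedAlignment,
    n_randomizations: int = 100,
    seed: int | None = None,
    statistic: str = "mi_corrected",
    pseudocount: float = 0.05,
    gap_mode: str = "exclude_pairs",
    pooled: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null-referenced coevolution z-scores from randomized alignments.

    Each randomization independently permutes residues within every column
    (preserving column composition and gap placement), recomputes the chosen
    statistic, and z(i,j) = (obs − null_mean) / null_sd. Pairs with zero null
    spread are reported NaN with a warning. ``pooled`` replaces the per-pair
    null moments by moments pooled over all pairs.
    """
    if n_randomizations < 2:
        raise ValueError("need at least 2 randomizations")
    if statistic not in ("mi", "mi_corrected"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    rng = np.random.default_rng(seed)
    X = wa.alignment.encoded()
    w = np.asarray(wa.weights, dtype=float)

    def stat(Xs: np.ndarray) -> np.ndarray:
        m = _pair_mi_matrix(Xs, w, pseudocount, gap_mode)
        return background_correction(m) if statistic == "mi_corrected" else m

    obs = stat(X)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_randomizations):
        s = stat(_permute_within_columns(X, rng))
        acc += s
        acc2 += s * s
    null_mean = acc / n_randomizations
    null_var = np.maximum(acc2 / n_randomizations - null_mean**2, 0.0)
    null_sd = np.sqrt(null_var * n_randomizations / (n_randomizations - 1))
    n = obs.shape[0]
    off = ~np.eye(n, dtype=bool)
    if pooled:
        null_mean = np.full_like(null_mean, null_mean[off].mean())
        null_sd = np.full_like(null_sd, null_sd[off].mean())
    zero = (null_sd == 0) & off
    if zero.any():
        warnings.warn(
            f"{int(zero.sum() // 2)} pair(s) with zero null spread; z set to NaN"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    np.fill_diagonal(z, 0.0)
    return z, null_mean, null_sd


def coevolution_edges(
    z: np.ndarray, mapping, cutoff: float = 6.5
) -> list[tuple[int, int, float]]:
    """Undirected edges (res_i, res_j, z) for pairs with z >= cutoff."""
    residues = mapping.residues
    n = z.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            v = z[i, j]
            if np.isfinite(v) and v >= cutoff:
                edges.append((residues[i], residues[j], float(v)))
    return edges


def node_mi_score(z: np.ndarray, mapping) -> dict[int, float]:
    """Cumulative per-residue score: sum of positive z over incident pairs."""
    residues = mapping.residues
    pos = np.where(np.isfinite(z) & (z > 0), z, 0.0)
    np.fill_diagonal(pos, 0.0)
    sums = pos.sum(axis=1)
    return {r: float(s) for r, s in zip(residues, sums)}


class CoevolutionScorer(BaseEstimator):
    """Estimator computing conservation, MI, corrected MI and z-scores.

    Parameters
    ----------
    pseudocount : float
        Symmetric low-count correction added to every pair-count cell.
    gap_mode : {"exclude_pairs", "gap_as_symbol"}
        Gap handling in pair frequencies.
    n_randomizations : int
        Number of within-column shuffles for the null distribution.
    statistic : {"mi_corrected", "mi"}
        Statistic z-scored against the null.
    cutoff : float
        z threshold for the coevolution edge list.
    pooled_null : bool
        Pool null moments over pairs instead of per-pair moments.
    random_state : int or None
        Seed for the randomization null.
    """

    def __init__(
        self,
        pseudocount: float = 0.05,
        gap_mode: str = "exclude_pairs",
        n_randomizations: int = 100,
        statistic: str = "mi_corrected",
        cutoff: float = 6.5,
        pooled_null: bool = False,
        random_state: int | None = None,
    ):
        self.pseudocount = pseudocount
        self.gap_mode = gap_mode
        self.n_randomizations = n_randomizations
        self.statistic = statistic
        self.cutoff = cutoff
        self.pooled_null = pooled_null
        self.random_state = random_state

    def fit(self, wa: WeightedAlignment, y=None):
        profile = column_profile(wa, self.pseudocount)
        self.conservation_ = conservation_score(profile)
        self.mi_ = weighted_mi(wa, self.pseudocount, self.gap_mode)
        self.mi_corrected_ = background_correction(self.mi_)
        self.z_, self.null_mean_, self.null_sd_ = zscore_vs_null(
            wa,
            n_randomizations=self.n_randomizations,
            seed=self.random_state,
            statistic=self.statistic,
            pseudocount=self.pseudocount,
            gap_mode=self.gap_mode,
            pooled=self.pooled_null,
        )
        self.edges_ = coevolution_edges(self.z_, wa.mapping, self.cutoff)
        self.node_scores_ = node_mi_score(self.z_, wa.mapping)
        self.result_ = CoevolutionResult(
            mi=self.mi_,
            mi_corrected=self.mi_corrected_,
            z=self.z_,
            null_mean=self.null_mean_,
            null_sd=self.null_sd_,
            conservation=self.conservation_,
            n_randomizations=self.n_randomizations,
            seed=self.random_state,
        )
        return self
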