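"""Family-alignment curation: reading, reference mapping, filtering, weighting.

The curation protocol mirrors the standard coevolution preprocessing recipe:
map every sequence onto a reference structure's sequence by local alignment,
keep close homologs only, truncate the alignment to structurally resolved
reference residues, drop redundant and gappy rows, then down-weight residual
redundancy by clustering so each sequence cluster contributes unit weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: integer codes: 0..19 amino acids, 20 gap, 21 unknown
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}
GAP_CODE = 20
UNK_CODE = 21


class AlignmentFormatError(ValueError):
    """Raised when an input alignment violates the expected format."""


@dataclass
class RawAlignment:
    """A rectangular multiple sequence alignment over {AA, '-', 'X'}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentFormatError("sequence identifiers are not unique")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise AlignmentFormatError(
                        f"ragged alignment: sequence {sid!r} has length "
                        f"{len(row)}, expected {n}"
                    )

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encoded(self) -> np.ndarray:
        """Integer-encode as an (n_seq, n_cols) int8 array."""
        out = np.empty((self.n_seq, self.n_cols), dtype=np.int8)
        lut = np.full(128, UNK_CODE, dtype=np.int8)
        for a, i in AA_INDEX.items():
            lut[ord(a)] = i
        lut[ord(GAP)] = GAP_CODE
        for k, row in enumerate(self.rows):
            out[k] = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        return out

    def subset_rows(self, keep: list[int]) -> "RawAlignment":
        return RawAlignment(
            [self.ids[i] for i in keep], [self.rows[i] for i in keep]
        )

    def subset_cols(self, cols: list[int]) -> "RawAlignment":
        return RawAlignment(
            list(self.ids), ["".join(r[c] for c in cols) for r in self.rows]
        )


@dataclass
class ReferenceMapping:
    """Partial map from alignment columns to 1-based reference residue numbers."""

    ref_id: str
    ref_seq: str
    col_to_refres: dict[int, int]

    def __post_init__(self) -> None:
        items = sorted(self.col_to_refres.items())
        cols = [c for c, _ in items]
        res = [r for _, r in items]
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ValueError("column->residue map must be strictly increasing")
        if cols and (res[0] < 1 or res[-1] > len(self.ref_seq)):
            raise ValueError("mapped residue number outside reference sequence")

    @property
    def residues(self) -> list[int]:
        return [self.col_to_refres[c] for c in sorted(self.col_to_refres)]


@dataclass
class WeightedAlignment:
    """Curated alignment with per-sequence weights and a reference mapping.

    Each redundancy cluster contributes total weight 1, split equally among
    its members, so the weights sum to ``n_clusters`` exactly.
    """

    alignment: RawAlignment
    mapping: ReferenceMapping
    weights: np.ndarray
    clusters: np.ndarray
    n_clusters: int
    min_identity: float = field(default=float("nan"))

    @property
    def n_seq(self) -> int:
        return self.alignment.n_seq

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols

    @property
    def residue_numbers(self) -> list[int]:
        return self.mapping.residues


def _normalize_row(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        if ch not in AA_INDEX and ch not in (GAP, UNKNOWN):
            ch = UNKNOWN
        out.append(ch)
    return "".join(out)


def read_alignment(path, format: str = "fasta") -> RawAlignment:
    """Read a FASTA or Stockholm alignment into a :class:`RawAlignment`.

    Lowercase letters are uppercased, '.' insert states become '-', and any
    symbol outside the 20-letter alphabet maps to 'X'.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq)) for r in records]
    return RawAlignment(ids, rows)


@dataclass
class LocalAlignment:
    """Result of a Smith–Waterman local alignment."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float


def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError as exc:  # pragma: no cover - message path
        raise ValueError(f"unknown substitution matrix: {name!r}") from exc


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> LocalAlignment:
    """Optimal local alignment with affine gaps (length-L gap costs
    ``gap_open + (L-1)*gap_extend``).

    Identity is matches divided by aligned non-gap-pair columns. 'X' scores 0
    against every letter and counts as a mismatch.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _pad_matrix(_load_matrix(matrix))
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    alignments = aligner.align(a, b)
    try:
        aln = alignments[0]
    except IndexError:
        # no positive-scoring local alignment exists
        return LocalAlignment("", "", 0.0, 0.0)
    sa, sb = str(aln[0]), str(aln[1])
    pairs = [(x, y) for x, y in zip(sa, sb) if x != GAP and y != GAP]
    matches = sum(
        1 for x, y in pairs if x == y and x != UNKNOWN
    )
    identity = matches / len(pairs) if pairs else 0.0
    return LocalAlignment(sa, sb, float(aln.score), identity)


def _pad_matrix(m):
    """Restrict a substitution matrix to the 20 AA + 'X', with 'X' scoring 0."""
    out = substitution_matrices.Array(AA_LETTERS + UNKNOWN, dims=2)
    for a in AA_LETTERS:
        for b in AA_LETTERS:
            out[a, b] = m[a, b]
    return out


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Identity of two *aligned* rows: matches / non-gap-pair columns."""
    both = [(x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    matches = sum(1 for x, y in both if x == y and x != UNKNOWN)
    return matches / len(both)


def identity_matrix(msa: RawAlignment) -> np.ndarray:
    """All pairwise identities (matches / non-gap-pair columns), vectorized."""
    X = msa.encoded()
    n = msa.n_seq
    residue = X < GAP_CODE  # 'X' (code 21) never matches and is not a residue pair? -> treated below
    present = X != GAP_CODE  # X counts as aligned (mismatching) column
    out = np.eye(n)
    for i in range(n):
        both = present[i] & present[i + 1 :]
        match = (X[i] == X[i + 1 :]) & both & residue[i]
        denom = both.sum(axis=1)
        num = match.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
        out[i, i + 1 :] = ident
        out[i + 1 :, i] = ident
    return out


def map_to_reference(
    msa: RawAlignment,
    ref_seq: str,
    ref_id: str = "reference",
    min_identity: float = 0.95,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[RawAlignment, ReferenceMapping]:
    """Drop sequences below ``min_identity`` to the reference and truncate the
    alignment to columns aligned to a reference residue.

    Every row is locally aligned (Smith–Waterman) to the ungapped reference;
    the best-matching row anchors the column -> reference-residue map.
    """
    ref_seq = _normalize_row(ref_seq).replace(GAP, "")
    identities = []
    for row in msa.rows:
        ungapped = row.replace(GAP, "")
        if not ungapped:
            identities.append(0.0)
            continue
        aln = smith_waterman(ungapped, ref_seq, matrix, gap_open, gap_extend)
        # identity relative to the full reference length, so short fragments
        # cannot reach the threshold on a partial overlap
        matched = sum(
            1
            for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x == y and x != GAP and x != UNKNOWN
        )
        identities.append(matched / len(ref_seq))
    keep = [i for i, v in enumerate(identities) if v >= min_identity]
    if not keep:
        raise ValueError("reference not found in family: no sequence reaches "
                         f"{min_identity:.0%} identity")
    anchor = max(keep, key=lambda i: identities[i])
    anchor_row = msa.rows[anchor]
    anchor_ungapped = anchor_row.replace(GAP, "")
    aln = smith_waterman(anchor_ungapped, ref_seq, matrix, gap_open, gap_extend)

    # residue index (0-based) in anchor_ungapped -> residue number in ref_seq
    res_map: dict[int, int] = {}
    # walk the local alignment; offsets of the aligned slices
    ia = _local_start(anchor_ungapped, aln.aligned_a)
    ib = _local_start(ref_seq, aln.aligned_b)
    pa, pb = ia, ib
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != GAP and y != GAP:
            res_map[pa] = pb + 1
        if x != GAP:
            pa += 1
        if y != GAP:
            pb += 1

    # column of the MSA -> index of the anchor residue occupying it
    col_to_refres: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(anchor_row):
        if ch != GAP:
            if k in res_map:
                col_to_refres[col] = res_map[k]
            k += 1
    if not col_to_refres:
        raise ValueError("reference alignment produced an empty column map")

    cols = sorted(col_to_refres)
    kept = msa.subset_rows(keep).subset_cols(cols)
    mapping = ReferenceMapping(
        ref_id, ref_seq, {j: col_to_refres[c] for j, c in enumerate(cols)}
    )
    return kept, mapping


def _local_start(full: str, aligned: str) -> int:
    """Offset of a local-alignment slice within the full sequence."""
    core = aligned.replace(GAP, "")
    idx = full.find(core)
    if idx < 0:  # pragma: no cover - cannot happen for a valid alignment
        raise RuntimeError("aligned slice not found in source sequence")
    return idx


def filter_redundancy(
    msa: RawAlignment, max_identity: float = 0.99, ref_id: str | None = None
) -> RawAlignment:
    """Greedy redundancy removal in input order.

    A sequence is kept iff its identity to every already-kept sequence is
    <= ``max_identity``; the reference row (``ref_id``), if named, is anchored
    first so it always survives.
    """
    if msa.n_seq == 0:
        raise ValueError("empty alignment")
    order = list(range(msa.n_seq))
    if ref_id is not None and ref_id in msa.ids:
        r = msa.ids.index(ref_id)
        order.remove(r)
        order.insert(0, r)
    ident = identity_matrix(msa)
    kept: list[int] = []
    for i in order:
        if all(ident[i, j] <= max_identity for j in kept):
            kept.append(i)
    kept.sort()
    return msa.subset_rows(kept)


def filter_gappy(msa: RawAlignment, max_gap_frac: float = 0.20) -> RawAlignment:
    """Drop rows with strictly more than ``max_gap_frac`` gaps."""
    if msa.n_seq == 0:
        raise ValueError("empty alignment")
    keep = [
        i
        for i, row in enumerate(msa.rows)
        if row.count(GAP) / max(len(row), 1) <= max_gap_frac
    ]
    if not keep:
        raise ValueError("all sequences exceed the gap-fraction threshold")
    return msa.subset_rows(keep)


def cluster_and_weight(
    msa: RawAlignment,
    mapping: ReferenceMapping,
    cluster_identity: float = 0.62,
) -> WeightedAlignment:
    """Single-linkage clustering at ``cluster_identity``; weight = 1/|cluster|.

    Two sequences join the same cluster iff connected through pairs of
    identity >= ``cluster_identity``. The minimum pairwise identity over the
    final alignment is recorded.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    ident = identity_matrix(msa)
    n = msa.n_seq
    adj = csr_matrix((ident >= cluster_identity) & ~np.eye(n, dtype=bool))
    n_clusters, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_clusters)
    weights = 1.0 / sizes[labels]
    off = ident[~np.eye(n, dtype=bool)]
    min_ident = float(off.min()) if off.size else 1.0
    return WeightedAlignment(
        alignment=msa,
        mapping=mapping,
        weights=weights,
        clusters=labels,
        n_clusters=int(n_clusters),
        min_identity=min_ident,
    )


def trivial_weighting(
    msa: RawAlignment, mapping: ReferenceMapping | None = None
) -> WeightedAlignment:
    """Unit-weight WeightedAlignment (every sequence its own cluster)."""
    if mapping is None:
        mapping = ReferenceMapping(
            "synthetic",
            "X" * msa.n_cols,
            {c: c + 1 for c in range(msa.n_cols)},
        )
        # reference sequence unknown for synthetic alignments; use first row
        first = msa.rows[0].replace(GAP, "") if msa.rows else ""
        if len(first) == msa.n_cols:
            mapping = ReferenceMapping(
                msa.ids[0], first, {c: c + 1 for c in range(msa.n_cols)}
            )
    n = msa.n_seq
    return WeightedAlignment(
        alignment=msa,
        mapping=mapping,
        weights=np.ones(n),
        clusters=np.arange(n),
        n_clusters=n,
    )


def msa_sequence_pca(
    wa: WeightedAlignment,
    score_matrix: str = "BLOSUM62",
    n_components: int = 3,
) -> np.ndarray:
    """Sequence-space PCA of the alignment.

    Each sequence is encoded as the concatenation of substitution-matrix score
    columns of its residues (gap/'X' columns are zero), then the weighted,
    centered encoding is decomposed so similar sequences land near each other.
    Returns an (n_seq, n_components) coordinate array.
    """
    if wa.n_seq < 2:
        raise ValueError("need at least 2 sequences")
    m = _load_matrix(score_matrix)
    alpha = str(m.alphabet)
    cols = {a: np.array([m[a, b] for b in AA_LETTERS]) for a in alpha if a in AA_INDEX}
    zero = np.zeros(20)
    X = np.empty((wa.n_seq, 20 * wa.n_cols))
    for i, row in enumerate(wa.alignment.rows):
        X[i] = np.concatenate([cols.get(ch, zero) for ch in row])
    max_dim = min(wa.n_seq, X.shape[1])
    if n_components > max_dim:
        raise ValueError(
            f"n_components={n_components} exceeds available dimensions {max_dim}"
        )
    w = np.asarray(wa.weights, dtype=float)
    mean = (w[:, None] * X).sum(0) / w.sum()
    Xc = (X - mean) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
    return (X - mean) @ vt[:n_components].T
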