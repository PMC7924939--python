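"""Pairwise and progressive multiple alignment.

The pipeline aligns carrier sequences before distance, likelihood and
conservation analysis.  Pairwise global alignment uses an affine-gap
Needleman–Wunsch (delegated to Biopython's PairwiseAligner); the multiple
aligner is a deliberately simple progressive scheme — UPGMA guide tree on
k-mer cosine distances, then leaf-to-root profile–profile merging — and the
pipeline equally accepts an externally produced aligned FASTA, so the
internal aligner is swappable.

Default scoring is BLOSUM62 with gap open -10 and gap extend -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_formats import AMINO_ACIDS, GAP, Alignment, SeqRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class SubstitutionMatrix:
    """Symmetric residue scores plus affine gap penalties (negative)."""

    scores: np.ndarray            # (20, 20), alphabet order AMINO_ACIDS
    gap_open: float = -10.0
    gap_extend: float = -1.0
    x_score: float = 0.0          # score of 'X' against anything

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        if a == "X" or b == "X":
            return self.x_score
        return float(self.scores[_AA_INDEX[a], _AA_INDEX[b]])

    def to_bio(self) -> substitution_matrices.Array:
        alpha = AMINO_ACIDS + "X"
        arr = substitution_matrices.Array(alphabet=alpha, dims=2)
        for i, a in enumerate(alpha):
            for j, b in enumerate(alpha):
                arr[a, b] = self.score(a, b)
        return arr


def default_matrix(gap_open: float = -10.0,
                   gap_extend: float = -1.0) -> SubstitutionMatrix:
    """BLOSUM62 restricted to the 20-residue alphabet."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = blosum[a, b]
    return SubstitutionMatrix(m, gap_open, gap_extend)


def identity_matrix(match: float = 1.0, mismatch: float = 0.0,
                    gap: float = -1.0) -> SubstitutionMatrix:
    """Toy scoring used in tests: match/mismatch constants, linear gaps."""
    m = np.full((20, 20), mismatch)
    np.fill_diagonal(m, match)
    return SubstitutionMatrix(m, gap_open=gap, gap_extend=gap)


def _as_residues(x) -> tuple[str, str]:
    if isinstance(x, SeqRecord):
        return x.id, x.residues
    return "seq", str(x)


def nw_align(a, b, matrix: SubstitutionMatrix | None = None
             ) -> tuple[Alignment, float]:
    """Optimal global affine-gap alignment of two sequences.

    Accepts :class:`SeqRecord` or plain strings; returns a two-row
    alignment plus its score.  Traceback is deterministic (the aligner's
    first reported optimum).
    """
    matrix = matrix or default_matrix()
    id_a, res_a = _as_residues(a)
    id_b, res_b = _as_residues(b)
    if isinstance(b, SeqRecord) or id_a == id_b:
        id_b = id_b if id_b != id_a else id_a + "_2"
    if not res_a and not res_b:
        raise ValueError("both sequences empty")
    if not res_a or not res_b:
        n = max(len(res_a), len(res_b))
        row_a = res_a or GAP * n
        row_b = res_b or GAP * n
        score = matrix.gap_open + matrix.gap_extend * (n - 1)
        return Alignment([SeqRecord(id_a, row_a), SeqRecord(id_b, row_b)]), score

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix.to_bio()
    # Biopython's open score applies to the first gap residue.
    aligner.open_gap_score = matrix.gap_open
    aligner.extend_gap_score = matrix.gap_extend
    result = aligner.align(res_a, res_b)
    best = result[0]
    row_a, row_b = str(best[0]), str(best[1])
    return (Alignment([SeqRecord(id_a, row_a), SeqRecord(id_b, row_b)]),
            float(best.score))


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _kmer_vector(residues: str, k: int = 3) -> dict[str, int]:
    v: dict[str, int] = {}
    s = residues.replace("X", "")
    for i in range(len(s) - k + 1):
        w = s[i:i + k]
        v[w] = v.get(w, 0) + 1
    return v


def _cosine_distance(u: dict[str, int], v: dict[str, int]) -> float:
    if not u or not v:
        return 1.0
    dot = sum(c * v[w] for w, c in u.items() if w in v)
    nu = np.sqrt(sum(c * c for c in u.values()))
    nv = np.sqrt(sum(c * c for c in v.values()))
    return 1.0 - dot / (nu * nv)


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies (gaps and X excluded), (n_cols, 20)."""
    n = len(rows[0])
    f = np.zeros((n, 20))
    for r in rows:
        for j, c in enumerate(r):
            i = _AA_INDEX.get(c)
            if i is not None:
                f[j, i] += 1
    tot = f.sum(axis=1, keepdims=True)
    np.divide(f, tot, out=f, where=tot > 0)
    return f


def _profile_nw(fa: np.ndarray, fb: np.ndarray, scores: np.ndarray,
                gap_open: float, gap_extend: float) -> list[tuple[int, int]]:
    """Affine global DP between two column-frequency profiles.

    Returns the merge path as (i, j) pairs with -1 marking a gap column.
    Column score is the expected substitution score under the two columns'
    frequency vectors.
    """
    S = fa @ scores @ fb.T
    n1, n2 = S.shape
    neg = -1e30
    M = np.full((n1 + 1, n2 + 1), neg)
    Ix = np.full((n1 + 1, n2 + 1), neg)   # gap in profile b (consume a)
    Iy = np.full((n1 + 1, n2 + 1), neg)   # gap in profile a (consume b)
    ptr_m = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_x = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_y = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        Ix[i, 0] = gap_open + gap_extend * (i - 1)
        ptr_x[i, 0] = 1
    for j in range(1, n2 + 1):
        Iy[0, j] = gap_open + gap_extend * (j - 1)
        ptr_y[0, j] = 2
    for i in range(1, n1 + 1):
        prev_m, prev_x, prev_y = M[i - 1], Ix[i - 1], Iy[i - 1]
        # Ix: vertical moves, depend on row i-1 only.
        cand = np.stack([prev_m + gap_open, prev_x + gap_extend,
                         prev_y + gap_open])
        ptr_x[i] = cand.argmax(axis=0)
        Ix[i] = cand.max(axis=0)
        # M: diagonal from (i-1, j-1).
        diag = np.stack([prev_m[:-1], prev_x[:-1], prev_y[:-1]])
        ptr_m[i, 1:] = diag.argmax(axis=0)
        M[i, 1:] = diag.max(axis=0) + S[i - 1]
        # Iy: horizontal within row i — sequential, done with a scan.
        m_row, x_row = M[i], Ix[i]
        y_row = Iy[i]
        best = neg
        src = 0
        for j in range(1, n2 + 1):
            open_m = m_row[j - 1] + gap_open
            open_x = x_row[j - 1] + gap_open
            ext = y_row[j - 1] + gap_extend
            y_row[j] = max(open_m, open_x, ext)
            ptr_y[i, j] = [open_m, open_x, ext].index(y_row[j])
    # Traceback.
    i, j = n1, n2
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    path: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = ptr_m[i, j]
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            prev = ptr_x[i, j]
            path.append((i - 1, -1))
            i -= 1
            state = 0 if prev == 0 else (1 if prev == 1 else 2)
        else:
            prev = ptr_y[i, j]
            path.append((-1, j - 1))
            j -= 1
            state = 0 if prev == 0 else (1 if prev == 1 else 2)
    path.reverse()
    return path


def _merge(rows_a: list[SeqRecord], rows_b: list[SeqRecord],
           matrix: SubstitutionMatrix) -> list[SeqRecord]:
    fa = _profile_freqs([r.residues for r in rows_a])
    fb = _profile_freqs([r.residues for r in rows_b])
    path = _profile_nw(fa, fb, matrix.scores, matrix.gap_open,
                       matrix.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for ia, ib in path:
        for k, r in enumerate(rows_a):
            out_a[k] += r.residues[ia] if ia >= 0 else GAP
        for k, r in enumerate(rows_b):
            out_b[k] += r.residues[ib] if ib >= 0 else GAP
    return ([SeqRecord(r.id, s, r.description) for r, s in zip(rows_a, out_a)]
            + [SeqRecord(r.id, s, r.description) for r, s in zip(rows_b, out_b)])


def progressive_align(seqs: list[SeqRecord],
                      matrix: SubstitutionMatrix | None = None,
                      k: int = 3) -> Alignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Guide-tree distances are cosine distances between k-mer count vectors
    (k = 3 by default); profiles are merged leaf-to-root and established
    columns are never reordered.  Row order follows the input.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    matrix = matrix or default_matrix()
    if len(seqs) == 2:
        aln, _ = nw_align(seqs[0], seqs[1], matrix)
        return aln
    vecs = [_kmer_vector(s.residues, k) for s in seqs]
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _cosine_distance(vecs[i], vecs[j])
    Z = linkage(squareform(dm, checks=False), method="average")
    clusters: dict[int, list[SeqRecord]] = {i: [s] for i, s in enumerate(seqs)}
    for step, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        ra, rb = clusters.pop(a), clusters.pop(b)
        if len(ra) == 1 and len(rb) == 1:
            merged, _ = nw_align(ra[0], rb[0], matrix)
            rows = list(merged.rows)
            # keep original descriptions/ids
            rows[0] = SeqRecord(ra[0].id, rows[0].residues, ra[0].description)
            rows[1] = SeqRecord(rb[0].id, rows[1].residues, rb[0].description)
        else:
            rows = _merge(ra, rb, matrix)
        clusters[n + step] = rows
    (rows,) = clusters.values()
    order = {s.id: i for i, s in enumerate(seqs)}
    rows.sort(key=lambda r: order[r.id])
    return Alignment(rows)
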