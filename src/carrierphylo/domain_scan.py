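"""Carrier-domain detection by position-specific scoring.

The harvest stage of the pipeline: given a seed alignment of the
mitochondrial carrier domain, build a log-odds profile (PSSM) and scan each
proteome sequence with a local, affine-gap, profile-to-sequence dynamic
program.  Sequences scoring at or above the profile's bit-score threshold
are declared family members.  An adapter is provided for users who prefer a
genuine HMMER ``--tblout`` hit table produced externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AMINO_ACIDS, GAP, Alignment, SeqRecord, UNKNOWN

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class ProfileError(ValueError):
    pass


@dataclass
class Profile:
    """Per-column log-odds scores (bits) over the 20-residue alphabet."""

    scores: np.ndarray            # (length, 20)
    background: np.ndarray        # (20,)
    gap_open: float = 8.0         # positive costs, subtracted during DP
    gap_extend: float = 1.0
    threshold: float = 0.0        # bits; pass iff score >= threshold

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ProfileError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.scores.argmax(axis=1))


@dataclass
class DomainHit:
    seq_id: str
    score: float
    start: int       # 1-based, inclusive
    end: int         # 1-based, inclusive
    passed: bool

    def as_row(self) -> tuple:
        return (self.seq_id, f"{self.score:.2f}", self.start, self.end,
                int(self.passed))


def build_profile(seed: Alignment, pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  allow_neginf: bool = False,
                  gap_open: float = 8.0, gap_extend: float = 1.0,
                  threshold: float = 0.0) -> Profile:
    """Build a PSSM from a seed alignment.

    Columns where gaps hold the majority are dropped.  Per column,
    ``score(aa) = log2(((count + pc * bg) / (N + pc)) / bg)`` with ``N`` the
    number of counted residues (gaps and ``X`` excluded).  A zero
    pseudocount with unobserved residues yields minus-infinity scores,
    which is an error unless explicitly allowed.
    """
    if pseudocount < 0:
        raise ProfileError("pseudocount must be non-negative")
    bg = (np.full(20, 1 / 20) if background is None
          else np.asarray(background, dtype=float))
    cols = []
    for i in range(seed.n_cols):
        col = seed.column(i)
        gaps = col.count(GAP)
        if gaps * 2 > len(col):
            continue
        counts = np.zeros(20)
        for sym in col:
            if sym in _AA_INDEX:
                counts[_AA_INDEX[sym]] += 1
        n = counts.sum()
        if n == 0:
            continue
        with np.errstate(divide="ignore"):
            freq = (counts + pseudocount * bg) / (n + pseudocount)
            cols.append(np.log2(freq / bg))
    scores = np.array(cols)
    if not allow_neginf and not np.isfinite(scores).all():
        raise ProfileError(
            "zero pseudocount with unobserved residues gives -inf scores; "
            "pass allow_neginf=True to permit them"
        )
    return Profile(scores, bg, gap_open=gap_open, gap_extend=gap_extend,
                   threshold=threshold)


def _encode(residues: str) -> np.ndarray:
    """Map residues to alphabet indices; gaps/'X' to -1 (scored 0)."""
    return np.array([_AA_INDEX.get(c, -1) for c in residues], dtype=int)


def scan_sequence(seq: SeqRecord, profile: Profile) -> DomainHit:
    """Best local alignment of the profile to the sequence.

    Smith–Waterman over the profile's per-column scores with affine gap
    costs; ties broken toward the smallest start coordinate, then the
    smallest end.  The hit interval is 1-based inclusive on the sequence.
    """
    if len(seq.residues) < 10:
        raise ProfileError(f"sequence {seq.id!r} shorter than 10 residues")
    enc = _encode(seq.residues)
    L, n = profile.length, len(enc)
    # Substitution score of profile column i against sequence position j.
    sub = np.zeros((L, n))
    known = enc >= 0
    for i in range(L):
        sub[i, known] = profile.scores[i][enc[known]]

    go, ge = profile.gap_open, profile.gap_extend
    neg = -1e30
    m_prev = np.zeros(n + 1)          # M[i-1, :]
    ix_prev = np.full(n + 1, neg)     # gap in sequence (profile column skipped)
    sm_prev = np.arange(n + 1)        # start coordinate bookkeeping
    sx_prev = np.zeros(n + 1, dtype=int)
    best = (0.0, 0, 0, 0)             # score, start, end, row
    for i in range(1, L + 1):
        m = np.full(n + 1, 0.0)
        sm = np.zeros(n + 1, dtype=int)
        # Ix: vertical gap (consume profile column, no sequence residue).
        ix = np.maximum(m_prev - go, ix_prev - ge)
        sx = np.where(m_prev - go >= ix_prev - ge, sm_prev, sx_prev)
        # Diagonal predecessors: best of M, Ix, Iy at (i-1, j-1), or fresh start.
        diag = np.maximum(m_prev[:-1], ix_prev[:-1])
        sdiag = np.where(m_prev[:-1] >= ix_prev[:-1], sm_prev[:-1], sx_prev[:-1])
        fresh = diag < 0
        sdiag = np.where(fresh, np.arange(n), sdiag)
        diag = np.where(fresh, 0.0, diag)
        cand = diag + sub[i - 1]
        # Iy: horizontal gap within row i (insertion in the sequence).
        # Affine scan: iy[j] = max(m[j-1]-go, iy[j-1]-ge), vectorized as a
        # running maximum in the ge-transformed domain.
        m[1:] = cand
        sm[1:] = sdiag
        j_idx = np.arange(1, n + 1)
        t = np.empty(n + 1)
        t[0] = neg
        t[1:] = m[:-1] - go + ge * j_idx
        run = np.maximum.accumulate(t)
        iy = run - ge * np.concatenate(([0], j_idx))
        # Start bookkeeping for Iy: index of the running maximum.
        src = np.maximum.accumulate(np.where(t >= run, np.arange(n + 1), 0))
        siy = np.concatenate(([0], sm[:-1]))[src]
        better = iy[1:] > m[1:]
        m[1:] = np.where(better, iy[1:], m[1:])
        sm[1:] = np.where(better, siy[1:], sm[1:])
        # Local alignment: clip negatives to zero (restart).
        restart = m < 0
        m[restart] = 0.0
        sm[restart] = np.arange(n + 1)[restart]

        row_best = m.max()
        if row_best > best[0] + 1e-12:
            js = np.flatnonzero(m >= row_best - 1e-12)
            j = min(js, key=lambda jj: (sm[jj], jj))
            best = (row_best, int(sm[j]), int(j), i)
        elif row_best >= best[0] - 1e-12 and best[0] > 0:
            js = np.flatnonzero(m >= row_best - 1e-12)
            j = min(js, key=lambda jj: (sm[jj], jj))
            if (sm[j], j) < (best[1], best[2]):
                best = (best[0], int(sm[j]), int(j), i)
        m_prev, ix_prev, sm_prev, sx_prev = m, ix, sm, sx

    score, start0, end, _ = best
    if end == 0:          # nothing scored above zero
        start0, end = 0, min(1, n)
    return DomainHit(seq.id, float(score), start0 + 1, end,
                     score >= profile.threshold)


def filter_proteome(seqs: list[SeqRecord], profile: Profile) -> list[DomainHit]:
    """Scan a proteome; return passing hits in stable input order.

    Sequences shorter than the scanner's 10-residue minimum cannot contain
    the domain and are silently skipped.
    """
    hits = []
    for s in seqs:
        if len(s.residues) < 10:
            continue
        h = scan_sequence(s, profile)
        if h.passed:
            hits.append(h)
    return hits


def calibrate_threshold(profile: Profile, null_seqs: list[SeqRecord],
                        fpr: float = 1e-3, margin: float = 1.0) -> float:
    """Bit-score threshold from an empirical null score distribution.

    Scores every null (decoy) sequence and returns the ``1 - fpr`` quantile
    (conservative interpolation) plus a safety margin in bits, so that the
    false-positive rate on composition-matched sequences stays at or below
    ``fpr``.  The null should match the length distribution of the
    sequences to be scanned: local-alignment maxima grow with length.
    """
    scores = np.array([scan_sequence(s, profile).score for s in null_seqs])
    return float(np.quantile(scores, 1.0 - fpr, method="higher") + margin)


def composition_null(seqs: list[SeqRecord], n: int, seed: int) -> list[SeqRecord]:
    """Null sequences drawn iid from the pooled residue composition.

    Lengths are resampled from the input length distribution, so the null
    matches the scanned proteome in both composition and length.
    """
    rng = np.random.default_rng(seed)
    pool = "".join(s.ungapped().replace(UNKNOWN, "") for s in seqs)
    comp = np.array([pool.count(a) for a in AMINO_ACIDS], dtype=float)
    comp = comp / comp.sum()
    lengths = np.array([len(s.ungapped()) for s in seqs])
    lengths = lengths[lengths >= 10]
    aa = np.array(list(AMINO_ACIDS))
    out = []
    for k in range(n):
        length = int(lengths[rng.integers(len(lengths))])
        out.append(SeqRecord(f"null_{k}",
                             "".join(aa[rng.choice(20, size=length, p=comp)])))
    return out


def shuffled_null(seqs: list[SeqRecord], n: int, seed: int) -> list[SeqRecord]:
    """Composition-preserving shuffles of the given sequences (decoy null)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        src = seqs[k % len(seqs)]
        res = list(src.ungapped().replace(UNKNOWN, ""))
        rng.shuffle(res)
        if len(res) >= 10:
            out.append(SeqRecord(f"null_{k}", "".join(res)))
    return out


def read_hmmer_tblout(text: str, threshold: float) -> list[DomainHit]:
    """Adapter for HMMER ``--tblout`` whitespace tables.

    Uses the full-sequence bit score (column 6); intervals are not present
    in tblout and are reported as 0.
    """
    hits = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 6:
            raise ProfileError(f"short tblout line: {line!r}")
        score = float(f[5])
        hits.append(DomainHit(f[0], score, 0, 0, score >= threshold))
    return hits
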