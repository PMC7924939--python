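"""Greedy identity clustering of near-redundant sequences.

Removes duplicate entries and transcript variants before tree building,
following the CD-HIT convention: sequences are considered longest-first and
each joins the first established cluster whose representative it matches at
or above the identity threshold, otherwise it founds a new cluster.
Identity is the number of identical aligned residue pairs in an optimal
global alignment divided by the length of the shorter sequence, which is
what lets a transcript variant (an exact prefix or fragment) be absorbed by
its full-length representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import SeqRecord
from .msa import default_matrix, nw_align


@dataclass
class ClusterSet:
    representatives: list[str]
    membership: dict[str, str]        # every input id -> representative id
    identity: dict[str, float]        # member id -> identity to its rep
    threshold: float

    def members(self, rep: str) -> list[str]:
        return [m for m, r in self.membership.items() if r == rep]

    def rows(self):
        for m, r in self.membership.items():
            yield (m, r, f"{self.identity[m]:.4f}")


def pairwise_identity(a: SeqRecord, b: SeqRecord,
                      matrix=None) -> float:
    """Identity fraction between two unaligned sequences.

    Globally aligns the pair, counts identical aligned residue pairs, and
    divides by the shorter sequence length (CD-HIT's denominator).
    Symmetric by construction.
    """
    if not a.residues or not b.residues:
        raise ValueError("empty sequence in identity computation")
    matrix = matrix or default_matrix()
    aln, _ = nw_align(a, b, matrix)
    r1, r2 = aln.rows[0].residues, aln.rows[1].residues
    ident = sum(1 for x, y in zip(r1, r2) if x == y and x != "-")
    return ident / min(len(a.residues), len(b.residues))


def greedy_cluster(seqs: list[SeqRecord], threshold: float = 0.9,
                   matrix=None) -> ClusterSet:
    """CD-HIT-style greedy clustering at the given identity threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    matrix = matrix or default_matrix()
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    by_id = {s.id: s for s in ordered}
    if len(by_id) != len(ordered):
        raise ValueError("duplicate ids in clustering input")
    reps: list[str] = []
    membership: dict[str, str] = {}
    identity: dict[str, float] = {}
    for s in ordered:
        placed = False
        for rep in reps:
            ident = pairwise_identity(s, by_id[rep], matrix)
            if ident >= threshold:
                membership[s.id] = rep
                identity[s.id] = ident
                placed = True
                break
        if not placed:
            reps.append(s.id)
            membership[s.id] = s.id
            identity[s.id] = 1.0
    return ClusterSet(reps, membership, identity, threshold)
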