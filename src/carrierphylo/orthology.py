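"""Clade-based classification of candidate carrier sequences.

Candidates are classified by where they fall in a phylogeny relative to
labeled reference sequences: two anchors (the yeast PIC2 and MIR1
equivalents) and an outgroup of other family members.  A candidate inside
the well-supported clade of anchor A is "A-like", inside anchor B's clade
"B-like"; candidates that join the smallest clade containing both anchors
without entering either subclade are "other family"; everything else is
outside the subfamily altogether.

The screen runs in two stages, as in the underlying study design: a fast
per-taxon neighbor-joining pass retains plausible subfamily members, and a
pooled tree over all retained candidates gives the final labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Alignment, PhyloTree, SeqRecord, TreeNode
from .msa import SubstitutionMatrix, progressive_align
from .phylo import nj_tree, poisson_distance

A_LIKE = "A_like"
B_LIKE = "B_like"
OTHER_FAMILY = "other_family"
NON_FAMILY = "non_family"


class OrthologyError(ValueError):
    pass


@dataclass
class ReferenceSet:
    """Labeled references: one anchor per paralog class plus outgroups."""

    anchor_a: SeqRecord
    anchor_b: SeqRecord
    outgroup: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.outgroup:
            raise OrthologyError("reference set needs at least one outgroup")

    def records(self) -> list[SeqRecord]:
        return [self.anchor_a, self.anchor_b] + list(self.outgroup)

    def outgroup_ids(self) -> list[str]:
        return [r.id for r in self.outgroup]

    @classmethod
    def from_records(cls, records: list[SeqRecord]) -> "ReferenceSet":
        """Build from FASTA records carrying ``role=...`` header tags."""
        a = b = None
        out = []
        for r in records:
            tags = dict(kv.split("=", 1) for kv in r.description.split()
                        if "=" in kv)
            role = tags.get("role", "")
            if role == "anchor_A":
                if a is not None:
                    raise OrthologyError("multiple anchor_A records")
                a = r
            elif role == "anchor_B":
                if b is not None:
                    raise OrthologyError("multiple anchor_B records")
                b = r
            elif role == "outgroup":
                out.append(r)
        if a is None or b is None:
            raise OrthologyError("reference FASTA must tag one anchor_A "
                                 "and one anchor_B")
        return cls(a, b, out)


@dataclass
class CladeAssignment:
    labels: dict[str, str]                   # candidate id -> label
    support: dict[str, float | None]         # defining-node support per call
    taxon: dict[str, str] = field(default_factory=dict)

    def of(self, label: str) -> list[str]:
        return [c for c, l in self.labels.items() if l == label]

    def rows(self):
        for cid, lab in self.labels.items():
            sup = self.support.get(cid)
            yield (cid, self.taxon.get(cid, ""), lab,
                   "" if sup is None else f"{sup:.1f}")


def root_at_outgroup(tree: PhyloTree, outgroup_ids: list[str]) -> PhyloTree:
    """Root on the branch separating the outgroup from everything else.

    If the outgroup is not monophyletic in the unrooted tree, the root goes
    on the branch whose bipartition best agrees with the outgroup/ingroup
    split (fewest misplaced leaves).
    """
    leaves = set(tree.leaf_names())
    og = set(outgroup_ids)
    missing = og - leaves
    if missing:
        raise OrthologyError(f"outgroup ids not in tree: {sorted(missing)}")
    if not og or og == leaves:
        raise OrthologyError("outgroup must be a proper non-empty leaf subset")
    best: tuple[int, int, TreeNode] | None = None
    order = 0
    for node in tree.postorder():
        if node.parent is None:
            continue
        side = set(node.leaf_names())
        # disagreement if rooted here with the outgroup on 'side'
        mis = min(len(og - side) + len((side - og)),
                  len(og & side) + len(leaves - side - og))
        order += 1
        if best is None or mis < best[0]:
            best = (mis, order, node)
    return tree.rooted_at_edge(best[2])


def _supported(node: TreeNode, support_min: float) -> bool:
    """Nodes without a recorded support (no bootstrap run) count as supported."""
    return node.support is None or node.support >= support_min


def assign_clades(tree: PhyloTree, refs: ReferenceSet,
                  support_min: float = 75.0) -> CladeAssignment:
    """Label every non-reference leaf of a rooted tree.

    The A clade is the largest clade containing anchor A — but neither
    anchor B nor any outgroup leaf — whose defining node meets the support
    threshold (the largest-clade rule keeps lineage-specific duplicates
    nested deep inside the clade).  Same for B.  Candidates inside the
    smallest clade containing both anchors but in neither subclade are
    "other family"; the rest are outside the subfamily.
    """
    ref_ids = {refs.anchor_a.id, refs.anchor_b.id, *refs.outgroup_ids()}
    for rid in (refs.anchor_a.id, refs.anchor_b.id):
        tree.find_leaf(rid)  # raises if absent
    forbidden_a = {refs.anchor_b.id, *refs.outgroup_ids()}
    forbidden_b = {refs.anchor_a.id, *refs.outgroup_ids()}

    def clade_of(anchor_id: str, forbidden: set[str]) -> TreeNode:
        node = tree.find_leaf(anchor_id)
        chosen = node
        while node.parent is not None:
            node = node.parent
            names = set(node.leaf_names())
            if names & forbidden:
                break
            if _supported(node, support_min):
                chosen = node
        return chosen

    clade_a = clade_of(refs.anchor_a.id, forbidden_a)
    clade_b = clade_of(refs.anchor_b.id, forbidden_b)
    set_a = set(clade_a.leaf_names())
    set_b = set(clade_b.leaf_names())
    assert not (set_a & set_b), "anchor clades must be disjoint"
    assert not (set_a | set_b) & set(refs.outgroup_ids()), \
        "anchor clades must exclude the outgroup"
    superclade = set(tree.mrca([refs.anchor_a.id,
                                refs.anchor_b.id]).leaf_names())

    labels: dict[str, str] = {}
    support: dict[str, float | None] = {}
    for leaf in tree.leaf_names():
        if leaf in ref_ids:
            continue
        if leaf in set_a:
            labels[leaf] = A_LIKE
            support[leaf] = clade_a.support
        elif leaf in set_b:
            labels[leaf] = B_LIKE
            support[leaf] = clade_b.support
        elif leaf in superclade:
            labels[leaf] = OTHER_FAMILY
            support[leaf] = None
        else:
            labels[leaf] = NON_FAMILY
            support[leaf] = None
    return CladeAssignment(labels, support)


def screen_candidates(hits_by_taxon: dict[str, list[SeqRecord]],
                      refs: ReferenceSet,
                      support_min: float = 75.0,
                      matrix: SubstitutionMatrix | None = None,
                      logger=None) -> dict[str, CladeAssignment]:
    """Stage-1 per-taxon screen.

    For each taxon, the domain-passing sequences are aligned together with
    the references, an NJ tree is built from Poisson distances, rooted at
    the outgroup, and clade labels assigned.  Sequences labeled A-like,
    B-like or other-family are the taxon's candidates for the pooled
    stage-2 classification.
    """
    out: dict[str, CladeAssignment] = {}
    for taxon in sorted(hits_by_taxon):
        seqs = hits_by_taxon[taxon]
        if not seqs:
            if logger is not None:
                logger.info("taxon %s: no domain hits, skipping", taxon)
            out[taxon] = CladeAssignment({}, {})
            continue
        aln = progressive_align(list(seqs) + refs.records(), matrix)
        tree = root_at_outgroup(nj_tree(poisson_distance(aln)),
                                refs.outgroup_ids())
        assignment = assign_clades(tree, refs, support_min)
        assignment.taxon = {cid: taxon for cid in assignment.labels}
        out[taxon] = assignment
    return out


def retained_candidates(screens: dict[str, CladeAssignment]
                        ) -> dict[str, list[str]]:
    """Candidates kept for stage 2: anything placed inside the subfamily."""
    keep = {A_LIKE, B_LIKE, OTHER_FAMILY}
    return {taxon: [c for c, l in a.labels.items() if l in keep]
            for taxon, a in screens.items()}
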