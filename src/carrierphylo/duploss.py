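"""Gene duplication and loss inference on a fixed species tree.

Per-taxon paralog-class counts (how many A-like, B-like and other
subfamily members each genome retains) are reconciled against the species
tree by exact integer-state parsimony: ancestral copy numbers over
{0..c_max} are chosen by Sankoff dynamic programming under asymmetric
gain/loss costs, and every branch where the reconstructed count changes is
reported as that many duplications (increase) or losses (decrease).

Defaults make gains twice as expensive as losses (w_gain=2, w_loss=1),
which biases reconstructions toward single ancient origins followed by
lineage-specific losses — a Dollo-like prior appropriate for a subfamily
present across the major eukaryotic supergroups.  Ties between equally
cheap ancestral counts resolve toward the larger count, again pushing
gains rootward.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PhyloTree, TreeNode
from .orthology import A_LIKE, B_LIKE, OTHER_FAMILY, CladeAssignment

CLASSES = (A_LIKE, B_LIKE, OTHER_FAMILY)


class DupLossError(ValueError):
    pass


@dataclass
class CopyNumberMatrix:
    """Taxa x paralog-class integer counts, optional supergroup labels."""

    counts: pd.DataFrame                       # index taxa, columns CLASSES
    supergroup: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DupLossError("copy numbers must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class BranchEvents:
    branch: str           # child-node id of the species-tree branch
    cls: str
    duplications: int
    losses: int


@dataclass
class EventSet:
    events: list[BranchEvents]
    ancestral: dict[str, dict[str, int]]       # node id -> class -> count
    total_cost: float

    def per_branch(self, branch: str, cls: str) -> tuple[int, int]:
        for e in self.events:
            if e.branch == branch and e.cls == cls:
                return e.duplications, e.losses
        return 0, 0

    def rows(self):
        for e in self.events:
            yield (e.branch, e.cls, e.duplications, e.losses)


def copy_number_matrix(assignments: CladeAssignment | list[CladeAssignment],
                       taxa: list[str],
                       supergroup: dict[str, str] | None = None
                       ) -> CopyNumberMatrix:
    """Count clade labels per (taxon, class); unseen taxa get zero rows."""
    if isinstance(assignments, CladeAssignment):
        assignments = [assignments]
    counts = pd.DataFrame(0, index=list(taxa), columns=list(CLASSES))
    for a in assignments:
        for cid, label in a.labels.items():
            if label not in CLASSES:
                continue
            taxon = a.taxon.get(cid)
            if taxon is None:
                raise DupLossError(f"assignment {cid!r} has no taxon of origin")
            if taxon not in counts.index:
                raise DupLossError(f"taxon {taxon!r} not in taxa list")
            counts.loc[taxon, label] += 1
    return CopyNumberMatrix(counts, dict(supergroup or {}))


def _node_ids(tree: PhyloTree) -> dict[int, str]:
    """Stable ids: leaf names, and N1.. for internal nodes in preorder."""
    ids: dict[int, str] = {}
    k = 0
    for node in tree.preorder():
        if node.is_leaf:
            ids[id(node)] = node.name
        elif node.name:
            ids[id(node)] = node.name
        else:
            k += 1
            ids[id(node)] = f"N{k}"
    return ids


def _transition_cost(parent: int, child: int, w_gain: float,
                     w_loss: float) -> float:
    return w_gain * max(0, child - parent) + w_loss * max(0, parent - child)


def sankoff_events(species_tree: PhyloTree, counts: CopyNumberMatrix,
                   w_gain: float = 2.0, w_loss: float = 1.0,
                   c_max: int = 4,
                   root_state: dict[str, int] | None = None) -> EventSet:
    """Minimum-cost ancestral copy numbers and the implied branch events.

    Exact Sankoff DP over states {0..c_max} per paralog class.  Ties in
    the backtrace prefer the larger ancestral count.

    ``root_state`` optionally pins the root copy number per class.  For
    the focal paralog classes the founding duplication predates the
    species-tree root, so each class starts at exactly one ancestral
    copy; without the pin, a free root absorbs deep duplications (a
    2-copy root plus losses is cheaper than a gain whenever
    w_gain > w_loss), misdating them.  A pinned class that is absent
    from every leaf is reconstructed as all-zero without the pin.
    """
    leaves = set(species_tree.leaf_names())
    if leaves != set(counts.taxa):
        raise DupLossError(
            f"species-tree leaves and count-matrix taxa differ: "
            f"{sorted(leaves ^ set(counts.taxa))}"
        )
    ids = _node_ids(species_tree)
    states = np.arange(c_max + 1)
    trans = np.array([[_transition_cost(p, c, w_gain, w_loss)
                       for c in states] for p in states])
    ancestral: dict[str, dict[str, int]] = {ids[id(n)]: {}
                                            for n in species_tree.preorder()}
    events: list[BranchEvents] = []
    total = 0.0
    for cls in CLASSES:
        cost: dict[int, np.ndarray] = {}
        for node in species_tree.postorder():
            if node.is_leaf:
                observed = int(counts.counts.loc[node.name, cls])
                if observed > c_max:
                    raise DupLossError(
                        f"leaf count {observed} exceeds c_max={c_max} "
                        f"for {node.name!r}/{cls}"
                    )
                c = np.full(c_max + 1, np.inf)
                c[observed] = 0.0
            else:
                c = np.zeros(c_max + 1)
                for child in node.children:
                    c += (trans + cost[id(child)][None, :]).min(axis=1)
            cost[id(node)] = c
        root_cost = cost[id(species_tree.root)].copy()
        pinned = (root_state or {}).get(cls)
        if pinned is not None and counts.counts[cls].sum() > 0:
            keep = root_cost[pinned]
            root_cost[:] = np.inf
            root_cost[pinned] = keep
        best = float(root_cost.min())
        total += best
        # tie-break toward the larger ancestral count
        chosen = int(max(np.flatnonzero(root_cost == best)))
        assign: dict[int, int] = {id(species_tree.root): chosen}
        for node in species_tree.preorder():
            s = assign[id(node)]
            ancestral[ids[id(node)]][cls] = s
            for child in node.children:
                opts = trans[s] + cost[id(child)]
                mn = opts.min()
                child_state = int(max(np.flatnonzero(opts == mn)))
                assign[id(child)] = child_state
                if child_state > s:
                    events.append(BranchEvents(ids[id(child)], cls,
                                               child_state - s, 0))
                elif child_state < s:
                    events.append(BranchEvents(ids[id(child)], cls, 0,
                                               s - child_state))
    return EventSet(events, ancestral, total)


def brute_force_min_cost(species_tree: PhyloTree, leaf_counts: dict[str, int],
                         w_gain: float, w_loss: float, c_max: int) -> float:
    """Oracle: enumerate every ancestral labeling (tiny trees only)."""
    internals = [n for n in species_tree.postorder() if not n.is_leaf]
    best = np.inf
    for assign in itertools.product(range(c_max + 1), repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assign)}
        for leaf in species_tree.leaves():
            state[id(leaf)] = leaf_counts[leaf.name]
        cost = 0.0
        for node in species_tree.postorder():
            if node.parent is not None:
                cost += _transition_cost(state[id(node.parent)],
                                         state[id(node)], w_gain, w_loss)
        best = min(best, cost)
    return float(best)


def supergroup_means(counts: CopyNumberMatrix,
                     grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Arithmetic mean copy number per (supergroup, class)."""
    grouping = grouping or counts.supergroup
    missing = [t for t in counts.taxa if t not in grouping]
    if missing:
        raise DupLossError(f"taxa without supergroup label: {missing}")
    df = counts.counts.copy()
    df["supergroup"] = [grouping[t] for t in counts.taxa]
    return df.groupby("supergroup").mean().astype(float)
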