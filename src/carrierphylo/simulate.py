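"""Synthetic data with known truth for every pipeline stage.

The generator emulates the evolutionary structure the pipeline is built to
recover: a gene subfamily born from a single ancient duplication (classes
A and B, standing in for PIC2-like and MIR1-like), evolving on a known
species tree with stochastic duplication and loss; additional deep
"other family" paralog lineages that share the domain but predate the
founding duplication (the rest of the carrier family); sequence evolution
with planted site classes — family-invariant sites, clade-specific sites
frozen within one clade after the duplication, and neutral sites — plus
optional indels; and composition-shuffled decoy proteins that fill out
each proteome for the domain screen.

Defaults define the reference study conditions used throughout the test
suite: 12 taxa, duplication and loss rates 0.05 per unit branch length,
300 sites.  All randomness flows from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, GAP, Alignment, PhyloTree, SeqRecord, TreeNode
from .phylo import SubstModel, lg_model, poisson_model

SITE_INVARIANT = "invariant"
SITE_A = "A_specific"
SITE_B = "B_specific"
SITE_NEUTRAL = "neutral"
SITE_INDEL = "indel"


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings; defaults are the reference study conditions."""

    seed: int
    n_taxa: int = 12
    species_newick: str | None = None       # supply a tree, or None for random
    dup_rate: float = 0.05                  # per unit branch length per lineage
    loss_rate: float = 0.05
    seq_length: int = 300
    frac_invariant: float = 0.15
    frac_a_specific: float = 0.10
    frac_b_specific: float = 0.10
    neutral_rate: float = 1.5               # keeps the family-wide mean rate near 1
    specific_rate: float = 3.0              # clade-specific sites, outside the frozen clade
    model: str = "poisson"                  # "poisson" | "lg"
    branch_length_range: tuple[float, float] = (0.1, 0.3)
    stem_length: float = 0.4                # founding duplication to each clade crown
    subfamily_stem: float = 0.3             # family root to the founding duplication
    n_other_families: int = 3
    other_stem: float = 1.2                 # family root to each other-family crown
    indel_rate: float = 0.02                # events per unit branch length
    indel_mean_len: int = 3
    plant_insertion_clade: str | None = None  # force one insertion on a clade stem
    plant_insertion_len: int = 3
    decoys_per_taxon: int = 20
    decoy_length: tuple[int, int] = (250, 450)

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise SimError("duplication and loss rates must be non-negative")
        total = self.frac_invariant + self.frac_a_specific + self.frac_b_specific
        if total > 1:
            raise SimError("site-class fractions exceed 1")


@dataclass
class GeneEvent:
    cls: str            # "A" or "B"
    branch: str         # species-tree child-node name
    kind: str           # "dup" or "loss"


@dataclass
class SimTruth:
    species_tree: PhyloTree
    gene_tree: PhyloTree                     # whole family, one tree
    events: list[GeneEvent]
    flow: dict[tuple[str, str], int]         # (species node, class) -> surviving lineages
    clade_of: dict[str, str]                 # gene leaf id -> "A"/"B"/"O<k>"
    alignment: Alignment | None = None       # true alignment (indel gaps included)
    site_labels: list[str] = field(default_factory=list)
    sequences: dict[str, SeqRecord] = field(default_factory=dict)  # unaligned
    proteomes: dict[str, list[SeqRecord]] = field(default_factory=dict)
    decoy_ids: set[str] = field(default_factory=set)

    def survivor_counts(self) -> pd.DataFrame:
        """Per-taxon copy counts: A, B, and all other families pooled."""
        taxa = self.species_tree.leaf_names()
        df = pd.DataFrame(0, index=taxa, columns=["A", "B", "other"])
        for leaf, cls in self.clade_of.items():
            taxon = leaf.split("|")[0]
            key = cls if cls in ("A", "B") else "other"
            df.loc[taxon, key] += 1
        return df

    def observable_branch_changes(self) -> list[tuple[str, str, int]]:
        """Net surviving-lineage change per species branch and class.

        Entries are (branch child-node name, class, delta); only branches
        where the number of surviving gene lineages changes appear.  These
        are the events an observer of present-day copy numbers could ever
        place, and the yardstick for reconciliation recall.
        """
        out = []
        for node in self.species_tree.preorder():
            for child in node.children:
                for cls in ("A", "B"):
                    delta = (self.flow.get((child.name or "", cls), 0)
                             - self.flow.get((node.name or "", cls), 0))
                    if delta:
                        out.append((child.name, cls, delta))
        return out


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def random_species_tree(n_taxa: int, rng: np.random.Generator,
                        length_range: tuple[float, float] = (0.1, 0.3)
                        ) -> PhyloTree:
    """Random rooted binary tree by sequential edge attachment."""
    if n_taxa < 2:
        raise SimError("need at least 2 taxa")
    names = [f"T{i + 1:02d}" for i in range(n_taxa)]
    root = TreeNode()
    root.add(TreeNode(name=names[0]))
    root.add(TreeNode(name=names[1]))
    for name in names[2:]:
        edges = [n for n in root.postorder() if n.parent is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        idx = parent.children.index(target)
        mid = TreeNode()
        mid.add(target)
        mid.add(TreeNode(name=name))
        parent.children[idx] = mid
        mid.parent = parent
    lo, hi = length_range
    k = 0
    for node in root.preorder():
        if node.parent is not None:
            node.length = float(rng.uniform(lo, hi))
        if not node.is_leaf and node.name is None:
            k += 1
            node.name = f"N{k}"
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Gene family birth–death
# ---------------------------------------------------------------------------

def _evolve_branch(entering: list[TreeNode], t: float, cls: str,
                   branch_name: str, cfg: SimConfig,
                   rng: np.random.Generator,
                   events: list[GeneEvent]) -> list[TreeNode]:
    """Birth–death along one species branch; returns lineages at the bottom."""
    lam, mu = cfg.dup_rate, cfg.loss_rate
    total = lam + mu
    survivors: list[TreeNode] = []
    queue = [(g, t) for g in entering]
    while queue:
        node, remaining = queue.pop()
        while True:
            if total == 0:
                node.length += remaining
                survivors.append(node)
                break
            wait = rng.exponential(1.0 / total)
            if wait >= remaining:
                node.length += remaining
                survivors.append(node)
                break
            node.length += wait
            remaining -= wait
            if rng.random() < lam / total:
                events.append(GeneEvent(cls, branch_name, "dup"))
                left = node.add(TreeNode(length=0.0))
                right = node.add(TreeNode(length=0.0))
                queue.append((right, remaining))
                node = left
            else:
                events.append(GeneEvent(cls, branch_name, "loss"))
                node.name = "__dead__"
                break
    return survivors


def _descend(species_node: TreeNode, entering: list[TreeNode], cls: str,
             cfg: SimConfig, rng: np.random.Generator,
             events: list[GeneEvent], counters: dict[str, int],
             with_bd: bool,
             presence: dict[tuple[str, str], list[TreeNode]] | None = None
             ) -> None:
    """Recursive speciation: carry each lineage into every child branch."""
    if presence is not None:
        presence.setdefault((species_node.name, cls), []).extend(entering)
    if species_node.is_leaf:
        for g in entering:
            counters[species_node.name] = counters.get(species_node.name, 0) + 1
            g.name = f"{species_node.name}|{cls}{counters[species_node.name]}"
        return
    for child in species_node.children:
        branch_entering = []
        for g in entering:
            sub = g.add(TreeNode(length=0.0))
            branch_entering.append(sub)
        if with_bd:
            survivors = _evolve_branch(branch_entering, child.length or 0.0,
                                       cls, child.name, cfg, rng, events)
        else:
            for g in branch_entering:
                g.length = child.length or 0.0
            survivors = branch_entering
        _descend(child, survivors, cls, cfg, rng, events, counters, with_bd,
                 presence)


def _prune_dead(node: TreeNode) -> bool:
    """Drop extinct lineages; returns True if the subtree survives."""
    if node.is_leaf:
        return node.name is not None and node.name != "__dead__"
    node.children = [c for c in node.children if _prune_dead(c)]
    for c in node.children:
        c.parent = node
    return bool(node.children)


def _collapse_unary(node: TreeNode) -> TreeNode:
    while len(node.children) == 1 and node.name is None:
        child = node.children[0]
        child.length = (child.length or 0.0) + (node.length or 0.0)
        child.parent = node.parent
        node = child
    node.children = [_collapse_unary(c) for c in node.children]
    for c in node.children:
        c.parent = node
    return node


def sim_gene_family(cfg: SimConfig) -> SimTruth:
    """Gene trees and true events for the whole carrier family.

    The founding A/B duplication sits on the family stem, so both classes
    exist ancestrally; other-family lineages branch off deeper and descend
    the species tree one copy per taxon.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.species_newick is not None:
        from .io_formats import parse_newick
        species = parse_newick(cfg.species_newick)
    else:
        species = random_species_tree(cfg.n_taxa, rng,
                                      cfg.branch_length_range)

    family_root = TreeNode(length=0.0)
    events: list[GeneEvent] = []
    presence: dict[tuple[str, str], list[TreeNode]] = {}

    # Other families: deep paralog lineages, one copy per taxon.
    for k in range(cfg.n_other_families):
        anc = family_root.add(TreeNode(length=cfg.other_stem))
        _descend(species.root, [anc], f"O{k + 1}", cfg, rng, events, {},
                 with_bd=False)

    # The focal subfamily: stem, founding duplication, two clades with BD.
    sub_root = family_root.add(TreeNode(length=cfg.subfamily_stem))
    for cls in ("A", "B"):
        anc = sub_root.add(TreeNode(length=cfg.stem_length))
        _descend(species.root, [anc], cls, cfg, rng, events, {},
                 with_bd=True, presence=presence)

    # Surviving-lineage flow, recorded before pruning: a lineage counts at
    # a species node iff it was alive there and has extant descendants.
    survives: dict[int, bool] = {}

    def mark(n: TreeNode) -> bool:
        if n.is_leaf:
            ok = n.name is not None and n.name != "__dead__"
        else:
            ok = any([mark(c) for c in n.children])
        survives[id(n)] = ok
        return ok

    mark(family_root)
    flow = {key: sum(1 for g in genes if survives[id(g)])
            for key, genes in presence.items()}

    _prune_dead(family_root)
    if not family_root.children:
        raise SimError("entire family went extinct; raise rates or reseed")
    root = _collapse_unary(family_root)
    root.parent = None
    gene_tree = PhyloTree(root)

    clade_of = {}
    for leaf in gene_tree.leaf_names():
        cls = leaf.split("|")[1]
        base = cls.rstrip("0123456789")
        clade_of[leaf] = base

    return SimTruth(species, gene_tree, events, flow, clade_of)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _site_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.seq_length
    n_inv = int(round(cfg.frac_invariant * n))
    n_a = int(round(cfg.frac_a_specific * n))
    n_b = int(round(cfg.frac_b_specific * n))
    labels = ([SITE_INVARIANT] * n_inv + [SITE_A] * n_a + [SITE_B] * n_b
              + [SITE_NEUTRAL] * (n - n_inv - n_a - n_b))
    labels = np.array(labels)
    rng.shuffle(labels)
    return labels


def _clade_members(gene_tree: PhyloTree, clade_of: dict[str, str],
                   cls: str) -> TreeNode | None:
    """The gene-tree node spanning exactly the class (its crown + stem)."""
    members = {l for l, c in clade_of.items() if c == cls}
    if not members:
        return None
    node = gene_tree.mrca(members)
    # include the stem: the clade is "frozen after the founding duplication",
    # so the frozen region is the whole subtree hanging off the duplication
    while (node.parent is not None
           and {l for l in node.parent.leaf_names()} <= members):
        node = node.parent
    return node


def sim_sequences(truth: SimTruth, cfg: SimConfig) -> SimTruth:
    """Evolve sequences along the gene tree; fills the truth in place.

    Root residues are drawn from the model's stationary frequencies.
    Family-invariant sites never substitute; clade-specific sites evolve at
    the elevated ``specific_rate`` everywhere except inside their frozen
    clade (the subtree of the founding duplication's daughter, stem
    included) where their rate is zero; neutral sites evolve at
    ``neutral_rate``.  Indels are applied afterwards and exist as gap
    columns in the true alignment and as missing residues in the unaligned
    view.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    model = poisson_model() if cfg.model == "poisson" else lg_model()
    labels = _site_classes(cfg, rng)
    n = cfg.seq_length

    frozen_node = {
        SITE_A: _clade_members(truth.gene_tree, truth.clade_of, "A"),
        SITE_B: _clade_members(truth.gene_tree, truth.clade_of, "B"),
    }
    in_frozen: dict[str, set[int]] = {SITE_A: set(), SITE_B: set()}
    for key, node in frozen_node.items():
        if node is not None:
            in_frozen[key] = {id(x) for x in node.preorder()}

    pi = model.frequencies
    root_seq = rng.choice(20, size=n, p=pi)
    seqs: dict[int, np.ndarray] = {id(truth.gene_tree.root): root_seq}
    leaf_rows: list[tuple[str, np.ndarray]] = []

    rate_of = np.where(labels == SITE_INVARIANT, 0.0,
                       np.where(labels == SITE_NEUTRAL, cfg.neutral_rate,
                                cfg.specific_rate))

    for node in truth.gene_tree.preorder():
        if node.parent is None:
            if node.is_leaf:
                leaf_rows.append((node.name, seqs[id(node)]))
            continue
        parent_seq = seqs[id(node.parent)]
        t = node.length or 0.0
        rates = rate_of.copy()
        for key in (SITE_A, SITE_B):
            if id(node) in in_frozen[key]:
                rates[labels == key] = 0.0
        child_seq = parent_seq.copy()
        if t > 0:
            for r in np.unique(rates):
                if r == 0:
                    continue
                sites = np.flatnonzero(rates == r)
                p = model.transition(t, float(r))
                cum = np.cumsum(p, axis=1)
                u = rng.random(len(sites))
                rows = cum[parent_seq[sites]]
                child_seq[sites] = (u[:, None] > rows).sum(axis=1).clip(0, 19)
        seqs[id(node)] = child_seq
        if node.is_leaf:
            leaf_rows.append((node.name, child_seq))

    aa = np.array(list(AMINO_ACIDS))
    columns = [list(aa[np.array([s[i] for _, s in leaf_rows])])
               for i in range(n)]
    site_labels = list(labels)
    leaf_ids = [name for name, _ in leaf_rows]

    _apply_indels(truth, cfg, rng, columns, site_labels, leaf_ids)

    rows = []
    for i, name in enumerate(leaf_ids):
        residues = "".join(col[i] for col in columns)
        rows.append(SeqRecord(name, residues))
    truth.alignment = Alignment(rows)
    truth.site_labels = site_labels
    truth.sequences = {r.id: SeqRecord(r.id, r.ungapped()) for r in rows}
    return truth


def _apply_indels(truth: SimTruth, cfg: SimConfig, rng: np.random.Generator,
                  columns: list[list[str]], site_labels: list[str],
                  leaf_ids: list[str]) -> None:
    leaf_index = {name: i for i, name in enumerate(leaf_ids)}
    pi = (poisson_model() if cfg.model == "poisson" else lg_model()).frequencies
    aa = np.array(list(AMINO_ACIDS))

    branch_events: list[tuple[TreeNode, str, int]] = []
    if cfg.indel_rate > 0:
        for node in truth.gene_tree.preorder():
            if node.parent is None or not node.length:
                continue
            for _ in range(rng.poisson(cfg.indel_rate * node.length)):
                kind = "ins" if rng.random() < 0.5 else "del"
                length = int(rng.geometric(1.0 / cfg.indel_mean_len))
                branch_events.append((node, kind, length))
    if cfg.plant_insertion_clade:
        node = _clade_members(truth.gene_tree, truth.clade_of,
                              cfg.plant_insertion_clade)
        if node is not None:
            branch_events.append((node, "ins", cfg.plant_insertion_len))

    for node, kind, length in branch_events:
        members = [leaf_index[l] for l in node.leaf_names()
                   if l in leaf_index]
        if not members or len(members) == len(leaf_ids):
            continue
        ncols = len(columns)
        if kind == "del":
            if ncols <= length:
                continue
            start = int(rng.integers(0, ncols - length + 1))
            for c in range(start, start + length):
                for m in members:
                    columns[c][m] = GAP
        else:
            start = int(rng.integers(0, ncols + 1))
            segment = aa[rng.choice(20, size=length, p=pi)]
            for off in range(length):
                col = [GAP] * len(leaf_ids)
                for m in members:
                    col[m] = segment[off]
                columns.insert(start + off, col)
                site_labels.insert(start + off, SITE_INDEL)


# ---------------------------------------------------------------------------
# Proteomes with decoys
# ---------------------------------------------------------------------------

def sim_proteome(truth: SimTruth, cfg: SimConfig) -> SimTruth:
    """Append composition-matched decoys to each taxon's family sequences."""
    rng = np.random.default_rng(cfg.seed + 2)
    all_res = "".join(s.residues for s in truth.sequences.values())
    comp = np.array([all_res.count(a) for a in AMINO_ACIDS], dtype=float)
    comp = comp / comp.sum()
    aa = np.array(list(AMINO_ACIDS))
    lo, hi = cfg.decoy_length
    proteomes: dict[str, list[SeqRecord]] = {}
    decoy_ids: set[str] = set()
    for taxon in truth.species_tree.leaf_names():
        members = [truth.sequences[l] for l in sorted(truth.sequences)
                   if l.split("|")[0] == taxon]
        decoys = []
        for i in range(cfg.decoys_per_taxon):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(aa[rng.choice(20, size=length, p=comp)])
            did = f"{taxon}|decoy{i + 1}"
            decoys.append(SeqRecord(did, seq))
            decoy_ids.add(did)
        proteomes[taxon] = members + decoys
    truth.proteomes = proteomes
    truth.decoy_ids = decoy_ids
    return truth


def simulate_dataset(cfg: SimConfig) -> SimTruth:
    """Full generator: family, sequences, proteomes — with all truth."""
    truth = sim_gene_family(cfg)
    sim_sequences(truth, cfg)
    sim_proteome(truth, cfg)
    return truth
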