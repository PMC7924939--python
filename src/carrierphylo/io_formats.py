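"""Core containers and readers/writers for the pipeline's file formats.

Four kinds of data move between stages: protein sequences (FASTA, plain or
aligned), phylogenetic trees (Newick with optional support values on internal
nodes), structure coordinates (a minimal fixed-column PDB ATOM subset), and
tab-separated result tables.  Everything downstream — the domain scan, the
aligners, the tree builders, the conservation profiler — operates on the
containers defined here.

Parsing of FASTA delegates to :mod:`Bio.SeqIO`, and Newick to
:mod:`Bio.Phylo`, with a thin conversion into the package's own light-weight
types.  The PDB reader handles only ``ATOM``/``HETATM`` records and reports
malformed lines by number.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import Phylo, SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"

_VALID_UNALIGNED = set(AMINO_ACIDS + UNKNOWN)
_VALID_ALIGNED = _VALID_UNALIGNED | {GAP}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Sequences and alignments
# ---------------------------------------------------------------------------

@dataclass
class SeqRecord:
    """A named protein sequence.

    ``residues`` uses the 20-letter amino-acid alphabet plus ``X`` for an
    unknown residue; the gap symbol ``-`` is legal only inside alignments.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class Alignment:
    """Equal-length rows of :class:`SeqRecord` with column access."""

    def __init__(self, rows: Sequence[SeqRecord]):
        rows = list(rows)
        if not rows:
            raise FormatError("alignment with no rows")
        n = len(rows[0].residues)
        for r in rows:
            if len(r.residues) != n:
                raise FormatError(
                    f"alignment rows differ in length: {rows[0].id!r} has {n}, "
                    f"{r.id!r} has {len(r.residues)}"
                )
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate row ids in alignment")
        self.rows = rows
        self.n_cols = n

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.rows)

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, rid: str) -> SeqRecord:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def column(self, i: int) -> str:
        """Residues of column ``i`` (0-based), top to bottom."""
        return "".join(r.residues[i] for r in self.rows)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        return Alignment([r for r in self.rows if r.id in keep])

    def drop_allgap_columns(self) -> "Alignment":
        cols = [i for i in range(self.n_cols)
                if any(r.residues[i] != GAP for r in self.rows)]
        return Alignment([
            SeqRecord(r.id, "".join(r.residues[i] for i in cols), r.description)
            for r in self.rows
        ])


def parse_fasta(text: str, aligned: bool = False) -> list[SeqRecord]:
    """Parse FASTA text into records, preserving input order.

    Multi-line sequences are concatenated.  Duplicate ids, sequence data
    before the first header, and empty sequences are errors.  Residues are
    upper-cased; symbols outside the amino-acid alphabet (plus ``X``, and
    ``-`` when ``aligned``) are rejected.
    """
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FormatError("sequence data before first FASTA header")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    valid = _VALID_ALIGNED if aligned else _VALID_UNALIGNED
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        bad = set(seq) - valid
        if bad:
            raise FormatError(
                f"invalid residue symbol(s) {sorted(bad)} in {rec.id!r}"
            )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[SeqRecord], width: int = 60) -> str:
    out: list[str] = []
    for r in records:
        header = f">{r.id}" + (f" {r.description}" if r.description else "")
        out.append(header)
        for i in range(0, len(r.residues), width):
            out.append(r.residues[i:i + width])
    return "\n".join(out) + "\n"


def read_fasta(path: str, aligned: bool = False) -> list[SeqRecord]:
    with open(path) as fh:
        return parse_fasta(fh.read(), aligned=aligned)


def read_alignment(path: str) -> Alignment:
    return Alignment(read_fasta(path, aligned=True))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """One node of a phylogeny; leaves carry names, internal nodes supports."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


class PhyloTree:
    """A rooted container for a (possibly conceptually unrooted) phylogeny.

    An unrooted tree is stored rooted at an arbitrary internal node with
    three or more children.  Branch lengths are substitutions per site and
    must be non-negative; supports live on internal nodes as percentages.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = root.leaf_names()
        if any(n is None for n in names):
            raise FormatError("tree has unnamed leaves")
        if len(set(names)) != len(names):
            raise FormatError("duplicate leaf labels in tree")
        for n in root.postorder():
            if n.length is not None and n.length < 0:
                raise FormatError(f"negative branch length at {n.name or 'internal node'}")

    # -- queries ----------------------------------------------------------
    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def find_leaf(self, name: str) -> TreeNode:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def mrca(self, names: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the named leaves."""
        targets = set(names)
        for node in self.root.postorder():
            if targets <= set(node.leaf_names()):
                return node
        raise KeyError(f"leaves {sorted(targets)} not all present")

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-canonical side."""
        all_names = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            other = all_names - side
            if not other:
                continue
            canon = min(side, other, key=lambda s: (len(s), sorted(s)))
            out.add(canon)
        return out

    def copy(self) -> "PhyloTree":
        def clone(n: TreeNode) -> TreeNode:
            m = TreeNode(n.name, n.length, n.support)
            for c in n.children:
                m.add(clone(c))
            return m
        return PhyloTree(clone(self.root))

    # -- rerooting --------------------------------------------------------
    def rooted_at_edge(self, child: TreeNode, fraction: float = 0.5) -> "PhyloTree":
        """Return a new tree rooted on the edge above ``child``.

        The edge's length is split ``fraction`` (toward the old parent side)
        to ``1 - fraction`` (toward ``child``).  The original tree is left
        untouched.
        """
        if child.parent is None:
            raise ValueError("cannot root above the current root")
        # Work on a copy; locate the corresponding node by path.
        path: list[int] = []
        n = child
        while n.parent is not None:
            path.append(n.parent.children.index(n))
            n = n.parent
        new = self.copy()
        node = new.root
        for i in reversed(path):
            node = node.children[i]

        old_parent = node.parent
        length = node.length if node.length is not None else 0.0
        old_parent.children.remove(node)
        node.parent = None

        new_root = TreeNode()
        new_root.add(node)
        node.length = (1.0 - fraction) * length

        # Re-hang the path from old_parent back to the old root.
        def rehang(n: TreeNode) -> TreeNode:
            """Reverse the parent edge of ``n``; returns n as a new subtree root."""
            p = n.parent
            n.parent = None
            if p is not None:
                p.children.remove(n)
                rehang(p)
                n.add(p)
                p.length = n.length
                p.support = n.support
            return n

        rehang(old_parent)
        new_root.add(old_parent)
        old_parent.length = fraction * length
        old_parent.support = node.support

        # Collapse a leftover unary node (the old root, if it had degree 2).
        for nd in list(new_root.postorder()):
            if not nd.is_leaf and len(nd.children) == 1 and nd.parent is not None:
                only = nd.children[0]
                only.length = (only.length or 0.0) + (nd.length or 0.0)
                only.parent = nd.parent
                idx = nd.parent.children.index(nd)
                nd.parent.children[idx] = only
        return PhyloTree(new_root)

    # -- serialization ----------------------------------------------------
    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                s = n.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.support is not None:
                    s += format_number(n.support)
                elif n.name:
                    s += n.name
            if n.length is not None:
                s += f":{format_number(n.length)}"
            return s
        return fmt(self.root) + ";"


def format_number(x: float) -> str:
    """Compact numeric formatting: integers bare, floats with up to 10 sig figs."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(round(float(x), 10))


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string.

    Internal node labels that look numeric are read as support values
    (the MEGA / IQ-TREE convention); other labels become node names.
    """
    try:
        btree = Phylo.read(io.StringIO(text), "newick")
    except Exception as exc:  # Bio raises NewickError subclasses of Exception
        raise FormatError(f"Newick parse error: {exc}") from exc

    def convert(clade) -> TreeNode:
        support = clade.confidence
        name = clade.name
        if name is not None and not clade.is_terminal():
            # Bio.Phylo usually routes numeric labels to confidence already;
            # handle the stragglers (e.g. "0.95" with a name-like dialect).
            try:
                support = float(name)
                name = None
            except ValueError:
                pass
        node = TreeNode(name=name,
                        length=clade.branch_length,
                        support=float(support) if support is not None else None)
        for ch in clade.clades:
            node.add(convert(ch))
        return node

    root = convert(btree.root)
    if root.is_leaf and root.name is None:
        raise FormatError("Newick parse error: empty tree")
    return PhyloTree(root)


def read_newick(path: str) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Structures (minimal PDB)
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    serial: int
    name: str
    res_name: str
    chain: str
    res_seq: int
    x: float
    y: float
    z: float
    b_factor: float = 0.0


@dataclass
class StructureModel:
    """Atoms plus a (chain, residue number) index."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise FormatError(f"non-finite coordinate in atom {a.serial}")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residues(self, chain: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain == chain:
                seen.setdefault(a.res_seq, None)
        return list(seen)

    def residue_atoms(self, chain: str, res_seq: int) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain and a.res_seq == res_seq]


_PDB_FLOAT_FIELDS = ((30, 38), (38, 46), (46, 54))


def parse_pdb(text: str, keep_hetatm: bool = False) -> StructureModel:
    """Parse fixed-column ``ATOM`` records; ``HETATM`` skipped by default."""
    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "HETATM" and not keep_hetatm:
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain = line[21:22].strip() or "A"
            res_seq = int(line[22:26])
            x, y, z = (float(line[a:b]) for a, b in _PDB_FLOAT_FIELDS)
            bfield = line[60:66].strip()
            b = float(bfield) if bfield else 0.0
        except (ValueError, IndexError) as exc:
            raise FormatError(f"malformed ATOM record at line {lineno}: {exc}") from exc
        atoms.append(Atom(serial, name, res_name, chain, res_seq, x, y, z, b))
    return StructureModel(atoms)


def write_pdb(model: StructureModel) -> str:
    lines = []
    for a in model.atoms:
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:>5d} {name}{'':1s}{a.res_name:>3s} {a.chain:1s}"
            f"{a.res_seq:>4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{a.b_factor:6.2f}"
        )
    return "\n".join(lines) + "\nEND\n"


def read_pdb(path: str, keep_hetatm: bool = False) -> StructureModel:
    with open(path) as fh:
        return parse_pdb(fh.read(), keep_hetatm=keep_hetatm)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_tsv(path: str, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """All result tables: tab-separated, single header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
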