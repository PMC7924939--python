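"""Distance and likelihood phylogenetics.

Two tree-building routes, matching the pipeline's two stages:

* A distance route — Poisson-corrected distances with pairwise gap
  deletion, neighbor joining, and nonparametric bootstrap supports — used
  for the fast per-taxon screens.
* A likelihood route — Felsenstein-pruning log-likelihood under an
  equal-rates (Poisson) or LG exchangeability matrix, optional empirical
  "+F" frequencies, FreeRate among-site rate heterogeneity, coordinate
  ascent over branch lengths and rate parameters, and hill-climbing NNI —
  used for the final pooled classification tree.

Saturated distance pairs (p >= 0.95) are capped at -ln(0.05) and flagged
rather than returned infinite, since neighbor joining needs finite input.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import gamma as gamma_dist

from .io_formats import AMINO_ACIDS, GAP, UNKNOWN, Alignment, PhyloTree, TreeNode
from .lg_data import LG_FREQS, lg_exchangeabilities

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

SATURATION_P = 0.95


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray                       # symmetric, zero diagonal
    n_usable: np.ndarray                # per-pair usable-site counts
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise PhyloError("distance matrix diagonal not zero")

    def pair(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Rows as integer codes: 0..19 residues, -1 for gap or 'X'."""
    code = np.full((len(aln.rows), aln.n_cols), -1, dtype=np.int8)
    for r, rec in enumerate(aln.rows):
        for c, sym in enumerate(rec.residues):
            code[r, c] = _AA_INDEX.get(sym, -1)
    return code


def poisson_distance(aln: Alignment) -> DistanceMatrix:
    """Poisson-corrected distances with pairwise gap deletion.

    For each pair, p is the proportion of differing sites among columns
    where both rows carry a known residue, and d = -ln(1 - p).  Pairs at or
    beyond p = 0.95 are capped at -ln(0.05) and flagged as saturated.
    """
    if len(aln.rows) < 2:
        raise PhyloError("need at least 2 rows for distances")
    code = encode_alignment(aln)
    n = code.shape[0]
    ids = aln.ids()
    d = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    saturated: set[tuple[str, str]] = set()
    known = code >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = known[i] & known[j]
            m = int(both.sum())
            if m == 0:
                raise PhyloError(
                    f"no usable sites between {ids[i]!r} and {ids[j]!r} "
                    "under pairwise deletion"
                )
            p = float((code[i, both] != code[j, both]).mean())
            if p >= SATURATION_P:
                dist = -math.log(1 - SATURATION_P)
                saturated.add((ids[i], ids[j]))
            else:
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
            usable[i, j] = usable[j, i] = m
    return DistanceMatrix(ids, d, usable, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    The result is stored rooted at the final trifurcation.  Negative
    branch-length estimates are clamped to zero with the deficit moved to
    the sister branch, preserving the joined pair's summed length.
    """
    n = len(dm.ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(q.argmin()), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # Distances from the new node to the remaining taxa.
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # Final three lineages join at the unrooted central node.
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.add(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: Alignment, builder, B: int, seed: int,
                      target_tree: PhyloTree | None = None) -> PhyloTree:
    """Nonparametric bootstrap supports on internal bipartitions.

    Columns are resampled with replacement ``B`` times; each replicate is
    passed to ``builder`` (an alignment -> tree callable).  The support of
    every internal bipartition of the point-estimate tree (``builder`` on
    the original alignment, or ``target_tree`` if given) is the percentage
    of replicate trees containing that bipartition.
    """
    if B < 1:
        raise PhyloError("bootstrap needs B >= 1")
    rng = np.random.default_rng(seed)
    point = target_tree.copy() if target_tree is not None else builder(aln)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    for _ in range(B):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rows = [type(r)(r.id, "".join(r.residues[c] for c in cols))
                for r in aln.rows]
        rep = builder(Alignment(rows))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_names = frozenset(point.leaf_names())
    for node in point.postorder():
        if node.is_leaf or node is point.root:
            continue
        side = frozenset(node.leaf_names())
        canon = min(side, all_names - side, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts.get(canon, 0) / B
    return point


def nj_builder(aln: Alignment) -> PhyloTree:
    return nj_tree(poisson_distance(aln))


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

@dataclass
class SubstModel:
    """Reversible amino-acid model with FreeRate heterogeneity.

    ``rates`` and ``weights`` define k categories with weights summing to 1
    and mean rate sum(w_i * r_i) normalized to 1.
    """

    name: str
    exchangeabilities: np.ndarray       # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray             # (20,), sums to 1
    rates: np.ndarray = field(default_factory=lambda: np.ones(1))
    weights: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.frequencies.sum() - 1) > 1e-9:
            raise PhyloError("stationary frequencies must sum to 1")
        if abs(self.weights.sum() - 1) > 1e-9:
            raise PhyloError("rate-category weights must sum to 1")
        mean = float(self.rates @ self.weights)
        if mean > 0 and abs(mean - 1) > 1e-9:
            self.rates = self.rates / mean
        self._decompose()

    def _decompose(self) -> None:
        pi = self.frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(pi @ np.diag(q))
        q = q / mu
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        vals, vecs = np.linalg.eigh((sym + sym.T) / 2)
        self._eigvals = vals
        self._left = vecs.T * sqrt_pi[None, :]          # U^T D^{1/2}
        self._right = vecs / sqrt_pi[:, None]           # D^{-1/2} U

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) under the normalized rate matrix scaled by ``rate``."""
        e = np.exp(self._eigvals * t * rate)
        p = (self._right * e[None, :]) @ self._left
        return np.clip(p, 0.0, None)

    def with_rates(self, rates: np.ndarray, weights: np.ndarray) -> "SubstModel":
        return SubstModel(self.name, self.exchangeabilities,
                          self.frequencies, rates, weights)


def poisson_model(k: int = 1) -> SubstModel:
    ex = np.ones((20, 20))
    np.fill_diagonal(ex, 0.0)
    rates, weights = free_rate_init(k)
    return SubstModel("poisson", ex, np.full(20, 1 / 20), rates, weights)


def lg_model(frequencies: np.ndarray | None = None, k: int = 1) -> SubstModel:
    """LG model; pass empirical frequencies for the '+F' variant."""
    freqs = LG_FREQS if frequencies is None else np.asarray(frequencies)
    rates, weights = free_rate_init(k)
    return SubstModel("lg", lg_exchangeabilities(), freqs, rates, weights)


def empirical_frequencies(aln: Alignment, pseudocount: float = 1.0) -> np.ndarray:
    """'+F' frequencies: alignment residue counts plus a pseudocount."""
    counts = np.full(20, pseudocount)
    for rec in aln.rows:
        for sym in rec.residues:
            i = _AA_INDEX.get(sym)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def free_rate_init(k: int) -> tuple[np.ndarray, np.ndarray]:
    """FreeRate starting values: Gamma(1) quantile-bin means, equal weights."""
    if k < 1:
        raise PhyloError("need at least one rate category")
    if k == 1:
        return np.ones(1), np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=1.0)
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        # mean of Exp(1) truncated to [lo, hi), each bin has mass 1/k
        lo_term = (lo + 1) * math.exp(-lo)
        hi_term = 0.0 if math.isinf(hi) else (hi + 1) * math.exp(-hi)
        rates.append((lo_term - hi_term) * k)
    rates = np.array(rates)
    weights = np.full(k, 1 / k)
    return rates / (rates @ weights), weights


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _check_leaves(aln: Alignment, tree: PhyloTree) -> None:
    rows = set(aln.ids())
    leaves = set(tree.leaf_names())
    if rows != leaves:
        raise PhyloError(
            f"leaf/row mismatch: only in alignment {sorted(rows - leaves)}, "
            f"only in tree {sorted(leaves - rows)}"
        )


def tree_loglik(aln: Alignment, tree: PhyloTree, model: SubstModel) -> float:
    """Felsenstein-pruning log-likelihood.

    Site likelihood is the weight-mixture over the model's rate categories;
    gaps and 'X' contribute partial likelihood 1 for every state.
    """
    _check_leaves(aln, tree)
    code = encode_alignment(aln)
    row_of = {rid: i for i, rid in enumerate(aln.ids())}
    n_sites = aln.n_cols
    pi = model.frequencies
    site_lik = np.zeros(n_sites)
    for rate, weight in zip(model.rates, model.weights):
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                p = np.ones((n_sites, 20))
                states = code[row_of[node.name]]
                obs = states >= 0
                p[obs] = 0.0
                p[np.arange(n_sites)[obs], states[obs]] = 1.0
            else:
                p = np.ones((n_sites, 20))
                for child in node.children:
                    t = child.length if child.length is not None else 0.0
                    pm = model.transition(t, rate)
                    p *= partial.pop(id(child)) @ pm.T
            partial[id(node)] = p
        site_lik += weight * (partial[id(tree.root)] @ pi)
    if np.any(site_lik <= 0):
        return -math.inf
    return float(np.log(site_lik).sum())


def brute_force_loglik(aln: Alignment, tree: PhyloTree,
                       model: SubstModel) -> float:
    """Independent oracle: sum over all internal-node state assignments.

    Exponential in the number of internal nodes — only for tiny trees.
    """
    _check_leaves(aln, tree)
    code = encode_alignment(aln)
    row_of = {rid: i for i, rid in enumerate(aln.ids())}
    internals = [n for n in tree.postorder() if not n.is_leaf]
    pi = model.frequencies
    total = 0.0
    for site in range(aln.n_cols):
        site_l = 0.0
        for rate, weight in zip(model.rates, model.weights):
            pms = {id(n): model.transition(n.length or 0.0, rate)
                   for n in tree.postorder() if n.parent is not None}
            lik = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                state = {id(n): s for n, s in zip(internals, assign)}
                val = pi[state[id(tree.root)]]
                for n in tree.postorder():
                    if n.parent is None:
                        continue
                    parent_state = state[id(n.parent)]
                    if n.is_leaf:
                        obs = code[row_of[n.name], site]
                        if obs < 0:
                            continue  # missing: sums to 1 over states
                        val *= pms[id(n)][parent_state, obs]
                    else:
                        val *= pms[id(n)][parent_state, state[id(n)]]
                    if val == 0.0:
                        break
                lik += val
            site_l += weight * lik
        total += math.log(site_l)
    return total


# ---------------------------------------------------------------------------
# Numeric optimization and NNI
# ---------------------------------------------------------------------------

def optimize_numeric(aln: Alignment, tree: PhyloTree, model: SubstModel,
                     tol: float = 1e-4, max_sweeps: int = 100,
                     max_branch: float = 20.0
                     ) -> tuple[PhyloTree, SubstModel, float]:
    """Coordinate ascent over branch lengths and FreeRate parameters.

    Each sweep optimizes every branch length by bounded scalar search and,
    when the model has more than one category, the rate/weight simplex by a
    Nelder–Mead move in unconstrained coordinates.  Stops when a sweep
    improves the log-likelihood by less than ``tol`` (or at ``max_sweeps``).
    """
    tree = tree.copy()
    ll = tree_loglik(aln, tree, model)
    branches = [n for n in tree.postorder() if n.parent is not None]
    for _ in range(max_sweeps):
        ll_start = ll
        for node in branches:
            def neg(t: float, node=node) -> float:
                node.length = t
                return -tree_loglik(aln, tree, model)
            res = minimize_scalar(neg, bounds=(1e-9, max_branch),
                                  method="bounded",
                                  options={"xatol": 1e-7})
            node.length = float(res.x)
            ll = -float(res.fun)
        if len(model.rates) > 1:
            model, ll = _optimize_rates(aln, tree, model, ll)
        if ll - ll_start < tol:
            break
    return tree, model, ll


def _optimize_rates(aln: Alignment, tree: PhyloTree, model: SubstModel,
                    ll_current: float) -> tuple[SubstModel, float]:
    k = len(model.rates)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raw_rates = np.exp(x[:k])
        logits = np.concatenate([x[k:], [0.0]])
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        mean = raw_rates @ w
        return raw_rates / mean, w

    def neg(x: np.ndarray) -> float:
        rates, weights = unpack(x)
        return -tree_loglik(aln, tree, model.with_rates(rates, weights))

    x0 = np.concatenate([np.log(model.rates),
                         np.log(model.weights[:-1] / model.weights[-1])])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"maxiter": 200 * k, "xatol": 1e-4, "fatol": 1e-5})
    if -res.fun > ll_current:
        rates, weights = unpack(res.x)
        return model.with_rates(rates, weights), float(-res.fun)
    return model, ll_current


def nni_search(aln: Alignment, tree: PhyloTree, model: SubstModel,
               max_rounds: int = 20) -> tuple[PhyloTree, float]:
    """Hill climbing over nearest-neighbor interchanges.

    Considers every internal edge in deterministic preorder; a move is kept
    only if it strictly increases the log-likelihood.  Stops when a full
    round accepts nothing.
    """
    tree = tree.copy()
    ll = tree_loglik(aln, tree, model)
    for _ in range(max_rounds):
        improved = False
        for node in list(tree.preorder()):
            if node.is_leaf or node.parent is None:
                continue
            if len(node.children) != 2:
                continue
            parent = node.parent
            others = [c for c in parent.children if c is not node]
            if not others:
                continue
            s = others[0]
            c1, c2 = node.children
            for swap_child in (c1, c2):
                _swap(parent, s, node, swap_child)
                cand = tree_loglik(aln, tree, model)
                if cand > ll + 1e-9:
                    ll = cand
                    improved = True
                    s, swap_child = swap_child, s  # roles after accepted swap
                    break
                _swap(parent, swap_child, node, s)  # revert
        if not improved:
            break
    return tree, ll


def _swap(parent: TreeNode, a: TreeNode, node: TreeNode, b: TreeNode) -> None:
    """Exchange subtree ``a`` (child of parent) with ``b`` (child of node)."""
    ia = parent.children.index(a)
    ib = node.children.index(b)
    parent.children[ia], node.children[ib] = b, a
    a.parent, b.parent = node, parent
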