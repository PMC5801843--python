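"""Rooted ultrametric phylogenies and the time quantities downstream models consume.

The central container is :class:`Phylogeny`, an immutable array-backed rooted
tree with branch lengths in millions of years (My).  Ages are measured backward
from the present (tips at age 0); heights from the root are derived, never
stored.  Parsing of Newick and NEXUS (including BEAST/TreeAnnotator-style
TRANSLATE blocks, quoted labels and square-bracket comments) is delegated to
dendropy; the writer emits plain Newick.

Time is summarised in two objects every likelihood downstream consumes:

* :func:`branching_times` — internal-node ages, sorted descending, the
  sufficient statistic for birth–death diversification likelihoods;
* :func:`shared_time_matrix` — the matrix of root-to-MRCA times ``s_ij``
  underpinning all Gaussian trait-evolution models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "TreeError",
    "ParseError",
    "Phylogeny",
    "BranchingTimes",
    "CalibrationPrior",
    "parse_tree",
    "read_tree",
    "branching_times",
    "shared_time_matrix",
    "prune",
    "prior_quantile",
]

#: relative tolerance within which a tree counts as ultrametric
ULTRAMETRIC_RTOL = 1e-6
#: relative deviation up to which terminal branches are silently repaired
ULTRAMETRIC_REPAIR_RTOL = 1e-3


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class ParseError(TreeError):
    """Malformed Newick/NEXUS input."""


@dataclass(frozen=True)
class BranchingTimes:
    """Internal-node ages of an ultrametric tree, time before present, descending."""

    ages: np.ndarray
    n_tips: int

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        if ages.ndim != 1 or np.any(np.diff(ages) > 0):
            raise TreeError("branching times must be a descending 1-D vector")

    @property
    def root_age(self) -> float:
        return float(self.ages[0])


@dataclass(frozen=True)
class CalibrationPrior:
    """Offset lognormal node-age prior: age = offset + LogNormal(meanlog, sdlog)."""

    offset: float
    meanlog: float
    sdlog: float

    def __post_init__(self):
        if self.sdlog < 0:
            raise ValueError("sdlog must be >= 0")

    def quantile(self, p: float) -> float:
        return prior_quantile(self, p)


def prior_quantile(prior: CalibrationPrior, p: float) -> float:
    """p-quantile (in My) of an offset lognormal calibration prior.

    ``offset + exp(meanlog + sdlog * Phi^{-1}(p))``; with ``sdlog = 0`` this
    degenerates to ``offset + exp(meanlog)`` for every p.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile probability must lie in (0, 1), got {p}")
    return prior.offset + math.exp(prior.meanlog + prior.sdlog * stats.norm.ppf(p))


class Phylogeny:
    """Rooted, binary, ultrametric phylogeny backed by flat arrays.

    Nodes are integer-indexed; ``parent[i]`` is the parent of node ``i`` (−1
    for the root) and ``edge_length[i]`` the length of the branch subtending
    ``i`` (0 for the root).  Construction resolves polytomies to binary with
    zero-length branches (with a warning) and checks/repairs ultrametricity.
    """

    def __init__(
        self,
        parent: np.ndarray,
        edge_length: np.ndarray,
        labels: list[str | None],
        *,
        check: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = list(labels)
        n_nodes = len(self.parent)
        if not (len(self.edge_length) == len(self.labels) == n_nodes):
            raise TreeError("parent, edge_length and labels must have equal length")

        children: list[list[int]] = [[] for _ in range(n_nodes)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                if root >= 0:
                    raise TreeError("multiple roots")
                root = i
            else:
                children[p].append(i)
        if root < 0:
            raise TreeError("no root found")
        self.root = root
        self.children = [tuple(c) for c in children]
        self.edge_length[root] = 0.0

        self._preorder = self._compute_preorder()
        self.depth = np.zeros(n_nodes)
        for v in self._preorder[1:]:
            self.depth[v] = self.depth[self.parent[v]] + self.edge_length[v]
        self.tips = np.array([v for v in self._preorder if not self.children[v]], dtype=np.int64)
        self.tips = np.sort(self.tips)

        if check:
            self._validate()

    # -- construction helpers ------------------------------------------------

    def _compute_preorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        if len(order) != len(self.parent):
            raise TreeError("tree is not connected")
        return np.array(order, dtype=np.int64)

    def _validate(self):
        if np.any(self.edge_length < 0):
            raise TreeError("negative branch lengths")
        for v in range(self.n_nodes):
            k = len(self.children[v])
            if k == 1:
                raise TreeError(f"unifurcation at node {v}")
        for t in self.tips:
            if self.labels[t] is None:
                raise TreeError(f"unlabeled tip at node {t}")
        names = [self.labels[t] for t in self.tips]
        if len(set(names)) != len(names):
            raise TreeError("duplicate tip labels")
        h = self.root_height
        tip_depths = self.depth[self.tips]
        if h > 0:
            dev = float(np.max(h - tip_depths) / h)
            if dev > ULTRAMETRIC_RTOL:
                if dev <= ULTRAMETRIC_REPAIR_RTOL:
                    # rounding noise in dated trees: extend terminal branches
                    for t in self.tips:
                        self.edge_length[t] += h - self.depth[t]
                        self.depth[t] = h
                else:
                    raise TreeError(
                        f"tree is not ultrametric (relative tip-depth spread {dev:.2e}); "
                        "deviations above 1e-3 are not repaired automatically"
                    )

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Phylogeny":
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        n_poly = sum(1 for nd in dtree if len(nd.child_nodes()) > 2)
        if n_poly:
            warnings.warn(
                f"resolving {n_poly} polytom{'y' if n_poly == 1 else 'ies'} to binary "
                "with zero-length branches",
                stacklevel=3,
            )
            dtree.resolve_polytomies()
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        length = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ParseError("tree has branches without lengths")
                length[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.is_leaf():
                labels[i] = nd.label
        return cls(parent, length, labels)

    # -- basic properties ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[t] for t in self.tips]

    @property
    def root_height(self) -> float:
        """Crown age in My (maximum tip depth)."""
        return float(np.max(self.depth[self.tips]))

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.array([v for v in range(self.n_nodes) if self.children[v]], dtype=np.int64)

    def node_age(self, v: int) -> float:
        """Age of node v, time before present."""
        return self.root_height - float(self.depth[v])

    @property
    def ages(self) -> np.ndarray:
        return self.root_height - self.depth

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        h = self.root_height
        if h == 0:
            return True
        return float(np.max(h - self.depth[self.tips]) / h) <= rtol

    def preorder(self) -> np.ndarray:
        return self._preorder

    def postorder(self) -> np.ndarray:
        return self._preorder[::-1]

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> node index."""
        return {self.labels[t]: int(t) for t in self.tips}

    def descendant_tips(self) -> list[np.ndarray]:
        """Per-node array of descendant tip node-indices (a tip descends from itself)."""
        sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in self.postorder():
            if not self.children[v]:
                sets[v] = [int(v)]
            else:
                for c in self.children[v]:
                    sets[v].extend(sets[c])
        return [np.array(s, dtype=np.int64) for s in sets]

    # -- I/O -----------------------------------------------------------------

    def _newick_label(self, name: str) -> str:
        if any(ch in name for ch in " ()[]:;,'\t\n"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def to_newick(self, *, precision: int = 12) -> str:
        def render(v: int) -> str:
            if not self.children[v]:
                s = self._newick_label(self.labels[v])
            else:
                s = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            if v != self.root:
                s += f":{self.edge_length[v]:.{precision}g}"
            return s

        return render(self.root) + ";"

    # -- structural operations ------------------------------------------------

    def prune(self, keep) -> "Phylogeny":
        return prune(self, keep)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def parse_tree(text: str) -> Phylogeny:
    """Parse a Newick or NEXUS string into a :class:`Phylogeny`.

    NEXUS is detected by the ``#NEXUS`` magic; TRANSLATE blocks, quoted labels
    and square-bracket comments are handled.  Taxon labels are preserved
    verbatim (underscores are not converted to spaces).
    """
    stripped = text.lstrip()
    schema = "nexus" if stripped.lower().startswith("#nexus") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"could not parse {schema} input: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def read_tree(path) -> Phylogeny:
    """Read a Newick or NEXUS tree file."""
    with open(path) as fh:
        return parse_tree(fh.read())


def branching_times(tree: Phylogeny) -> BranchingTimes:
    """Internal-node ages before present, sorted descending (ties preserved)."""
    if not tree.is_ultrametric():
        if tree.is_ultrametric(ULTRAMETRIC_REPAIR_RTOL):
            raise TreeError(
                "tree is not ultrametric at tolerance 1e-6; re-parse to apply the "
                "terminal-branch repair"
            )
        raise TreeError("tree is not ultrametric; branching times undefined")
    ages = tree.root_height - tree.depth[tree.internal_nodes]
    ages = np.sort(ages)[::-1]
    return BranchingTimes(ages=ages, n_tips=tree.n_tips)


def shared_time_matrix(tree: Phylogeny, order: list[str] | None = None) -> np.ndarray:
    """Matrix of times (My) from the root to the MRCA of each tip pair.

    Rows/columns follow ``tree.tip_labels`` unless ``order`` gives an explicit
    label ordering.  The diagonal holds tip depths (the crown age for an
    exactly ultrametric tree).  Symmetric positive semi-definite.
    """
    n = tree.n_tips
    pos = {int(t): i for i, t in enumerate(tree.tips)}
    S = np.zeros((n, n))
    desc = tree.descendant_tips()
    for v in tree.internal_nodes:
        d = tree.depth[v]
        kids = tree.children[v]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = np.array([pos[int(t)] for t in desc[kids[a]]])
                ib = np.array([pos[int(t)] for t in desc[kids[b]]])
                S[np.ix_(ia, ib)] = d
                S[np.ix_(ib, ia)] = d
    for t in tree.tips:
        S[pos[int(t)], pos[int(t)]] = tree.depth[t]
    if order is not None:
        idx = {lab: i for i, lab in enumerate(tree.tip_labels)}
        missing = [lab for lab in order if lab not in idx]
        if missing:
            raise TreeError(f"labels not in tree: {missing}")
        sel = np.array([idx[lab] for lab in order])
        S = S[np.ix_(sel, sel)]
    return S


def prune(tree: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on the tip set ``keep`` (labels).

    Degree-2 internal nodes are suppressed with branch lengths summed; the new
    root is the MRCA of the kept tips, so the crown age may shrink.
    """
    keep = list(keep)
    idx = tree.tip_index()
    unknown = sorted(set(keep) - set(idx))
    if unknown:
        raise TreeError(f"species not in tree: {unknown}")
    if len(set(keep)) < 2:
        raise TreeError("need at least 2 tips to prune to")
    kept_nodes = {idx[lab] for lab in keep}

    n_kept_below = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder():
        if not tree.children[v]:
            n_kept_below[v] = 1 if v in kept_nodes else 0
        else:
            n_kept_below[v] = sum(n_kept_below[c] for c in tree.children[v])

    # new root: deepest node with all kept tips below
    new_root = tree.root
    total = len(kept_nodes)
    while True:
        heavy = [c for c in tree.children[new_root] if n_kept_below[c] == total]
        if heavy:
            new_root = heavy[0]
        else:
            break

    # retained nodes: kept tips and internal nodes with >=2 children subtrees
    # containing kept tips (plus the new root)
    parent_out: list[int] = []
    length_out: list[float] = []
    labels_out: list[str | None] = []

    def build(v: int, pending_len: float, parent_id: int) -> None:
        while tree.children[v]:
            live = [c for c in tree.children[v] if n_kept_below[c] > 0]
            if len(live) >= 2 or v == new_root:
                break
            c = live[0]
            pending_len += tree.edge_length[c]
            v = c
        my_id = len(parent_out)
        parent_out.append(parent_id)
        length_out.append(pending_len)
        labels_out.append(tree.labels[v] if not tree.children[v] else None)
        for c in tree.children[v]:
            if n_kept_below[c] > 0:
                build(c, float(tree.edge_length[c]), my_id)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, tree.n_nodes * 2 + 100))
    try:
        build(new_root, 0.0, -1)
    finally:
        sys.setrecursionlimit(old_limit)
    return Phylogeny(np.array(parent_out), np.array(length_out), labels_out)
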