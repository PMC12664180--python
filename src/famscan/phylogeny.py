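"""Domain-anchored alignment, neighbor-joining trees, bootstrap, subgroups.

Distances are p-distances with pairwise gap deletion (optional Poisson
correction).  Trees are built by the Saitou-Nei neighbor-joining
agglomeration with the standard Q criterion; ties are broken by joining
the lowest-index pair so the procedure is deterministic.  Bootstrap
support is the percentage of column-resampled replicate trees containing
each internal bipartition of the full-data tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .family_scan import HEPTAPEPTIDE

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alignment

def align_domains(domain_seqs: Mapping[str, str]) -> dict[str, str]:
    """Anchor-align WRKY domain sequences on the heptapeptide.

    Each sequence is split at its heptapeptide; the upstream segments
    are right-justified and the downstream segments left-justified with
    gap characters, so the heptapeptide occupies the same columns in
    every row.  Sequences lacking the anchor are excluded with a
    warning.  Ungapping any row returns its input.
    """
    anchored: dict[str, tuple[str, str]] = {}
    for name, seq in domain_seqs.items():
        pos = seq.find(HEPTAPEPTIDE)
        if pos == -1:
            logger.warning("%s lacks the heptapeptide anchor; excluded", name)
            continue
        anchored[name] = (seq[:pos], seq[pos:])
    if len(anchored) < 2:
        raise ValueError("need at least two sequences containing the anchor")
    left_w = max(len(left) for left, _ in anchored.values())
    right_w = max(len(right) for _, right in anchored.values())
    return {
        name: left.rjust(left_w, "-") + right.ljust(right_w, "-")
        for name, (left, right) in anchored.items()
    }


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape must match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def p_distance_matrix(
    alignment: Mapping[str, str], poisson_correct: bool = False
) -> DistanceMatrix:
    """Pairwise p-distances with pairwise gap deletion.

    With ``poisson_correct`` the distance is -ln(1 - p).
    """
    taxa = list(alignment)
    rows = np.array([np.frombuffer(alignment[t].encode(), dtype=np.uint8) for t in taxa])
    gap = ord("-")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            valid = (a != gap) & (b != gap)
            nv = int(valid.sum())
            p = float(((a != b) & valid).sum()) / nv if nv else 0.0
            if poisson_correct:
                if p >= 1.0:
                    raise ValueError("p-distance 1.0 cannot be Poisson corrected")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(leaf.name for leaf in self.leaves())

    def walk(self):
        yield self
        for child, _ in self.children:
            yield from child.walk()

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self, length: float | None = None) -> str:
        if self.is_leaf:
            body = self.name
        else:
            inner = ",".join(c._newick_node(bl) for c, bl in self.children)
            label = "" if self.support is None else f"{self.support:g}"
            body = f"({inner}){label}"
        if length is None:
            return body
        return f"{body}:{length:g}"


@dataclass
class PhyloTree:
    root: TreeNode
    taxa: list[str]

    def newick(self) -> str:
        return self.root.newick()

    def internal_bipartitions(self) -> set[frozenset]:
        """Nontrivial bipartitions (as the smaller/canonical leaf side).

        Canonical side = the side NOT containing the lexicographically
        smallest taxon, so the representation is independent of rooting
        and of input taxon order.
        """
        all_taxa = frozenset(self.taxa)
        ref = min(self.taxa)
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(side)
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths along the tree's branches."""
        # distance from each leaf to every ancestor node (keyed by id)
        anc: dict[str, dict[int, float]] = {}

        def visit2(node: TreeNode, path: list[tuple[int, float]]) -> None:
            if node.is_leaf:
                total = 0.0
                dists = {}
                for nid, bl in reversed(path):
                    total += bl
                    dists[nid] = total
                dists[id(node)] = 0.0
                anc[node.name] = dists
            for child, bl in node.children:
                visit2(child, path + [(id(node), bl)])

        visit2(self.root, [])
        # leaf-to-leaf distance through the lowest common ancestor
        order: dict[int, int] = {}
        for idx, node in enumerate(self.root.walk()):
            order[id(node)] = idx
        n = len(self.taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = self.taxa[i], self.taxa[j]
                common = set(anc[a]) & set(anc[b])
                lca = max(common, key=lambda nid: order[nid])
                d[i, j] = d[j, i] = anc[a][lca] + anc[b][lca]
        return DistanceMatrix(list(self.taxa), d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    On an additive distance matrix the output tree's path-length matrix
    reproduces the input exactly (up to floating point).  Negative
    branch lengths are clamped to zero with a log record.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    D = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # reuse slot i for the new node
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        active.remove(j)

    i, j = active
    root = TreeNode(children=[(nodes[i], clamp(D[i, j])), (nodes[j], 0.0)])
    return PhyloTree(root=root, taxa=list(dm.taxa))


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 1000,
    seed: int | None = None,
    poisson_correct: bool = False,
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap support percentages.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each internal bipartition
    of the full-data tree.  With ``n_reps=0`` supports stay missing.
    """
    if len(alignment) < 4:
        raise ValueError("bootstrap requires at least 4 aligned sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    ncol = lengths.pop()
    tree = nj_tree(p_distance_matrix(alignment, poisson_correct=poisson_correct))
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    taxa = list(alignment)
    rows = np.array([list(alignment[t]) for t in taxa])
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.internal_bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_alignment = {
            t: "".join(rows[k][cols]) for k, t in enumerate(taxa)
        }
        rep_tree = nj_tree(
            p_distance_matrix(rep_alignment, poisson_correct=poisson_correct)
        )
        rep_bps = rep_tree.internal_bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_taxa = frozenset(taxa)
    ref = min(taxa)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = node.leaf_names()
        canon = all_taxa - side if ref in side else side
        if canon in counts:
            node.support = 100.0 * counts[canon] / n_reps
    return tree


# ---------------------------------------------------------------------------
# subgroup assignment

def assign_subgroups(
    tree: PhyloTree,
    reference_labels: Mapping[str, str],
    domain_info: Mapping[str, tuple[int, str]] | None = None,
) -> dict[str, str]:
    """Assign each non-reference leaf the group of its enclosing reference clade.

    For each gene the smallest clade containing it together with at
    least one reference taxon determines the group (majority group of
    the clade's references; ties broken alphabetically).  Clades are
    taken unrooted: both sides of every internal edge qualify, so the
    arbitrary NJ rooting cannot split a group.  When no clade
    qualifies, an optional domain-architecture fallback applies:
    two domains -> 'I'; one domain with a C2HC zinc finger -> 'III';
    otherwise 'unassigned'.
    """
    groups = set(reference_labels.values())
    if not groups:
        raise ValueError("reference_labels must not be empty")
    all_taxa = frozenset(tree.taxa)
    sides: set[frozenset] = set()
    for node in tree.root.walk():
        if node.is_leaf:
            continue
        side = node.leaf_names()
        for s in (side, all_taxa - side):
            if 0 < len(s) < len(all_taxa):
                sides.add(s)
    clades = sorted(sides, key=lambda s: (len(s), sorted(s)))
    out: dict[str, str] = {}
    for leaf in tree.taxa:
        if leaf in reference_labels:
            continue
        assigned = None
        for clade in clades:
            if leaf not in clade:
                continue
            refs = [reference_labels[t] for t in clade if t in reference_labels]
            if refs:
                tally: dict[str, int] = {}
                for g in refs:
                    tally[g] = tally.get(g, 0) + 1
                top = max(tally.values())
                assigned = sorted(g for g, c in tally.items() if c == top)[0]
                break
        if assigned is None and domain_info is not None and leaf in domain_info:
            n_domains, zf = domain_info[leaf]
            if n_domains >= 2:
                assigned = "I"
            elif zf == "C2HC":
                assigned = "III"
        out[leaf] = assigned if assigned is not None else "unassigned"
    return out
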