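"""Progressive alignment, neighbor-joining trees and bootstrap supports.

Precursor family members are aligned with a built-in progressive aligner
(k-mer distance guide, profile-profile Needleman-Wunsch), distances are
p-distances with pairwise deletion of gap sites, trees are canonical
Saitou-Nei neighbor joining (Q-matrix joins; deterministic tie-break by
taxon label order; negative branch lengths clamped to zero), and supports
come from column-resampling bootstrap (default 1000 replicates), reported as
the percentage of replicates containing each original bipartition.

An adapter reading an externally produced aligned FASTA
(:func:`read_alignment_fasta`) slots external aligners into the same flow.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import SequenceRecord, read_fasta

GAP = "-"


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None  # % bootstrap, internal edges only
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> set:
        return {l.name for l in self.leaves()}

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    root: TreeNode
    outgroup: Optional[str] = None

    def taxa(self) -> set:
        return self.root.leaf_names()

    def bipartitions(self) -> set:
        """Non-trivial splits as canonical frozensets.

        Each internal edge splits the taxa; the side not containing the
        alphabetically smallest taxon represents the split.  Only splits
        with at least two taxa on both sides are reported.
        """
        all_taxa = self.taxa()
        anchor = min(all_taxa)
        splits = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = frozenset(all_taxa - side)
            if len(side) >= 2 and len(all_taxa) - len(side) >= 2:
                splits.add(side)
        return splits

    def to_newick(self, with_supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string with branch lengths and internal-node support
    labels (the serialisation format of :meth:`PhyloTree.to_newick`)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label (leaf name or internal support), optionally with :length
        start = pos
        while pos < len(s) and s[pos] not in ",();":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                name, _, ln = label.partition(":")
                node.name = name
                node.length = float(ln) if ln else 0.0
            else:
                sup, _, ln = label.partition(":")
                if sup:
                    node.support = float(sup)
                node.length = float(ln) if ln else 0.0
        return node

    root = parse_node()
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


_GAP_OPEN = -1.0
_GAP_EXTEND = -0.3
_GAP_SCORE = -0.65  # column-vs-gap score inside profiles
_MISMATCH_SCORE = 0.0
_MATCH_SCORE = 1.0


def _profile_columns(rows: Sequence[str]) -> list[dict]:
    cols = []
    for i in range(len(rows[0])):
        freq: dict[str, float] = {}
        for r in rows:
            c = r[i]
            freq[c] = freq.get(c, 0.0) + 1.0
        n = len(rows)
        cols.append({c: v / n for c, v in freq.items()})
    return cols


def _col_score(fa: dict, fb: dict) -> float:
    score = 0.0
    for ca, pa in fa.items():
        for cb, pb in fb.items():
            if ca == GAP or cb == GAP:
                s = _GAP_SCORE / 2.0
            elif ca == cb:
                s = _MATCH_SCORE
            else:
                s = _MISMATCH_SCORE
            score += pa * pb * s
    return score


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with affine gaps (prefers one gap
    block over scattered gaps at equal match count)."""
    A, B = _profile_columns(rows_a), _profile_columns(rows_b)
    n, m = len(A), len(B)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A column)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = _GAP_OPEN + (i - 1) * _GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = _GAP_OPEN + (j - 1) * _GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _col_score(A[i - 1], B[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + _GAP_OPEN, X[i - 1, j] + _GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + _GAP_OPEN, Y[i, j - 1] + _GAP_EXTEND)
    # traceback from the best final state (M preferred on ties)
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m])
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            s = _col_score(A[i - 1], B[j - 1])
            prev = M[i, j] - s
            if abs(M[i - 1, j - 1] - prev) < eps:
                state = "M"
            elif abs(X[i - 1, j - 1] - prev) < eps:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X" or j == 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            if i > 1 and abs(X[i - 1, j] + _GAP_EXTEND - X[i, j]) < eps and j > 0:
                state = "X"
            else:
                state = "M"
            i -= 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            if j > 1 and abs(Y[i, j - 1] + _GAP_EXTEND - Y[i, j]) < eps and i > 0:
                state = "Y"
            else:
                state = "M"
            j -= 1
    return ["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b]


def progressive_align(seqs: Sequence[SequenceRecord | str]) -> tuple[list[str], list[str]]:
    """Multiple alignment by progressive profile merging.

    Sequences are joined in increasing k-mer distance order (single-linkage
    agglomeration), aligning profile to profile with Needleman-Wunsch.
    Returns (ids, aligned_rows); all rows share one length >= the longest
    input.  A single sequence is an error.
    """
    ids = [getattr(s, "id", f"seq{i}") for i, s in enumerate(seqs)]
    raw = [getattr(s, "sequence", s) for s in seqs]
    if len(raw) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [raw[i]]) for i in range(len(raw))
    }
    dists = {
        (i, j): _kmer_distance(raw[i], raw[j])
        for i, j in itertools.combinations(range(len(raw)), 2)
    }
    active = set(clusters)
    while len(active) > 1:
        (i, j) = min(
            ((i, j) for (i, j) in dists if i in active and j in active),
            key=lambda ij: (dists[ij], ij),
        )
        ids_a, rows_a = clusters[i]
        ids_b, rows_b = clusters[j]
        new_a, new_b = _align_profiles(rows_a, rows_b)
        clusters[i] = (ids_a + ids_b, new_a + new_b)
        active.discard(j)
        for (p, q) in list(dists):
            if j in (p, q):
                other = q if p == j else p
                if other in active and other != i:
                    key = (min(i, other), max(i, other))
                    dists[key] = min(dists.get(key, math.inf), dists[(p, q)])
                del dists[(p, q)]
    final_ids, rows = clusters[active.pop()]
    order = {name: k for k, name in enumerate(final_ids)}
    perm = sorted(range(len(ids)), key=lambda k: order[ids[k]])  # restore input order
    by_name = dict(zip(final_ids, rows))
    return ids, [by_name[name] for name in ids]


def read_alignment_fasta(path) -> tuple[list[str], list[str]]:
    """Adapter: load an externally computed alignment (aligned FASTA).

    Rows keep their gap characters; T is converted to U.
    """
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace("T", "U"))
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows have unequal lengths")
    return ids, rows


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    taxa: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.d).all():
            raise ValueError("distances must be finite")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def p_distance(ids: Sequence[str], rows: Sequence[str]) -> DistanceMatrix:
    """Proportion of differing sites per pair, pairwise-deleting gap sites."""
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = comparable = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                comparable += 1
                if a != b:
                    diff += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = diff / comparable
    return DistanceMatrix(list(ids), d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei NJ.

    Q(i,j) = (n-2) d(i,j) - r(i) - r(j); the joined pair gets branch lengths
    from the standard three-point formulas; negative lengths are clamped to
    zero.  Ties in Q are broken by taxon label order, making the topology
    deterministic.  The result is unrooted, represented with a trifurcating
    root.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    labels = list(dm.taxa)
    D = {
        (a, b): dm.d[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else D[(a, b)]

    active = sorted(labels)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * dist(a, b) - r[a] - r[b]
            if best is None or q < best[0] - 1e-12:
                best = (q, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        new_label = f"({a}|{b})"
        node = TreeNode()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = max(0.0, la), max(0.0, lb)
        node.children = [na, nb]
        nodes[new_label] = node
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            D[(new_label, c)] = D[(c, new_label)] = max(0.0, duc)
        active = sorted([c for c in active if c not in (a, b)] + [new_label])

    a, b, c = active
    root = TreeNode()
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    for label, ln in ((a, la), (b, lb), (c, lc)):
        nd = nodes.pop(label)
        nd.length = max(0.0, ln)
        root.children.append(nd)
    return PhyloTree(root)


def reroot(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root the tree on the outgroup leaf's edge (outgroup at the base).

    The tree is flattened to an undirected graph; a new root node bisects
    the outgroup's pendant edge and the rooted tree is rebuilt from there.
    Edge lengths and supports travel with their edges.
    """
    # undirected adjacency over the existing nodes
    adj: dict[int, list[tuple[TreeNode, float, Optional[float]]]] = {}
    objs: dict[int, TreeNode] = {}

    def connect(a: TreeNode, b: TreeNode, length: float, support: Optional[float]) -> None:
        adj.setdefault(id(a), []).append((b, length, support))
        adj.setdefault(id(b), []).append((a, length, support))
        objs[id(a)], objs[id(b)] = a, b

    target = None
    for node in tree.root.walk():
        if node.is_leaf and node.name == outgroup:
            target = node
        for c in node.children:
            connect(node, c, c.length, c.support)
    if target is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")

    (parent, plen, psup) = adj[id(target)][0]
    half = plen / 2.0

    def build(node: TreeNode, parent_obj: Optional[TreeNode]) -> TreeNode:
        out = TreeNode(name=node.name)
        for (nb, length, support) in adj[id(node)]:
            if parent_obj is not None and nb is parent_obj:
                continue
            if nb is target or node is target:
                continue
            child = build(nb, node)
            child.length, child.support = length, support
            out.children.append(child)
        return out

    new_root = TreeNode()
    og = TreeNode(name=outgroup, length=half)
    rest = build(parent, target)
    rest.length, rest.support = half, psup

    # suppress a degree-2 node left where the old root sat
    def flatten(n: TreeNode) -> None:
        for idx, c in enumerate(list(n.children)):
            flatten(c)
            if not c.is_leaf and len(c.children) == 1:
                only = c.children[0]
                only.length += c.length
                if only.support is None:
                    only.support = c.support
                n.children[n.children.index(c)] = only

    new_root.children = [og, rest]
    flatten(new_root)
    return PhyloTree(new_root, outgroup=outgroup)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap(
    ids: Sequence[str],
    rows: Sequence[str],
    replicates: int = 1000,
    seed: int = 0,
    outgroup: Optional[str] = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``replicates`` times; each
    replicate alignment is rebuilt into an NJ tree, and every internal edge
    of the original tree is annotated with the percentage of replicates
    containing its bipartition.  Reproducible from ``seed``.
    """
    rows = list(rows)
    n_cols = len(rows[0])
    if n_cols < 4:
        raise ValueError("bootstrap needs an alignment with >= 4 columns")
    base = neighbor_joining(p_distance(ids, rows))
    counts: dict[frozenset, int] = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed)
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        res_rows = ["".join(r[c] for c in cols) for r in rows]
        try:
            rep = neighbor_joining(p_distance(ids, res_rows))
        except ValueError:
            continue
        done += 1
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_taxa = base.taxa()
    anchor = min(all_taxa)
    for node in base.root.walk():
        if node is base.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = frozenset(all_taxa - side)
        if side in counts and done:
            node.support = 100.0 * counts[side] / done
    if outgroup is not None:
        rooted = reroot(base, outgroup)
        return rooted
    return base
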