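"""Neighbor-Joining trees from Poisson-corrected protein distances.

Distances are computed per pair over the columns where neither sequence
has a gap (pairwise deletion; ambiguous X residues are excluded too):
p = differing shared columns / shared columns, d = -ln(1 - p).  Trees are
built with the Saitou–Nei Q-criterion; negative branch lengths are
floored at zero (and logged).  Bootstrap support resamples alignment
columns with replacement and reports the percentage of replicate trees
containing each internal bipartition; branches at or below the cutoff
can be collapsed for rendering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


def poisson_distance(seq_i: str, seq_j: str) -> float:
    """Poisson-corrected distance between two aligned sequences."""
    shared = diff = 0
    for a, b in zip(seq_i.upper(), seq_j.upper()):
        if a in "-X" or b in "-X":
            continue
        shared += 1
        diff += a != b
    if shared == 0:
        raise ValueError("no shared gap-free columns")
    p = diff / shared
    if p >= 1.0:
        raise ValueError(
            f"proportion of differences is {p:.3f}; the Poisson correction "
            "-ln(1-p) is undefined at p = 1")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix must be finite")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        self.matrix = m


def _encode_msa(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(msa)
    width = len(next(iter(msa.values())))
    if any(len(s) != width for s in msa.values()):
        raise ValueError("alignment rows have unequal width")
    arr = np.array([list(msa[l].upper()) for l in labels])
    return labels, arr


def distance_matrix(msa: dict[str, str],
                    columns: np.ndarray | None = None) -> DistanceMatrix:
    """All-pairs Poisson distances under pairwise deletion.

    `columns` restricts/duplicates alignment columns (bootstrap resampling).
    """
    labels, arr = _encode_msa(msa)
    if columns is not None:
        arr = arr[:, columns]
    usable = (arr != "-") & (arr != "X")
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = usable[i] & usable[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(f"no shared columns between {labels[i]} "
                                 f"and {labels[j]}")
            p = float((arr[i, shared] != arr[j, shared]).sum()) / total
            if p >= 1.0:
                raise ValueError(f"p = 1 between {labels[i]} and {labels[j]}")
            out[i, j] = out[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(labels, out)


@dataclass
class Clade:
    """A node of an (unrooted) tree; the NJ root is a trifurcation."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True,
               collapse_below: float | None = None) -> str:
        return self._newick(with_support, collapse_below, top=True) + ";"

    def _newick(self, with_support, collapse_below, top=False) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        kids = list(self.children)
        # collapse unsupported internal edges into polytomies
        if collapse_below is not None:
            flat = []
            for c in kids:
                if (c.children and c.support is not None
                        and c.support <= collapse_below):
                    for gc in c.children:
                        gc = Clade(gc.name, gc.length + 0.0, gc.support,
                                   gc.children)
                        flat.append(gc)
                else:
                    flat.append(c)
            kids = flat
        inner = ",".join(c._newick(with_support, collapse_below) for c in kids)
        label = ""
        if with_support and self.support is not None and not top:
            label = f"{self.support:g}"
        tail = "" if top else f":{self.length:.6f}"
        return f"({inner}){label}{tail}"

    def bipartitions(self) -> set[frozenset]:
        """Leaf sets of internal edges, canonicalised against the full set."""
        universe = frozenset(self.leaves())
        parts = set()

        def walk(node, top):
            for c in node.children:
                if c.children:
                    side = frozenset(c.leaves())
                    parts.add(_canonical(side, universe))
                    walk(c, False)

        walk(self, True)
        return {p for p in parts if 1 < len(p) < len(universe) - 1}

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths through the tree."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def build(node):
            nid = id(node)
            names[nid] = node.name
            adj.setdefault(nid, [])
            for c in node.children:
                cid = build(c)
                adj[nid].append((cid, c.length))
                adj[cid].append((nid, c.length))
            return nid

        build(self)
        leaves = [nid for nid, nbrs in adj.items()
                  if len(nbrs) == 1 and names[nid] is not None]
        out = {}
        for start in leaves:
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other in leaves:
                if names[start] < names[other]:
                    out[(names[start], names[other])] = dist[other]
        return out


def _canonical(side: frozenset, universe: frozenset) -> frozenset:
    anchor = min(universe)
    return side if anchor not in side else universe - side


def nj_tree(dm: DistanceMatrix) -> Clade:
    """Saitou–Nei neighbor joining; exact on additive matrices."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [Clade(name=l) for l in dm.labels]
    D = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _floor(li, dm.labels, i), _floor(lj, dm.labels, j)
        nodes[i].length, nodes[j].length = li, lj
        parent = Clade(children=[nodes[i], nodes[j]])
        # distances from the new node to the rest
        for ak in active:
            if ak in (i, j):
                continue
            D[i, ak] = D[ak, i] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    # closed-form lengths for the final trifurcation
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = _floor(length, dm.labels, idx)
    return Clade(children=[nodes[a], nodes[b], nodes[c]])


def _floor(length: float, labels, idx) -> float:
    if length < 0:
        logger.info("negative branch length %.4f floored to 0 near %s",
                    length, labels[idx] if idx < len(labels) else "internal")
        return 0.0
    return length


def bootstrap_support(msa: dict[str, str], n_reps: int = 1000, seed: int = 0,
                      collapse: float = 50.0) -> Clade:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement; support is the percentage of
    replicate trees containing each internal bipartition of the reference
    tree.  Replicates whose resampled distances are undefined (p = 1) are
    skipped with a log message.
    """
    labels, arr = _encode_msa(msa)
    width = arr.shape[1]
    if width < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj_tree(distance_matrix(msa))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    done = 0
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        try:
            rep = nj_tree(distance_matrix(msa, columns=cols))
        except ValueError as e:
            logger.info("bootstrap replicate skipped: %s", e)
            continue
        done += 1
        for part in rep.bipartitions():
            counts[part] = counts.get(part, 0) + 1

    universe = frozenset(labels)

    def annotate(node):
        for c in node.children:
            if c.children:
                side = _canonical(frozenset(c.leaves()), universe)
                if 1 < len(side) < len(universe) - 1:
                    c.support = 100.0 * counts.get(side, 0) / max(done, 1)
                annotate(c)

    annotate(tree)
    return tree
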