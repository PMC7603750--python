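"""Neighbour-joining trees over the query and its representatives.

One tree is built per analyzed residue from that residue's
representative set; leaves are annotated with residue presence and the
tree is serialized to Newick.  Distances are uncorrected p-distances on
mutually ungapped columns — the homologs are pre-filtered for high
similarity, where p-distance is monotone with model-corrected
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, MultipleAlignment
from .seqio import ConCysFindError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ConCysFindError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ConCysFindError("distance matrix is asymmetric")
        if np.any(np.diag(self.d) != 0):
            raise ConCysFindError("distance matrix diagonal must be zero")


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]


def p_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise mismatch fraction over columns where both rows carry a
    residue; a pair with zero comparable columns is a degenerate-pair
    error."""
    rows = msa.rows
    if len(rows) < 2:
        raise ConCysFindError("p-distance needs at least two rows")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(rows[i][1], rows[j][1]):
                if a != GAP and b != GAP:
                    comparable += 1
                    if a != b:
                        mismatch += 1
            if comparable == 0:
                raise ConCysFindError(
                    f"rows {rows[i][0]!r} and {rows[j][0]!r} share no aligned residues")
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(labels=tuple(label for label, _ in rows), d=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic neighbour joining (Q-criterion, Studier-Keppler update).

    Deterministic: the joined pair minimizes Q, ties broken by the
    lexicographically smallest (min-leaf-label, max-leaf-label) pair.
    Negative branch-length estimates are clamped to zero with a warning.
    """
    n = len(dm.labels)
    if n < 2:
        raise ConCysFindError("neighbour joining needs at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    keys: list[str] = list(dm.labels)  # smallest leaf label within each subtree
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 2:
        N = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (N - 2) * d[i, j] - r[i] - r[j]
                pair_key = (min(keys[i], keys[j]), max(keys[i], keys[j]))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (N - 2))
        bj = d[i, j] - bi
        parent = TreeNode(children=[(nodes[i], clamp(bi)), (nodes[j], clamp(bj))])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        u = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    # final join: the remaining edge; split evenly so the tree is
    # symmetric (path length between the two subtrees equals d[i, j])
    half = clamp(d[i, j]) / 2.0
    root = TreeNode(children=[(nodes[i], half), (nodes[j], half)])
    return PhyloTree(root=root)


def _newick(node: TreeNode) -> str:
    if not node.children:
        return node.name or ""
    inner = ",".join(f"{_newick(c)}:{format(ln, '.10g')}" for c, ln in node.children)
    return f"({inner}){node.name or ''}"


def serialize_newick(tree: PhyloTree) -> str:
    """Newick string with branch lengths, ';'-terminated."""
    return _newick(tree.root) + ";"


def annotate_and_serialize(tree: PhyloTree, presence: dict[str, bool],
                           position: int, target_aa: str = "C") -> str:
    """Append a presence marker (e.g. ``|C126+`` / ``|C126-``) to every
    leaf label and serialize.  Leaf labels are ``species|accession``;
    the query leaf (``query|...``) is always marked present.  A species
    without a presence flag is an error."""
    marker = f"{target_aa}{position}"
    annotated_root = _annotate(tree.root, presence, marker)
    return _newick(annotated_root) + ";"


def _annotate(node: TreeNode, presence: dict[str, bool], marker: str) -> TreeNode:
    if not node.children:
        species = node.name.split("|")[0]
        if species == "query":
            flag = True
        elif species in presence:
            flag = presence[species]
        else:
            raise ConCysFindError(f"no presence flag for species {species!r}")
        return TreeNode(name=f"{node.name}|{marker}{'+' if flag else '-'}")
    return TreeNode(children=[(_annotate(c, presence, marker), ln)
                              for c, ln in node.children])
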