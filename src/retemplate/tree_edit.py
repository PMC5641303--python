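"""Ordered tree edit distance between secondary structures.

A nested structure maps to a rooted ordered tree in the full representation:
every base pair becomes an internal ``P`` node, every unpaired position a
``U`` leaf, all hanging under a virtual ``R`` root.  The distance is the
minimum-cost sequence of node deletions, insertions and relabelings
(Zhang–Shasha algorithm).

Costs follow RNAdistance's full-structure mode, the reference tool for this
metric: deleting or inserting a ``U`` leaf costs 1, a ``P`` node costs 2 (a
pair involves two bases), and relabeling between different labels costs the
sum of the indel costs (so a ``P``/``U`` swap is never cheaper than an
explicit delete+insert).  Distances are integers and are not normalised by
structure size.  This reproduces the RNAdistance binary's output exactly
(validated in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .rna_io import SecondaryStructure, StructureError

__all__ = ["TreeNode", "to_tree", "tree_edit_distance"]

_INDEL_COST = {"R": 10**9, "P": 2, "U": 1}


@dataclass
class TreeNode:
    """Node of the structure tree: label 'R' (root), 'P' (pair) or 'U' (unpaired)."""

    label: str
    children: list["TreeNode"] = field(default_factory=list)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)


def to_tree(s: SecondaryStructure) -> TreeNode:
    """Full-representation tree of a nested structure (virtual root included)."""
    if not s.is_nested:
        raise StructureError("tree representation requires a nested structure")
    root = TreeNode("R")
    stack = [root]
    for i in range(s.length):
        j = s.partner(i)
        if j == -1:
            stack[-1].children.append(TreeNode("U"))
        elif j > i:
            node = TreeNode("P")
            stack[-1].children.append(node)
            stack.append(node)
        else:
            stack.pop()
    return root


def _indel(label: str) -> int:
    return _INDEL_COST[label]


def _relabel(a: str, b: str) -> int:
    return 0 if a == b else _INDEL_COST[a] + _INDEL_COST[b]


def _postorder(root: TreeNode) -> tuple[list[str], list[int]]:
    """Labels in postorder and, per node, the index of its leftmost leaf."""
    labels: list[str] = []
    lml: list[int] = []

    def walk(node: TreeNode) -> int:
        first = None
        for c in node.children:
            idx = walk(c)
            if first is None:
                first = lml[idx]
        my = len(labels)
        labels.append(node.label)
        lml.append(first if first is not None else my)
        return my

    walk(root)
    return labels, lml


def _keyroots(lml: list[int]) -> list[int]:
    seen: set[int] = set()
    roots: list[int] = []
    for i in range(len(lml) - 1, -1, -1):
        if lml[i] not in seen:
            roots.append(i)
            seen.add(lml[i])
    return sorted(roots)


def tree_edit_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Zhang–Shasha distance between the full trees of two nested structures."""
    return tree_distance(to_tree(a), to_tree(b))


def tree_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Zhang–Shasha ordered tree edit distance between two label trees."""
    l1, lml1 = _postorder(t1)
    l2, lml2 = _postorder(t2)
    n1, n2 = len(l1), len(l2)
    kr1, kr2 = _keyroots(lml1), _keyroots(lml2)
    td = [[0] * n2 for _ in range(n1)]

    for i in kr1:
        li = lml1[i]
        for j in kr2:
            lj = lml2[j]
            # forest distance over subforests l1[li..i], l2[lj..j]
            w, h = i - li + 2, j - lj + 2
            fd = [[0] * h for _ in range(w)]
            for x in range(1, w):
                fd[x][0] = fd[x - 1][0] + _indel(l1[li + x - 1])
            for y in range(1, h):
                fd[0][y] = fd[0][y - 1] + _indel(l2[lj + y - 1])
            for x in range(1, w):
                node1 = li + x - 1
                for y in range(1, h):
                    node2 = lj + y - 1
                    if lml1[node1] == li and lml2[node2] == lj:
                        fd[x][y] = min(
                            fd[x - 1][y] + _indel(l1[node1]),
                            fd[x][y - 1] + _indel(l2[node2]),
                            fd[x - 1][y - 1] + _relabel(l1[node1], l2[node2]),
                        )
                        td[node1][node2] = fd[x][y]
                    else:
                        xo = lml1[node1] - li
                        yo = lml2[node2] - lj
                        fd[x][y] = min(
                            fd[x - 1][y] + _indel(l1[node1]),
                            fd[x][y - 1] + _indel(l2[node2]),
                            fd[xo][yo] + td[node1][node2],
                        )
    return td[n1 - 1][n2 - 1]
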