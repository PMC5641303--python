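"""Dinucleotide-preserving sequence shuffling (Altschul–Erickson).

The shuffle draws uniformly from the set of sequences with exactly the
original's dinucleotide multiset.  In graph terms the sequence is an Eulerian
walk on the multigraph whose vertices are the four bases and whose edges are
the observed dinucleotides; a uniform random Eulerian walk with the same
start is produced by randomising the edge orderings and accepting them when
the designated last-out edges of the non-terminal vertices form an
arborescence into the terminal vertex.  First and last residues are always
preserved.
"""

from __future__ import annotations

import numpy as np

from .rna_io import RnaSequence

__all__ = ["dinucleotide_shuffle"]


def dinucleotide_shuffle(
    seq: RnaSequence | str, rng: np.random.Generator
) -> RnaSequence:
    """Return a uniform dinucleotide-preserving shuffle of ``seq``."""
    s = seq.residues if isinstance(seq, RnaSequence) else str(seq)
    name = seq.identifier if isinstance(seq, RnaSequence) else "seq"
    if len(s) < 2:
        raise ValueError("dinucleotide shuffle needs a sequence of length >= 2")

    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    root = s[-1]
    vertices = sorted(edges)  # every non-terminal vertex has out-edges

    # choose last-out edges for non-root vertices until they form a tree to root
    while True:
        last: dict[str, str] = {}
        for v in vertices:
            if v == root:
                continue
            outs = edges[v]
            last[v] = outs[int(rng.integers(len(outs)))]
        if _reaches_root(last, root):
            break

    # randomly order the remaining edges, append the reserved last edge
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        outs = list(edges[v])
        if v in last:
            outs.remove(last[v])
        perm = rng.permutation(len(outs))
        outs = [outs[i] for i in perm]
        if v in last:
            outs.append(last[v])
        ordered[v] = outs

    # Eulerian walk from the original start
    counters = {v: 0 for v in ordered}
    walk = [s[0]]
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = ordered[cur][counters[cur]]
        counters[cur] += 1
        walk.append(nxt)
        cur = nxt
    out = "".join(walk)
    return RnaSequence(f"{name}|shuffled", out)


def _reaches_root(last: dict[str, str], root: str) -> bool:
    for v in last:
        seen = {v}
        cur = v
        while cur != root:
            cur = last.get(cur)
            if cur is None or cur in seen:
                return False
            seen.add(cur)
    return True
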