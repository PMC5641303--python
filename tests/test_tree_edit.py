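"""Tree edit distance: representation, oracle agreement, metric axioms.

The independent oracle is a plain recursive forest edit distance with the
same cost model; the production code is Zhang–Shasha.  Both use the
RNAdistance full-representation costs (U indel 1, P indel 2), which the
suite additionally cross-checks against the RNAdistance binary when present.
"""

import functools
import shutil
import subprocess

import numpy as np
import pytest

from retemplate import parse_dot_bracket, random_nested_structure, to_dot_bracket, to_tree, tree_edit_distance
from retemplate.rna_io import StructureError

COST = {"R": 10**9, "P": 2, "U": 1}


def oracle_distance(a, b):
    """Recursive forest edit distance (memoised), independent of Zhang–Shasha."""

    def freeze(node):
        return (node.label, tuple(freeze(c) for c in node.children))

    @functools.lru_cache(maxsize=None)
    def forest(f1, f2):
        if not f1 and not f2:
            return 0
        if not f1:
            return sum(cost_tree(t) for t in f2)
        if not f2:
            return sum(cost_tree(t) for t in f1)
        (l1, c1), rest1 = f1[-1], f1[:-1]
        (l2, c2), rest2 = f2[-1], f2[:-1]
        options = [
            forest(rest1 + c1, f2) + COST[l1],          # delete root of last tree in f1
            forest(f1, rest2 + c2) + COST[l2],          # insert root of last tree in f2
            forest(rest1, rest2)
            + forest(c1, c2)
            + (0 if l1 == l2 else COST[l1] + COST[l2]),  # match/relabel
        ]
        return min(options)

    @functools.lru_cache(maxsize=None)
    def cost_tree(t):
        label, children = t
        return COST[label] + sum(cost_tree(c) for c in children)

    return forest((freeze(to_tree(a)),), (freeze(to_tree(b)),))


def all_structures_up_to(max_len, min_loop=3):
    """Every dot-bracket structure (min hairpin loop 3) up to max_len."""
    out = []
    for n in range(1, max_len + 1):
        frontier = [("", ())]  # (prefix, stack of open positions)
        for pos in range(n):
            nxt = []
            remaining = n - pos
            for prefix, stack in frontier:
                nxt.append((prefix + ".", stack))
                if remaining > len(stack) + 1:  # room to close everything
                    nxt.append((prefix + "(", stack + (pos,)))
                if stack and pos - stack[-1] > min_loop:
                    nxt.append((prefix + ")", stack[:-1]))
            frontier = nxt
        out.extend(parse_dot_bracket(p) for p, stack in frontier if not stack)
    return out


class TestTreeRepresentation:
    def test_single_hairpin_tree(self):
        root = to_tree(parse_dot_bracket("(...)"))
        assert root.label == "R"
        (p,) = root.children
        assert p.label == "P"
        assert [c.label for c in p.children] == ["U", "U", "U"]

    def test_single_base(self):
        root = to_tree(parse_dot_bracket("."))
        assert [c.label for c in root.children] == ["U"]

    def test_nested_pair_with_interleaved_unpaired(self):
        root = to_tree(parse_dot_bracket("(.(.).)"))
        (outer,) = root.children
        assert [c.label for c in outer.children] == ["U", "P", "U"]

    def test_node_count(self, random_structures):
        for s in random_structures[:20]:
            assert to_tree(s).size() == len(s.pairs) + (
                s.length - 2 * len(s.pairs)
            ) + 1

    def test_pseudoknot_rejected(self):
        from retemplate import SecondaryStructure

        with pytest.raises(StructureError):
            to_tree(SecondaryStructure.from_pairs(4, [(0, 2), (1, 3)]))


class TestDistance:
    def test_identity(self, random_structures):
        for s in random_structures[:10]:
            assert tree_edit_distance(s, s) == 0

    def test_known_small_values(self):
        # values verified against the RNAdistance binary (full representation)
        a, b = parse_dot_bracket("(...)"), parse_dot_bracket(".....")
        assert tree_edit_distance(a, b) == 4  # delete P (2) + insert 2 U
        assert tree_edit_distance(parse_dot_bracket("((...))"), a) == 2
        assert tree_edit_distance(parse_dot_bracket("(....)"), a) == 1

    def test_exhaustive_oracle_agreement_small(self):
        structures = all_structures_up_to(7)
        for a in structures:
            for b in structures:
                assert tree_edit_distance(a, b) == oracle_distance(a, b)

    def test_oracle_agreement_random_length_10(self):
        rng = np.random.default_rng(13)
        pool = [random_nested_structure(10, rng, 2.0) for _ in range(25)]
        for a in pool:
            for b in pool:
                assert tree_edit_distance(a, b) == oracle_distance(a, b)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(29)
        for _ in range(40):
            n = int(rng.integers(5, 41))
            a = random_nested_structure(n, rng)
            b = random_nested_structure(int(rng.integers(5, 41)), rng)
            c = random_nested_structure(int(rng.integers(5, 41)), rng)
            dab = tree_edit_distance(a, b)
            assert dab >= 0
            assert tree_edit_distance(b, a) == dab
            assert dab <= tree_edit_distance(a, c) + tree_edit_distance(c, b)
            if a == b:
                assert dab == 0

    def test_distance_zero_implies_identical_shape(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            a = random_nested_structure(20, rng)
            b = random_nested_structure(20, rng)
            if tree_edit_distance(a, b) == 0:
                assert a == b


@pytest.mark.skipif(shutil.which("RNAdistance") is None, reason="RNAdistance not on PATH")
def test_agreement_with_rnadistance_binary():
    """Non-gating cross-check against the reference implementation."""
    rng = np.random.default_rng(41)
    pairs = []
    for _ in range(25):
        a = random_nested_structure(int(rng.integers(5, 60)), rng)
        b = random_nested_structure(int(rng.integers(5, 60)), rng)
        pairs.append((a, b))
    stdin = "".join(f"{to_dot_bracket(a)}\n{to_dot_bracket(b)}\n" for a, b in pairs)
    out = subprocess.run(
        ["RNAdistance"], input=stdin, capture_output=True, text=True, check=True
    ).stdout.split()
    reported = [int(tok) for tok in out if tok != "f:"]
    assert reported == [tree_edit_distance(a, b) for a, b in pairs]
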