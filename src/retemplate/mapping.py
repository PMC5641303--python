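"""Transfer of the template structure onto the query: the intermediate structure.

For each query position ``p`` with image ``r = A_q(p)`` in the template there
are four possibilities:

1. ``r`` is a gap (the query position has no template counterpart);
2. ``r`` is unpaired in the template structure;
3. ``r`` is paired to ``r'`` but its mate has no query counterpart
   (``A_t(r')`` is a gap) or the mapped residues do not form a canonical pair;
4. ``r`` is paired to ``r'``, ``A_t(r')`` exists, and the query residues at
   ``p`` and ``A_t(r')`` form a canonical pair.

Only case 4 yields a pair in the intermediate structure (``p`` with
``A_t(r')``); cases 1-3 leave ``p`` unpaired.  Cases 2 and 4 are *consistent*,
cases 1 and 3 *inconsistent*; these flags drive the element-level
re-prediction decision later on.

Canonical pairs are Watson-Crick A·U and G·C plus the G·U wobble — the pair
set the downstream folding engines accept.  ``N`` never pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import PairwiseAlignment
from .rna_io import RnaSequence, SecondaryStructure

__all__ = ["is_canonical", "IntermediateStructure", "build_intermediate"]

_CANONICAL = {
    frozenset("AU"),
    frozenset("GC"),
    frozenset("GU"),
}

CASE_GAP = 1
CASE_UNPAIRED = 2
CASE_BROKEN_PAIR = 3
CASE_PAIR = 4


def is_canonical(a: str, b: str) -> bool:
    """True iff residues a, b can form a canonical (WC or wobble) base pair."""
    return frozenset((a, b)) in _CANONICAL


@dataclass(frozen=True)
class IntermediateStructure:
    """Template structure mapped onto the query, with per-position bookkeeping.

    ``cases[p]`` is the mapping case (1-4) of query position ``p``;
    ``consistent[p]`` is derived from it (cases 2 and 4).  ``structure``
    contains exactly the case-4 pairs.
    """

    structure: SecondaryStructure
    cases: tuple[int, ...]
    query: RnaSequence
    consistent: tuple[bool, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "consistent",
            tuple(c in (CASE_UNPAIRED, CASE_PAIR) for c in self.cases),
        )

    def render(self) -> str:
        """Three-line debug dump: sequence, dot-bracket, case digits."""
        from .rna_io import to_dot_bracket

        return "\n".join(
            (
                self.query.residues,
                to_dot_bracket(self.structure),
                "".join(str(c) for c in self.cases),
            )
        )


def build_intermediate(
    template_structure: SecondaryStructure,
    aln: PairwiseAlignment,
    query: RnaSequence,
) -> IntermediateStructure:
    """Apply the four-case rule per query position.

    The template structure must be nested and live on the template sequence of
    ``aln``.  No pair is invented: every pair in the output is the image of a
    template pair whose both ends map and whose query residues are canonical.
    """
    if template_structure.length != len(aln.a_t):
        raise ValueError(
            f"template structure length {template_structure.length} does not "
            f"match aligned template length {len(aln.a_t)}"
        )
    if not template_structure.is_nested:
        raise ValueError("template structure must be nested (remove pseudoknots)")
    if len(query) != len(aln.a_q):
        raise ValueError("query length does not match alignment")

    n = len(query)
    cases = [CASE_GAP] * n
    pairs: list[tuple[int, int]] = []
    for p in range(n):
        r = aln.a_q[p]
        if r is None:
            cases[p] = CASE_GAP
            continue
        r2 = template_structure.partner(r)
        if r2 == -1:
            cases[p] = CASE_UNPAIRED
            continue
        mate = aln.a_t[r2]
        if mate is None or not is_canonical(query[p], query[mate]):
            cases[p] = CASE_BROKEN_PAIR
        else:
            cases[p] = CASE_PAIR
            if p < mate:
                pairs.append((p, mate))
    structure = SecondaryStructure.from_pairs(n, pairs)
    return IntermediateStructure(structure, tuple(cases), query)
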