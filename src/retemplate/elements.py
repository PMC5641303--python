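"""Decomposition of a nested structure into elementary elements.

Two element types exist:

* **Hairpin** — seeded at a loop-closing pair (a pair with only unpaired
  positions between its ends) and extended outward pair-by-pair, through
  internal loops and bulges, for as long as the enclosing pair still encloses
  only this hairpin.  Extension stops below a multiloop junction.  All
  unpaired positions between the hairpin's pairs belong to it, and unpaired
  runs flanking the outermost pair are attached per the sharing rule below.

* **Stem** — claims the remaining pairs: maximal helix chains (bulges
  allowed) that enclose more than one hairpin, processed outermost-first.
  Stems own their pairing positions only; they are never extended with
  single-stranded neighbours.

Sharing rule for an unpaired run between two hairpins: split at the midpoint,
left half (including the middle position when the run length is odd) to the
upstream hairpin.  A run with a hairpin neighbour on exactly one side
(the other side being a stem position or a sequence end) goes entirely to
that hairpin.  Runs with no hairpin neighbour (e.g. multiloop cores between
stems) stay unassigned; they are carried into the final structure as
unpaired and never trigger re-prediction.

Decomposition depends only on the pair table, never on sequence content.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rna_io import SecondaryStructure, StructureError

__all__ = ["Hairpin", "Stem", "Decomposition", "find_hairpins", "find_stems", "decompose"]


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop: contiguous span, its pairs, and the loop-closing pair."""

    span: tuple[int, int]  # inclusive 0-based interval
    member_pairs: tuple[tuple[int, int], ...]
    loop_pair: tuple[int, int]
    positions: frozenset[int]  # owned positions (paired + attached unpaired)

    @property
    def kind(self) -> str:
        return "hairpin"


@dataclass(frozen=True)
class Stem:
    """A two-strand helix bridging distal regions; owns pairing positions only."""

    strand5: tuple[int, int]  # inclusive interval of 5' pairing positions
    strand3: tuple[int, int]
    member_pairs: tuple[tuple[int, int], ...]
    positions: frozenset[int]

    @property
    def kind(self) -> str:
        return "stem"


@dataclass(frozen=True)
class Decomposition:
    """Hairpins + stems + the per-position ownership table.

    ``assignment[p]`` is the index into ``elements`` of the element owning
    position ``p``, or -1 for unassigned single-strand positions.
    """

    structure: SecondaryStructure
    hairpins: tuple[Hairpin, ...]
    stems: tuple[Stem, ...]
    assignment: tuple[int, ...]

    @property
    def elements(self) -> tuple:
        return self.hairpins + self.stems


def _pair_children(s: SecondaryStructure) -> dict[tuple[int, int] | None, list[tuple[int, int]]]:
    """Direct nesting tree of the pairs (None = virtual root)."""
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int] | None] = [None]
    for i in range(s.length):
        j = s.partner(i)
        if j > i:
            pair = (i, j)
            children[stack[-1]].append(pair)
            children[pair] = []
            stack.append(pair)
        elif j != -1:
            stack.pop()
    return children


def find_hairpins(s: SecondaryStructure) -> list[Hairpin]:
    """Identify hairpins: loop-closing pairs extended up to (not into) junctions."""
    if not s.is_nested:
        raise StructureError("decomposition requires a nested structure")
    children = _pair_children(s)
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    for par, kids in children.items():
        for kid in kids:
            parent[kid] = par

    hairpins: list[Hairpin] = []
    loop_pairs = [p for p in sorted(parent) if not children[p]]
    for loop in loop_pairs:
        member = [loop]
        top = loop
        while True:
            par = parent[top]
            if par is None or len(children[par]) != 1:
                break  # junction (or exterior): the enclosing pair is not ours
            member.append(par)
            top = par
        outer = member[-1]
        positions = set(range(outer[0], outer[1] + 1))
        hairpins.append(
            Hairpin(
                span=(outer[0], outer[1]),
                member_pairs=tuple(sorted(member)),
                loop_pair=loop,
                positions=frozenset(positions),
            )
        )
    hairpins.sort(key=lambda h: h.span)
    return _attach_flanks(s, hairpins)


def _attach_flanks(s: SecondaryStructure, hairpins: list[Hairpin]) -> list[Hairpin]:
    """Attach unpaired runs flanking hairpin spans per the sharing rule."""
    if not hairpins:
        return hairpins
    owner = {}
    for idx, h in enumerate(hairpins):
        for p in h.positions:
            owner[p] = idx
    extra: dict[int, set[int]] = {i: set() for i in range(len(hairpins))}

    n = s.length
    i = 0
    while i < n:
        if s.is_paired(i) or i in owner:
            i += 1
            continue
        j = i
        while j + 1 < n and not s.is_paired(j + 1) and (j + 1) not in owner:
            j += 1
        run = range(i, j + 1)
        left = owner.get(i - 1) if i - 1 >= 0 and (i - 1) in owner else None
        right = owner.get(j + 1) if j + 1 < n and (j + 1) in owner else None
        # only a hairpin whose outermost pair abuts the run counts as neighbour
        if left is not None and hairpins[left].span[1] != i - 1:
            left = None
        if right is not None and hairpins[right].span[0] != j + 1:
            right = None
        if left is not None and right is not None and left != right:
            mid = i + (len(run) + 1) // 2  # left half incl. middle -> upstream
            extra[left].update(range(i, mid))
            extra[right].update(range(mid, j + 1))
        elif left is not None and right is None:
            extra[left].update(run)
        elif right is not None and left is None:
            extra[right].update(run)
        # no hairpin neighbour (e.g. multiloop core between stems): unassigned
        i = j + 1

    out = []
    for idx, h in enumerate(hairpins):
        pos = frozenset(h.positions | extra[idx])
        out.append(
            Hairpin(
                span=(min(pos), max(pos)),
                member_pairs=h.member_pairs,
                loop_pair=h.loop_pair,
                positions=pos,
            )
        )
    return out


def find_stems(s: SecondaryStructure, hairpins: list[Hairpin]) -> list[Stem]:
    """Group the pairs not claimed by hairpins into stems, outermost-first.

    Each stem starts at the unclaimed pair with the smallest opening position
    and extends inward pair-by-pair (skipping unpaired positions) until a pair
    belonging to a hairpin or a pair connecting to a different branch is met.
    """
    hairpin_pairs = {p for h in hairpins for p in h.member_pairs}
    taken = set(hairpin_pairs)
    remaining = sorted(p for p in s.pairs if p not in taken)
    stems: list[Stem] = []
    for start in remaining:
        if start in taken:
            continue
        a, b = start
        member = [start]
        taken.add(start)
        a, b = a + 1, b - 1
        while a < b:
            while a < b and not s.is_paired(a):
                a += 1
            while a < b and not s.is_paired(b):
                b -= 1
            if a >= b or s.partner(a) != b or (a, b) in taken:
                break
            member.append((a, b))
            taken.add((a, b))
            a, b = a + 1, b - 1
        fives = [p[0] for p in member]
        threes = [p[1] for p in member]
        stems.append(
            Stem(
                strand5=(min(fives), max(fives)),
                strand3=(min(threes), max(threes)),
                member_pairs=tuple(sorted(member)),
                positions=frozenset(fives + threes),
            )
        )
    stems.sort(key=lambda st: st.strand5)
    return stems


def decompose(s: SecondaryStructure) -> Decomposition:
    """Full decomposition; every paired position ends up in exactly one element."""
    hairpins = tuple(find_hairpins(s))
    stems = tuple(find_stems(s, list(hairpins)))
    assignment = [-1] * s.length
    for idx, el in enumerate(hairpins + stems):
        for p in el.positions:
            if assignment[p] != -1:
                raise AssertionError(f"position {p} owned by two elements")
            assignment[p] = idx
    for p in range(s.length):
        if s.is_paired(p) and assignment[p] == -1:
            raise AssertionError(f"paired position {p} not owned by any element")
    return Decomposition(s, hairpins, stems, tuple(assignment))
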