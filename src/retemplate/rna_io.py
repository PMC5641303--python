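"""Sequences, pair tables and the standard text formats that carry them.

The whole pipeline speaks two in-memory types: :class:`RnaSequence` (a
normalised RNA string with a label) and :class:`SecondaryStructure` (an
immutable pair table).  Dot-bracket strings, FASTA, Vienna sequence+structure
records and CT files are parsed into / serialised from these types here and
nowhere else.

Coordinates are 0-based everywhere inside the package; human-facing reports
(CLI output, CT files) use 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "StructureError",
    "parse_dot_bracket",
    "to_dot_bracket",
    "remove_pseudoknots",
    "read_fasta",
    "read_vienna",
    "write_vienna",
    "read_ct",
]

#: residues accepted on input (case-insensitive); everything is stored as ACGUN
_INPUT_ALPHABET = set("ACGUTN")
_BRACKET_TIERS = ("()", "[]", "{}", "<>")
_OPEN = {t[0]: t for t in _BRACKET_TIERS}
_CLOSE = {t[1]: t for t in _BRACKET_TIERS}


class StructureError(ValueError):
    """Raised for malformed structures or sequence/structure records."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with an identifier.

    Residues are normalised on construction: upper-cased and DNA-style T
    converted to U.  Characters outside ``A C G U T N`` (any case) are
    rejected.  ``N`` is accepted and treated as unpairable downstream.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        bad = set(norm) - set("ACGUN")
        if bad:
            raise StructureError(
                f"sequence {self.identifier!r} contains invalid residues: "
                f"{sorted(bad)}"
            )
        if not norm:
            raise StructureError(f"sequence {self.identifier!r} is empty")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pair table: ``length`` positions, each in at most one pair.

    ``pairs`` holds 0-based ``(i, j)`` tuples with ``i < j``.  The structure
    may contain pseudoknots (crossing pairs); :func:`to_dot_bracket` and the
    tree-edit machinery require a nested structure, obtainable with
    :func:`remove_pseudoknots`.
    """

    length: int
    pairs: frozenset[tuple[int, int]]
    # partner[i] = j if (i,j) or (j,i) is a pair, else -1; derived, cached
    _partner: tuple[int, ...] = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        partner = [-1] * self.length
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise StructureError(f"pair ({i}, {j}) out of range or unordered")
            if partner[i] != -1 or partner[j] != -1:
                raise StructureError(
                    f"position {i if partner[i] != -1 else j} occurs in two pairs"
                )
            partner[i] = j
            partner[j] = i
        object.__setattr__(self, "_partner", tuple(partner))

    @classmethod
    def from_pairs(cls, length: int, pairs: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        return cls(length, frozenset((min(i, j), max(i, j)) for i, j in pairs))

    def partner(self, i: int) -> int:
        """Partner of position ``i``, or -1 if unpaired."""
        return self._partner[i]

    @property
    def partner_table(self) -> tuple[int, ...]:
        return self._partner

    def is_paired(self, i: int) -> bool:
        return self._partner[i] != -1

    @property
    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    @property
    def is_nested(self) -> bool:
        """True iff no two pairs cross (i < k < j < l)."""
        stack: list[int] = []
        for i in range(self.length):
            j = self._partner[i]
            if j > i:
                stack.append(j)
            elif j != -1:  # closing
                if not stack or stack[-1] != i:
                    return False
                stack.pop()
        return not stack


def parse_dot_bracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a pair table.

    The primary tier is ``()``; pseudoknot tiers ``[] {} <>`` are accepted on
    input.  Unbalanced brackets raise :class:`StructureError` naming the
    offending position (0-based).
    """
    stacks: dict[str, list[int]] = {t: [] for t in _BRACKET_TIERS}
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise StructureError(
                    f"unbalanced {ch!r} at position {pos}: no matching opener"
                )
            pairs.append((stack.pop(), pos))
        else:
            raise StructureError(f"invalid structure character {ch!r} at position {pos}")
    for stack in stacks.values():
        if stack:
            raise StructureError(
                f"unbalanced bracket at position {stack[0]}: never closed"
            )
    return SecondaryStructure.from_pairs(len(text), pairs)


def to_dot_bracket(s: SecondaryStructure) -> str:
    """Serialise a nested structure; inverse of :func:`parse_dot_bracket`."""
    if not s.is_nested:
        raise StructureError(
            "structure contains pseudoknots; apply remove_pseudoknots() first"
        )
    out = ["."] * s.length
    for i, j in s.pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def remove_pseudoknots(s: SecondaryStructure) -> SecondaryStructure:
    """Return a nested structure keeping a maximum crossing-free pair subset.

    Dynamic programming over intervals (Nussinov-style on the existing pair
    set).  Ties are broken deterministically by preferring to keep the pair
    with the smaller opening index.  The input is not modified.
    """
    if s.is_nested:
        return s
    n = s.length
    partner = s._partner
    # best[(i, j)] = max pairs retainable inside [i, j]; keep[(i, j)] = True if
    # the pair (i, partner[i]) is used in the optimum for that interval.
    best: dict[tuple[int, int], int] = {}
    keep: dict[tuple[int, int], bool] = {}

    def get(i: int, j: int) -> int:
        return best.get((i, j), 0) if i <= j else 0

    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            skip = get(i + 1, j)
            k = partner[i]
            use = -1
            if i < k <= j:
                use = 1 + get(i + 1, k - 1) + get(k + 1, j)
            if use >= skip:  # tie -> keep pair with smaller opening index
                best[(i, j)] = use
                keep[(i, j)] = True
            else:
                best[(i, j)] = skip
                keep[(i, j)] = False

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if keep.get((i, j), False):
            k = partner[i]
            pairs.append((i, k))
            stack.append((i + 1, k - 1))
            stack.append((k + 1, j))
        else:
            stack.append((i + 1, j))
    return SecondaryStructure.from_pairs(n, pairs)


# ---------------------------------------------------------------------------
# file formats

def read_fasta(source) -> list[RnaSequence]:
    """Read a (multi-)FASTA file or handle into normalised RNA sequences."""
    handle = source if hasattr(source, "read") else open(source)
    records = [
        RnaSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")
    ]
    if handle is not source:
        handle.close()
    if not records:
        raise StructureError("no FASTA records found")
    return records


def read_vienna(source) -> list[tuple[RnaSequence, SecondaryStructure]]:
    """Read Vienna-style records: FASTA header, sequence line(s), structure line(s).

    Sequence and dot-bracket parts may each span several lines; their total
    lengths must match.
    """
    handle = source if hasattr(source, "read") else open(source)
    try:
        lines = [ln.strip() for ln in handle if ln.strip()]
    finally:
        if handle is not source:
            handle.close()
    records: list[tuple[RnaSequence, SecondaryStructure]] = []
    i = 0
    struct_chars = set(".()[]{}<>")
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected FASTA header, got {lines[i]!r}")
        name = lines[i][1:].split()[0] if lines[i][1:].split() else lines[i][1:]
        i += 1
        seq_parts: list[str] = []
        while i < len(lines) and not lines[i].startswith(">") and not set(lines[i]) <= struct_chars:
            seq_parts.append(lines[i])
            i += 1
        db_parts: list[str] = []
        while i < len(lines) and set(lines[i]) <= struct_chars and lines[i]:
            db_parts.append(lines[i])
            i += 1
        if not seq_parts or not db_parts:
            raise StructureError(f"record {name!r}: missing sequence or structure")
        seq = RnaSequence(name, "".join(seq_parts))
        struct = parse_dot_bracket("".join(db_parts))
        if struct.length != len(seq):
            raise StructureError(
                f"record {name!r}: structure length {struct.length} != "
                f"sequence length {len(seq)}"
            )
        records.append((seq, struct))
    if not records:
        raise StructureError("no Vienna records found")
    return records


def write_vienna(
    records: Sequence[tuple[RnaSequence, SecondaryStructure]], handle: TextIO
) -> None:
    for seq, struct in records:
        handle.write(f">{seq.identifier}\n{seq.residues}\n{to_dot_bracket(struct)}\n")


def read_ct(source) -> list[tuple[RnaSequence, SecondaryStructure]]:
    """Read a CT (connect) file, the common carrier of experimental structures.

    Columns: index, base, prev, next, partner (0 = unpaired), index again.
    Multiple concatenated records are supported.
    """
    handle = source if hasattr(source, "read") else open(source)
    try:
        lines = [ln for ln in (l.strip() for l in handle) if ln]
    finally:
        if handle is not source:
            handle.close()
    records: list[tuple[RnaSequence, SecondaryStructure]] = []
    i = 0
    while i < len(lines):
        head = lines[i].split()
        try:
            n = int(head[0])
        except (ValueError, IndexError):
            raise StructureError(f"bad CT header line: {lines[i]!r}")
        title = " ".join(head[1:]) or f"ct_record_{len(records)}"
        body = lines[i + 1 : i + 1 + n]
        if len(body) < n:
            raise StructureError(f"CT record {title!r}: expected {n} rows")
        residues: list[str] = []
        pairs: list[tuple[int, int]] = []
        for row in body:
            f = row.split()
            idx, base, part = int(f[0]), f[1], int(f[4])
            residues.append(base)
            if part > idx:  # record each pair once, convert to 0-based
                pairs.append((idx - 1, part - 1))
        seq = RnaSequence(title, "".join(residues))
        records.append((seq, SecondaryStructure.from_pairs(n, pairs)))
        i += 1 + n
    if not records:
        raise StructureError("no CT records found")
    return records
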