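"""Synthetic template/query homolog pairs for hermetic testing.

Real benchmark families come with experimentally determined structures; this
module emulates the essentials so every pipeline stage can be exercised
without external data: a random nested structure, a template sequence that
realises it with canonical pairs, and a diverged homolog with controllable
substitution, indel and compensatory-mutation rates.

Divergence model: each position mutates independently at ``substitution_rate``.
At a paired position the substitution is *compensatory* with probability
``compensatory_fraction`` — the pair is redrawn as a fresh canonical pair
type, preserving pairing potential — otherwise the single base is replaced at
random (usually breaking the pair).  Indels occur at ``indel_rate`` per
position, single-position events extended geometrically (p = 0.5), insertions
and deletions equally likely; pair members are never both deleted.  No
phylogeny and no rate matrix — the generator controls exactly the quantities
the mapping and consistency stages respond to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rna_io import RnaSequence, SecondaryStructure

__all__ = [
    "HomologSpec",
    "random_nested_structure",
    "make_template",
    "mutate_homolog",
    "random_sequence",
]

_BASES = "ACGU"
_PAIR_TYPES = ("AU", "UA", "GC", "CG", "GU", "UG")
MIN_LOOP = 3


@dataclass(frozen=True)
class HomologSpec:
    """Divergence parameters for :func:`mutate_homolog` (all rates in [0, 1])."""

    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    compensatory_fraction: float = 0.8

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "compensatory_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def random_nested_structure(
    length: int,
    rng: np.random.Generator,
    pair_attempts_per_nt: float = 1.0,
    stack_continue_prob: float = 0.75,
) -> SecondaryStructure:
    """A random nested structure with minimum hairpin loop 3.

    Candidate pairs (i, j) are proposed uniformly and accepted when they
    neither reuse a position nor cross an accepted pair; each accepted pair
    is stacked outward and inward into a helix with geometrically distributed
    run length (continuation probability ``stack_continue_prob``).  The
    defaults give ~55% paired positions on average with helices of mean
    length 4 — in the range of real structured RNAs (tRNA, 5S rRNA).
    """
    partner = [-1] * length
    pairs: list[tuple[int, int]] = []

    def crosses(i: int, j: int) -> bool:
        return any((a < i < b) != (a < j < b) for a, b in pairs)

    attempts = int(length * pair_attempts_per_nt)
    for _ in range(attempts):
        i = int(rng.integers(0, max(1, length - MIN_LOOP - 1)))
        j = int(rng.integers(i + MIN_LOOP + 1, length))
        if partner[i] != -1 or partner[j] != -1 or crosses(i, j):
            continue
        pairs.append((i, j))
        partner[i], partner[j] = j, i
        for di, dj in ((-1, 1), (1, -1)):  # stack outward, then inward
            a, b = i, j
            while True:
                a, b = a + di, b + dj
                if not (0 <= a < length and 0 <= b < length and b - a - 1 >= MIN_LOOP):
                    break
                if partner[a] != -1 or partner[b] != -1 or crosses(a, b):
                    break
                if rng.random() > stack_continue_prob:
                    break
                pairs.append((a, b))
                partner[a], partner[b] = b, a
    return SecondaryStructure.from_pairs(length, pairs)


def make_template(
    structure: SecondaryStructure, rng: np.random.Generator, identifier: str = "template"
) -> RnaSequence:
    """A sequence realising ``structure`` with a canonical pair at every pair."""
    residues = [""] * structure.length
    for i, j in structure.sorted_pairs:
        a, b = _PAIR_TYPES[int(rng.integers(len(_PAIR_TYPES)))]
        residues[i], residues[j] = a, b
    for p in range(structure.length):
        if not residues[p]:
            residues[p] = _BASES[int(rng.integers(4))]
    return RnaSequence(identifier, "".join(residues))


def random_sequence(
    length: int, rng: np.random.Generator, identifier: str = "random"
) -> RnaSequence:
    return RnaSequence(
        identifier, "".join(_BASES[int(k)] for k in rng.integers(0, 4, size=length))
    )


def mutate_homolog(
    template: RnaSequence,
    structure: SecondaryStructure,
    spec: HomologSpec,
    rng: np.random.Generator,
    identifier: str = "homolog",
) -> RnaSequence:
    """Diverge ``template`` according to ``spec``; returns the query sequence."""
    residues = list(template.residues)
    n = len(residues)

    # substitutions; paired sites may be compensatory (pair redrawn canonically)
    handled: set[int] = set()
    for p in range(n):
        if p in handled or rng.random() >= spec.substitution_rate:
            continue
        q = structure.partner(p)
        if q != -1 and rng.random() < spec.compensatory_fraction:
            a, b = _PAIR_TYPES[int(rng.integers(len(_PAIR_TYPES)))]
            i, j = (p, q) if p < q else (q, p)
            residues[i], residues[j] = a, b
            handled.update((p, q))
        else:
            old = residues[p]
            choices = [b for b in _BASES if b != old]
            residues[p] = choices[int(rng.integers(3))]
            handled.add(p)

    # indels: single-position events with geometric extension (p = 0.5);
    # deletions skip paired positions whose partner is already deleted
    deleted: set[int] = set()
    inserts: dict[int, str] = {}
    for p in range(n):
        if rng.random() >= spec.indel_rate:
            continue
        size = 1 + int(rng.geometric(0.5) - 1)
        if rng.random() < 0.5:  # deletion starting at p
            for q in range(p, min(n, p + size)):
                mate = structure.partner(q)
                if mate != -1 and mate in deleted:
                    continue
                deleted.add(q)
        else:  # insertion after p
            ins = "".join(_BASES[int(k)] for k in rng.integers(0, 4, size=size))
            inserts[p] = inserts.get(p, "") + ins

    out: list[str] = []
    for p in range(n):
        if p not in deleted:
            out.append(residues[p])
        if p in inserts:
            out.append(inserts[p])
    seq = "".join(out)
    if not seq:  # pathological all-deleted case
        seq = residues[0]
    return RnaSequence(identifier, seq)
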