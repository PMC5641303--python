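"""Element-level consistency calls.

An element is *inconsistent* when the fraction of its owned positions flagged
inconsistent by the template mapping is strictly over the threshold for its
type: 20% for hairpins, 10% for stems (the published operating point; both
are configurable).  The denominator is the element's owned position count —
paired positions plus, for hairpins, the attached unpaired positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .elements import Decomposition
from .mapping import IntermediateStructure

__all__ = ["Thresholds", "ElementLabel", "classify"]


@dataclass(frozen=True)
class Thresholds:
    """Maximum tolerated inconsistent-position fractions, by element type."""

    hairpin: float = 0.20
    stem: float = 0.10

    def __post_init__(self) -> None:
        for name, v in (("hairpin", self.hairpin), ("stem", self.stem)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} threshold must be in [0, 1], got {v}")

    def for_kind(self, kind: str) -> float:
        return self.hairpin if kind == "hairpin" else self.stem


@dataclass(frozen=True)
class ElementLabel:
    """Consistency verdict for one element of a decomposition."""

    element_index: int
    kind: str
    inconsistent_fraction: float
    inconsistent: bool


def classify(
    d: Decomposition,
    im: IntermediateStructure,
    thresholds: Thresholds = Thresholds(),
) -> list[ElementLabel]:
    """Label every element of ``d`` using the per-position flags of ``im``.

    ``d`` must have been computed from ``im.structure``.
    """
    if d.structure.length != im.structure.length:
        raise ValueError("decomposition and intermediate structure lengths differ")
    labels: list[ElementLabel] = []
    for idx, el in enumerate(d.elements):
        owned = el.positions
        assert owned, "element with zero owned positions cannot be constructed"
        bad = sum(1 for p in owned if not im.consistent[p])
        frac = bad / len(owned)
        labels.append(
            ElementLabel(
                element_index=idx,
                kind=el.kind,
                inconsistent_fraction=frac,
                inconsistent=frac > thresholds.for_kind(el.kind),
            )
        )
    return labels
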