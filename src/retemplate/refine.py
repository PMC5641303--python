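"""De-novo re-prediction of inconsistent elements and final assembly.

Consistent elements keep their template-transferred pairing verbatim.
Inconsistent hairpins are re-folded as single strands over their contiguous
span (attached unpaired positions included); inconsistent stems are re-folded
as a two-strand duplex over their strand intervals.  Because element spans
are disjoint and nested, splicing the local predictions back into the global
coordinate system always yields a valid nested pair table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .alignment import AlignmentParams, PairwiseAlignment, align
from .consistency import ElementLabel, Thresholds, classify
from .elements import Decomposition, Hairpin, Stem, decompose
from .engines import FoldingEngine, NussinovEngine
from .mapping import IntermediateStructure, build_intermediate
from .rna_io import RnaSequence, SecondaryStructure, remove_pseudoknots

__all__ = ["GeneratedStructure", "refine_element", "assemble", "generate"]

log = logging.getLogger(__name__)

TEMPLATE_TRANSFER = "template-transfer"
DE_NOVO = "de-novo"
SINGLE_STRAND = "single-strand"


@dataclass(frozen=True)
class GeneratedStructure:
    """The generated query structure plus per-position provenance.

    ``provenance[p]`` records whether position ``p`` was copied from the
    template (inside a consistent element), re-predicted de novo (inside an
    inconsistent element) or carried as unassigned single strand.  The
    intermediate stages are attached for reporting.
    """

    structure: SecondaryStructure
    provenance: tuple[str, ...]
    alignment: PairwiseAlignment | None = None
    intermediate: IntermediateStructure | None = None
    decomposition: Decomposition | None = None
    labels: tuple[ElementLabel, ...] | None = None


def refine_element(
    el: Hairpin | Stem, query: RnaSequence, engine: FoldingEngine
) -> list[tuple[int, int]]:
    """De-novo fold one inconsistent element; pairs returned in global coordinates.

    Hairpins go through ``fold_single`` on their contiguous subsequence;
    stems through ``fold_duplex`` on their two strand subsequences.
    """
    try:
        if isinstance(el, Hairpin):
            lo, hi = min(el.positions), max(el.positions)
            local, _ = engine.fold_single(query.residues[lo : hi + 1])
            return [(lo + i, lo + j) for i, j in local.pairs]
        lo5, hi5 = el.strand5
        lo3, hi3 = el.strand3
        duplex, _ = engine.fold_duplex(
            query.residues[lo5 : hi5 + 1], query.residues[lo3 : hi3 + 1]
        )
        return [(lo5 + i, lo3 + j) for i, j in duplex]
    except Exception as exc:
        raise RuntimeError(
            f"folding engine failed on {el.kind} at {getattr(el, 'span', (el.strand5, el.strand3))}: {exc}"
        ) from exc


def assemble(
    im: IntermediateStructure,
    d: Decomposition,
    labels: list[ElementLabel],
    refined: dict[int, list[tuple[int, int]]],
) -> GeneratedStructure:
    """Combine kept and re-predicted element structures into the final structure."""
    pairs: list[tuple[int, int]] = []
    provenance = [SINGLE_STRAND] * im.structure.length
    for label, el in zip(labels, d.elements):
        tag = DE_NOVO if label.inconsistent else TEMPLATE_TRANSFER
        for p in el.positions:
            provenance[p] = tag
        if label.inconsistent:
            if label.element_index not in refined:
                raise ValueError(
                    f"no refined structure supplied for inconsistent element "
                    f"{label.element_index} ({el.kind})"
                )
            for i, j in refined[label.element_index]:
                pairs.append((i, j))
                # stem duplexes may pair bulge positions outside the owned set
                provenance[i] = provenance[j] = tag
        else:
            pairs.extend(el.member_pairs)
    structure = SecondaryStructure.from_pairs(im.structure.length, pairs)
    assert structure.is_nested, "assembled structure must be nested"
    return GeneratedStructure(structure, tuple(provenance), None, im, d, tuple(labels))


def generate(
    query: RnaSequence,
    template_seq: RnaSequence,
    template_struct: SecondaryStructure,
    *,
    engine: FoldingEngine | None = None,
    thresholds: Thresholds = Thresholds(),
    alignment_params: AlignmentParams = AlignmentParams(),
    alignment: PairwiseAlignment | None = None,
    remove_pk: bool = True,
) -> GeneratedStructure:
    """Full pipeline: align, map, decompose, classify, refine, assemble.

    A precomputed ``alignment`` (e.g. from ClustalW2) may be supplied to skip
    the built-in aligner.  A pseudoknotted template is reduced to its maximum
    nested pair subset when ``remove_pk`` is true.  A structure is produced
    for *any* input; reliability of the result is the bootstrap's business.
    """
    engine = engine or NussinovEngine()
    if not template_struct.is_nested:
        if not remove_pk:
            raise ValueError("template structure is pseudoknotted")
        template_struct = remove_pseudoknots(template_struct)
        log.info("removed pseudoknots from template structure")

    try:
        aln = alignment or align(query, template_seq, alignment_params)
    except Exception as exc:
        raise RuntimeError(f"alignment stage failed: {exc}") from exc
    im = build_intermediate(template_struct, aln, query)
    d = decompose(im.structure)
    labels = classify(d, im, thresholds)
    refined = {
        lab.element_index: refine_element(d.elements[lab.element_index], query, engine)
        for lab in labels
        if lab.inconsistent
    }
    result = assemble(im, d, labels, refined)
    return GeneratedStructure(
        result.structure, result.provenance, aln, im, d, tuple(labels)
    )
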