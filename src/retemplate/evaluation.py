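"""Scoring generated structures against references; cross-validation protocol.

Two metrics: tree edit distance (see :mod:`retemplate.tree_edit`) and the
percentage of nucleotide positions with correctly predicted structural
information.  A position is correct when its pairing status matches the
reference and, if paired, the partner index matches too — under this strict
reading 100% is equivalent to structural identity (distance 0).

Cross-validation: within each RNA family with at least two members carrying
experimental structures, every ordered (template, query) pair with distinct
members yields one prediction, scored against the query's experimental
structure (a family of k members gives k·(k−1) records).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bootstrap import bootstrap
from .consistency import Thresholds
from .engines import FoldingEngine, NussinovEngine
from .refine import generate
from .rna_io import RnaSequence, SecondaryStructure
from .tree_edit import tree_edit_distance

__all__ = ["EvaluationRecord", "percent_correct", "cross_validate", "records_to_frame"]

log = logging.getLogger(__name__)

FamilyMembers = Sequence[tuple[RnaSequence, SecondaryStructure]]


@dataclass(frozen=True)
class EvaluationRecord:
    """One cross-validation prediction and its scores."""

    family: str
    query_id: str
    template_id: str
    tree_edit_distance: int
    percent_correct_positions: float
    z_d: float | None = None
    reliable: bool | None = None


def percent_correct(
    predicted: SecondaryStructure, reference: SecondaryStructure
) -> float:
    """Percent of positions with correct structural information (0-100).

    Both structures must live on the same sequence (equal lengths).
    """
    if predicted.length != reference.length:
        raise ValueError(
            f"structures have different lengths: {predicted.length} vs "
            f"{reference.length}"
        )
    same = sum(
        1
        for p in range(predicted.length)
        if predicted.partner(p) == reference.partner(p)
    )
    return 100.0 * same / predicted.length


def cross_validate(
    families: Mapping[str, FamilyMembers],
    *,
    engine: FoldingEngine | None = None,
    thresholds: Thresholds = Thresholds(),
    bootstrap_n: int = 0,
    rng: np.random.Generator | int | None = None,
) -> list[EvaluationRecord]:
    """All-vs-all within-family predictions, scored against experiment.

    ``bootstrap_n > 0`` additionally runs the shuffle bootstrap per prediction
    and records ``z_d`` and the reliability verdict.  Families with fewer than
    two members are skipped with a warning.
    """
    engine = engine or NussinovEngine()
    rng = np.random.default_rng(rng)
    records: list[EvaluationRecord] = []
    for name, members in families.items():
        if len(members) < 2:
            log.warning("family %r has fewer than 2 members; skipped", name)
            continue
        for t_seq, t_struct in members:
            for q_seq, q_struct in members:
                if q_seq.identifier == t_seq.identifier:
                    continue
                gen = generate(
                    q_seq, t_seq, t_struct, engine=engine, thresholds=thresholds
                )
                z_d = reliable = None
                if bootstrap_n > 0:
                    bres = bootstrap(
                        q_seq,
                        t_seq,
                        t_struct,
                        engine=engine,
                        n=bootstrap_n,
                        rng=rng,
                        thresholds=thresholds,
                    )
                    z_d, reliable = bres.z_d, bres.reliable
                records.append(
                    EvaluationRecord(
                        family=name,
                        query_id=q_seq.identifier,
                        template_id=t_seq.identifier,
                        tree_edit_distance=tree_edit_distance(gen.structure, q_struct),
                        percent_correct_positions=percent_correct(
                            gen.structure, q_struct
                        ),
                        z_d=z_d,
                        reliable=reliable,
                    )
                )
    return records


def records_to_frame(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
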