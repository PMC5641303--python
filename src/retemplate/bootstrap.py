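"""Reliability assessment of a generated structure by a shuffle bootstrap.

The pipeline produces a structure for *any* input, including a template that
is unrelated to the query.  To flag such spurious transfers, the query is
dinucleotide-shuffled N times (default 100), each shuffle is run through the
identical generation pipeline, and two statistics of the generated structure
are standardised against the resulting null sample:

* ``d``: tree edit distance between the generated structure and the template
  structure (the primary decision metric);
* ``e``: free energy of the generated structure on its sequence.

The z-scores are oriented so that *better than the null* is positive:
``z = (mean(null) - observed) / sd(null)`` for both metrics (a homologous
query sits closer to the template and at lower energy than shuffled
sequences).  A structure is called reliable when ``z_d >= 2``, roughly the
one-sided 5% significance point.  ``sd`` is the sample standard deviation
(n−1 denominator).  A degenerate null (zero spread) yields undefined
z-scores and an unreliable verdict, flagged explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentParams
from .consistency import Thresholds
from .engines import FoldingEngine, NussinovEngine
from .refine import GeneratedStructure, generate
from .rna_io import RnaSequence, SecondaryStructure
from .shuffle import dinucleotide_shuffle
from .tree_edit import tree_edit_distance

__all__ = ["BootstrapResult", "RepeatedBootstrapResult", "bootstrap", "repeated_bootstrap"]

RELIABILITY_Z = 2.0


@dataclass(frozen=True)
class BootstrapResult:
    """Null distributions and z-scores for one bootstrap run."""

    d_gen: float
    e_gen: float
    d_rnd: tuple[float, ...]
    e_rnd: tuple[float, ...]
    z_d: float  # NaN when the null is degenerate
    z_e: float
    reliable: bool
    degenerate_null: bool
    generated: GeneratedStructure

    def summary(self) -> dict:
        return {
            "d_gen": self.d_gen,
            "e_gen": self.e_gen,
            "z_d": self.z_d,
            "z_e": self.z_e,
            "reliable": self.reliable,
            "degenerate_null": self.degenerate_null,
            "null_d_mean": float(np.mean(self.d_rnd)),
            "null_d_sd": float(np.std(self.d_rnd, ddof=1)) if len(self.d_rnd) > 1 else 0.0,
            "null_e_mean": float(np.mean(self.e_rnd)),
            "null_e_sd": float(np.std(self.e_rnd, ddof=1)) if len(self.e_rnd) > 1 else 0.0,
            "n": len(self.d_rnd),
        }


@dataclass(frozen=True)
class RepeatedBootstrapResult:
    """z-scores across independent bootstrap runs."""

    z_d: tuple[float, ...]
    z_e: tuple[float, ...]
    fraction_reliable: float


def _z(observed: float, null: np.ndarray) -> float:
    sd = float(np.std(null, ddof=1))
    if sd == 0.0 or math.isnan(sd):
        return float("nan")
    return float((np.mean(null) - observed) / sd)


def bootstrap(
    query: RnaSequence,
    template_seq: RnaSequence,
    template_struct: SecondaryStructure,
    *,
    engine: FoldingEngine | None = None,
    n: int = 100,
    rng: np.random.Generator | int | None = None,
    thresholds: Thresholds = Thresholds(),
    alignment_params: AlignmentParams = AlignmentParams(),
) -> BootstrapResult:
    """Run the generation pipeline on the query and on ``n`` shuffles of it."""
    if n < 1:
        raise ValueError("bootstrap needs n >= 1 shuffled sequences")
    engine = engine or NussinovEngine()
    rng = np.random.default_rng(rng)

    kwargs = dict(
        engine=engine, thresholds=thresholds, alignment_params=alignment_params
    )
    gen = generate(query, template_seq, template_struct, **kwargs)
    d_gen = float(tree_edit_distance(gen.structure, template_struct))
    e_gen = float(engine.energy_of(query.residues, gen.structure))

    d_rnd: list[float] = []
    e_rnd: list[float] = []
    for _ in range(n):
        shuffled = dinucleotide_shuffle(query, rng)
        g = generate(shuffled, template_seq, template_struct, **kwargs)
        d_rnd.append(float(tree_edit_distance(g.structure, template_struct)))
        e_rnd.append(float(engine.energy_of(shuffled.residues, g.structure)))

    d_arr, e_arr = np.asarray(d_rnd), np.asarray(e_rnd)
    z_d, z_e = _z(d_gen, d_arr), _z(e_gen, e_arr)
    degenerate = math.isnan(z_d)
    reliable = (not degenerate) and z_d >= RELIABILITY_Z
    return BootstrapResult(
        d_gen, e_gen, tuple(d_rnd), tuple(e_rnd), z_d, z_e, reliable, degenerate, gen
    )


def repeated_bootstrap(
    query: RnaSequence,
    template_seq: RnaSequence,
    template_struct: SecondaryStructure,
    *,
    runs: int = 100,
    n: int = 100,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> RepeatedBootstrapResult:
    """Repeat the bootstrap to gauge the spread of the z-scores themselves."""
    if runs < 1:
        raise ValueError("repeated bootstrap needs runs >= 1")
    rng = np.random.default_rng(rng)
    z_d: list[float] = []
    z_e: list[float] = []
    hits = 0
    for _ in range(runs):
        res = bootstrap(
            query, template_seq, template_struct, n=n, rng=rng, **kwargs
        )
        z_d.append(res.z_d)
        z_e.append(res.z_e)
        hits += int(res.reliable)
    return RepeatedBootstrapResult(tuple(z_d), tuple(z_e), hits / runs)
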