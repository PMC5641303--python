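"""Query/template pairwise alignment and the two position maps.

The alignment is consumed downstream only through two functions: ``A_q``
(query position -> template position or gap) and ``A_t`` (template -> query).
The built-in aligner is a global Needleman-Wunsch/Gotoh with affine gaps,
parameterised like the ClustalW2 run the method was designed around:
GAPOPEN = 7, GAPEXT = 0.5, nucleotide match score 1.9, mismatch 0 (U scored
as T-equivalent).  A gap of length L costs ``open + extend * L``.

An adapter for an external ``clustalw2`` binary is provided for users who
want byte-identical ClustalW alignments; it produces the same
:class:`PairwiseAlignment` type.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rna_io import RnaSequence

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "align",
    "maps_from_aligned",
    "align_clustalw",
    "ConfigurationError",
]

GAP = None  # sentinel used in the position maps


class ConfigurationError(RuntimeError):
    """An external backend was requested but is not usable."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for the built-in affine-gap aligner (ClustalW2-style defaults)."""

    gap_open: float = 7.0
    gap_extend: float = 0.5
    match: float = 1.9
    mismatch: float = 0.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global query/template alignment plus its two position maps.

    ``a_q[p]`` is the template position aligned to query position ``p`` (or
    ``None`` for a gap); ``a_t`` is the inverse map.  Where both are defined
    they are mutually inverse: ``a_t[a_q[p]] == p``.
    """

    aligned_query: str
    aligned_template: str
    a_q: tuple = field(repr=False)
    a_t: tuple = field(repr=False)
    score: float | None = None

    def query_to_template(self, p: int):
        return self.a_q[p]

    def template_to_query(self, r: int):
        return self.a_t[r]

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def template(self) -> str:
        return self.aligned_template.replace("-", "")


def maps_from_aligned(
    aligned_query: str, aligned_template: str, score: float | None = None
) -> PairwiseAlignment:
    """Build the position maps from two gapped strings (columns read left to right).

    Lets users supply a precomputed alignment (e.g. from ClustalW2) instead of
    the built-in aligner.
    """
    if len(aligned_query) != len(aligned_template):
        raise ValueError(
            f"aligned strings differ in length: {len(aligned_query)} vs "
            f"{len(aligned_template)}"
        )
    a_q: list = []
    a_t: list = []
    for col, (cq, ct) in enumerate(zip(aligned_query, aligned_template)):
        if cq == "-" and ct == "-":
            raise ValueError(f"column {col} is all-gap")
        if cq != "-":
            a_q.append(len(a_t) if ct != "-" else GAP)
        if ct != "-":
            a_t.append(len(a_q) - 1 if cq != "-" else GAP)
    return PairwiseAlignment(
        aligned_query, aligned_template, tuple(a_q), tuple(a_t), score
    )


def align(
    query: RnaSequence | str,
    template: RnaSequence | str,
    params: AlignmentParams = AlignmentParams(),
) -> PairwiseAlignment:
    """Globally align query and template with affine gap costs (Gotoh).

    Traceback is deterministic: on ties, diagonal is preferred over a gap in
    the template (up) over a gap in the query (left).
    """
    q = query.residues if isinstance(query, RnaSequence) else str(query)
    t = template.residues if isinstance(template, RnaSequence) else str(template)
    if not q or not t:
        raise ValueError("cannot align empty sequences")

    n, m = len(q), len(t)
    neg = -1e30
    open_cost = params.gap_open + params.gap_extend  # first gap position
    ext = params.gap_extend

    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    sub = np.where(ta[None, :] == qa[:, None], params.match, params.mismatch)

    # M: q[i-1]~t[j-1] aligned; X: gap in template (query residue unmatched,
    # vertical move); Y: gap in query (horizontal move).
    M = np.full(m + 1, neg)
    X = np.full(m + 1, neg)
    Y = np.full(m + 1, neg)
    M[0] = 0.0
    Y[1:] = -(params.gap_open + ext * np.arange(1, m + 1))
    # pointers: for each matrix, which matrix the optimum came from (0=M,1=X,2=Y)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    # leading-gap chain along row 0: stay in Y until the origin
    if m >= 1:
        ptrY[0, 1] = 0
        ptrY[0, 2:] = 2

    for i in range(1, n + 1):
        prevM, prevX, prevY = M, X, Y
        M = np.full(m + 1, neg)
        X = np.empty(m + 1)
        Y = np.full(m + 1, neg)

        # X: vertical move (consume q[i-1]); from previous row, same column
        cand = np.vstack((prevM - open_cost, prevX - ext, prevY - open_cost))
        ptrX[i] = np.argmax(cand, axis=0)
        X = cand[ptrX[i], np.arange(m + 1)]

        # M: diagonal from previous row, previous column
        diag = np.vstack((prevM[:-1], prevX[:-1], prevY[:-1]))
        ptrM[i, 1:] = np.argmax(diag, axis=0)
        M[1:] = diag[ptrM[i, 1:], np.arange(m)] + sub[i - 1]

        # Y: horizontal move (consume t[j-1]); sequential within the row
        for j in range(1, m + 1):
            candy = (M[j - 1] - open_cost, X[j - 1] - open_cost, Y[j - 1] - ext)
            k = int(np.argmax(candy))
            ptrY[i, j] = k
            Y[j] = candy[k]

    finals = (M[m], X[m], Y[m])
    state = int(np.argmax(finals))
    score = float(finals[state])

    aq_parts: list[str] = []
    at_parts: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            aq_parts.append(q[i - 1])
            at_parts.append(t[j - 1])
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            aq_parts.append(q[i - 1])
            at_parts.append("-")
            state = int(ptrX[i, j])
            i -= 1
        else:
            aq_parts.append("-")
            at_parts.append(t[j - 1])
            state = int(ptrY[i, j])
            j -= 1
    return maps_from_aligned("".join(reversed(aq_parts)), "".join(reversed(at_parts)), score)


def align_clustalw(
    query: RnaSequence,
    template: RnaSequence,
    executable: str = "clustalw2",
    gap_open: float = 7.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Align with an external ClustalW2 binary (optional backend).

    Raises :class:`ConfigurationError` when the executable is not on PATH.
    """
    exe = shutil.which(executable)
    if exe is None:
        raise ConfigurationError(
            f"ClustalW backend requested but executable {executable!r} was not "
            "found on PATH; install ClustalW2 or use the built-in aligner"
        )
    from Bio import AlignIO

    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        out = Path(tmp) / "out.aln"
        fasta.write_text(
            f">query\n{query.residues}\n>template\n{template.residues}\n"
        )
        subprocess.run(
            [
                exe,
                f"-INFILE={fasta}",
                f"-OUTFILE={out}",
                "-OUTPUT=CLUSTAL",
                "-TYPE=DNA",
                f"-GAPOPEN={gap_open}",
                f"-GAPEXT={gap_extend}",
            ],
            check=True,
            capture_output=True,
        )
        aln = AlignIO.read(str(out), "clustal")
    rows = {rec.id: str(rec.seq).upper().replace("T", "U") for rec in aln}
    return maps_from_aligned(rows["query"], rows["template"])
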