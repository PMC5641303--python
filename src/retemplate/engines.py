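"""Folding engines used to re-predict inconsistent elements.

Two interchangeable implementations of the :class:`FoldingEngine` contract:

* :class:`ViennaEngine` — production engine, backed by the ViennaRNA Python
  bindings with RNAfold (single-sequence MFE), RNAduplex (two-strand duplex)
  and RNAeval (free energy of a given structure) semantics.  Energies are in
  kcal/mol.

* :class:`NussinovEngine` — deterministic, dependency-free engine: maximum
  canonical base pairing with a minimum hairpin loop of 3, duplex as maximum
  antiparallel canonical matching, and energy −1 per pair.  It keeps the full
  pipeline and its tests hermetic and bit-reproducible.

``fold_duplex`` returns pairs as ``(i, j)`` with ``i`` indexing the 5' strand
and ``j`` the 3' strand, both 0-based and local to the strands.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

from .mapping import is_canonical
from .rna_io import SecondaryStructure, parse_dot_bracket, to_dot_bracket

__all__ = ["FoldingEngine", "NussinovEngine", "ViennaEngine", "get_engine"]

DuplexPairs = list[tuple[int, int]]


class FoldingEngine(ABC):
    """Contract for the de-novo prediction backends."""

    name: str = "abstract"

    @abstractmethod
    def fold_single(self, seq: str) -> tuple[SecondaryStructure, float]:
        """MFE-style structure and energy for a single strand."""

    @abstractmethod
    def fold_duplex(self, seq5: str, seq3: str) -> tuple[DuplexPairs, float]:
        """Best inter-strand pairing between two strands (no intra-strand pairs)."""

    @abstractmethod
    def energy_of(self, seq: str, structure: SecondaryStructure) -> float:
        """Free energy of a given structure on a given sequence (deterministic)."""


class NussinovEngine(FoldingEngine):
    """Maximum canonical pairing (min loop 3); energy = −1 per pair."""

    name = "stub"
    min_loop = 3

    def fold_single(self, seq: str) -> tuple[SecondaryStructure, float]:
        n = len(seq)
        # best[i][j] = max pairs in seq[i..j]
        best = [[0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                b = best[i + 1][j]  # i unpaired
                # pair i with some k; prefer larger k on ties (deterministic)
                for k in range(j, i + self.min_loop, -1):
                    if is_canonical(seq[i], seq[k]):
                        cand = 1 + (best[i + 1][k - 1] if k - 1 > i else 0)
                        cand += best[k + 1][j] if k + 1 <= j else 0
                        if cand > b:
                            b = cand
                best[i][j] = b
        pairs: list[tuple[int, int]] = []
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or best[i][j] == 0:
                continue
            done = False
            for k in range(j, i + self.min_loop, -1):
                if is_canonical(seq[i], seq[k]):
                    cand = 1 + (best[i + 1][k - 1] if k - 1 > i else 0)
                    cand += best[k + 1][j] if k + 1 <= j else 0
                    if cand == best[i][j]:
                        pairs.append((i, k))
                        stack.append((i + 1, k - 1))
                        stack.append((k + 1, j))
                        done = True
                        break
            if not done:
                stack.append((i + 1, j))
        s = SecondaryStructure.from_pairs(n, pairs)
        return s, -float(len(pairs))

    def fold_duplex(self, seq5: str, seq3: str) -> tuple[DuplexPairs, float]:
        # maximum non-crossing antiparallel matching: LCS-style DP between
        # seq5 and reversed(seq3) with canonical-pair matches
        t = seq3[::-1]
        n, m = len(seq5), len(t)
        L = [[0] * (m + 1) for _ in range(n + 1)]
        for i in range(1, n + 1):
            for k in range(1, m + 1):
                L[i][k] = max(
                    L[i - 1][k],
                    L[i][k - 1],
                    L[i - 1][k - 1] + (1 if is_canonical(seq5[i - 1], t[k - 1]) else 0),
                )
        pairs: DuplexPairs = []
        i, k = n, m
        while i > 0 and k > 0:
            if (
                is_canonical(seq5[i - 1], t[k - 1])
                and L[i][k] == L[i - 1][k - 1] + 1
            ):
                pairs.append((i - 1, len(seq3) - k))
                i, k = i - 1, k - 1
            elif L[i - 1][k] >= L[i][k - 1]:  # prefer advancing the 5' strand
                i -= 1
            else:
                k -= 1
        pairs.reverse()
        return pairs, -float(len(pairs))

    def energy_of(self, seq: str, structure: SecondaryStructure) -> float:
        return -float(len(structure.pairs))


class ViennaEngine(FoldingEngine):
    """RNAfold / RNAduplex / RNAeval via the ViennaRNA Python bindings."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "the 'vienna' engine needs the ViennaRNA Python bindings "
                "(import RNA); install the viennarna package or use the stub engine"
            ) from exc
        self._rna = RNA

    def fold_single(self, seq: str) -> tuple[SecondaryStructure, float]:
        db, mfe = self._rna.fold(seq)
        return parse_dot_bracket(db), float(mfe)

    def fold_duplex(self, seq5: str, seq3: str) -> tuple[DuplexPairs, float]:
        dup = self._rna.duplexfold(seq5, seq3)
        left, right = dup.structure.split("&")
        # dup.i: 1-based end of the binding site on seq5;
        # dup.j: 1-based start of the binding site on seq3
        start5 = dup.i - len(left)  # 0-based start of left segment
        start3 = dup.j - 1
        stack: list[int] = []
        pairs: DuplexPairs = []
        for off, ch in enumerate(left):
            if ch == "(":
                stack.append(start5 + off)
        for off, ch in enumerate(right):
            if ch == ")":
                pairs.append((stack.pop(), start3 + off))
        pairs.sort()
        return pairs, float(dup.energy)

    def energy_of(self, seq: str, structure: SecondaryStructure) -> float:
        return float(self._rna.energy_of_struct(seq, to_dot_bracket(structure)))


def get_engine(name: str) -> FoldingEngine:
    """Factory: ``"stub"`` or ``"vienna"``."""
    if name == "stub":
        return NussinovEngine()
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown folding engine {name!r} (expected 'stub' or 'vienna')")
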