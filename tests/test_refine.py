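"""De-novo refinement of inconsistent elements and final assembly."""

import numpy as np
import pytest

from retemplate import (
    NussinovEngine,
    RnaSequence,
    Thresholds,
    ViennaEngine,
    align,
    build_intermediate,
    classify,
    decompose,
    generate,
    make_template,
    parse_dot_bracket,
    random_nested_structure,
    refine_element,
    to_dot_bracket,
)
from retemplate.refine import DE_NOVO, SINGLE_STRAND, TEMPLATE_TRANSFER, assemble


def _all_nested_structures(n, min_loop=3):
    """Enumerate every nested pair set on n positions (oracle for tiny n)."""
    results = []

    def rec(free, pairs):
        results.append(frozenset(pairs))
        if not free:
            return
        i = free[0]
        rec(free[1:], pairs)
        for j in free[1:]:
            if j - i > min_loop:
                inside = [p for p in free[1:] if i < p < j]
                outside = [p for p in free[1:] if p > j]
                for s_in in _nested_on(inside, min_loop):
                    rec(outside, pairs + [(i, j)] + list(s_in))

    def _nested_on(positions, min_loop):
        subs = []

        def r2(free, pairs):
            subs.append(list(pairs))
            if not free:
                return
            i = free[0]
            r2(free[1:], pairs)
            for j in free[1:]:
                if j - i > min_loop:
                    inside = [p for p in free[1:] if i < p < j]
                    outside = [p for p in free[1:] if p > j]
                    for s_in in _nested_on(inside, min_loop):
                        r2(outside, pairs + [(i, j)] + list(s_in))

        r2(positions, [])
        return subs

    rec(list(range(n)), [])
    return set(results)


class TestNussinovEngine:
    def test_max_pairing_is_brute_force_optimal(self):
        """Stub fold reaches the enumerated maximum canonical pair count."""
        from retemplate.mapping import is_canonical

        engine = NussinovEngine()
        rng = np.random.default_rng(8)
        for _ in range(15):
            n = int(rng.integers(4, 10))
            seq = "".join("ACGU"[k] for k in rng.integers(0, 4, size=n))
            s, energy = engine.fold_single(seq)
            best = max(
                len(p)
                for p in _all_nested_structures(n)
                if all(is_canonical(seq[i], seq[j]) for i, j in p)
            )
            assert len(s.pairs) == best
            assert energy == -best
            assert s.is_nested

    def test_hairpin_example(self):
        s, _ = NussinovEngine().fold_single("GGGAAACCC")
        assert to_dot_bracket(s) == "(((...)))"

    def test_duplex_full_complement(self):
        pairs, energy = NussinovEngine().fold_duplex("GGGG", "CCCC")
        assert pairs == [(0, 3), (1, 2), (2, 1), (3, 0)]
        assert energy == -4

    def test_unpairable_sequence(self):
        s, _ = NussinovEngine().fold_single("AAAAAAA")
        assert not s.pairs


class TestViennaEngine:
    """The production engine: RNAfold/RNAduplex/RNAeval semantics."""

    def test_fold_single_matches_known_mfe(self):
        s, mfe = ViennaEngine().fold_single("GGGAAACCC")
        assert to_dot_bracket(s) == "(((...)))"
        assert mfe == pytest.approx(-1.2, abs=0.01)

    def test_duplex_returns_interstrand_pairs_only(self):
        from retemplate.mapping import is_canonical

        seq5, seq3 = "GCAGGGAU", "AUCCCAAA"
        pairs, energy = ViennaEngine().fold_duplex(seq5, seq3)
        assert pairs
        assert energy < 0
        for i, j in pairs:
            assert 0 <= i < len(seq5) and 0 <= j < len(seq3)
            assert is_canonical(seq5[i], seq3[j])

    def test_energy_of_agrees_with_fold(self):
        eng = ViennaEngine()
        s, mfe = eng.fold_single("GGGGAAAACCCC")
        assert eng.energy_of("GGGGAAAACCCC", s) == pytest.approx(mfe, abs=0.01)


class TestRefineAndAssemble:
    def test_all_consistent_keeps_intermediate(self):
        t = parse_dot_bracket("(((...)))")
        seq = RnaSequence("t", "GGGAAACCC")
        im = build_intermediate(t, align(seq, seq), seq)
        d = decompose(im.structure)
        labels = classify(d, im)
        out = assemble(im, d, labels, {})
        assert out.structure == im.structure
        assert set(out.provenance) == {TEMPLATE_TRANSFER}

    def test_broken_hairpin_is_refolded(self):
        """2/9 inconsistent positions > 20%: the hairpin is re-predicted."""
        t = parse_dot_bracket("(((...)))")
        tmpl = RnaSequence("t", "GGGAAACCC")
        q = RnaSequence("q", "GGGAAACCA")
        out = generate(q, tmpl, t, engine=NussinovEngine())
        # stub maximum pairing on the full 9-mer: (0,7),(1,6)
        assert set(out.structure.pairs) == {(0, 7), (1, 6)}
        assert set(out.provenance) == {DE_NOVO}

    def test_refine_element_reindexes_into_global_coordinates(self):
        s = parse_dot_bracket("......(((...)))")
        d = decompose(s)
        q = RnaSequence("q", "AAAAAAGGGAAACCC")
        pairs = refine_element(d.hairpins[0], q, NussinovEngine())
        assert set(pairs) == {(6, 14), (7, 13), (8, 12)}

    def test_missing_refined_element_rejected(self):
        t = parse_dot_bracket("(((...)))")
        tmpl = RnaSequence("t", "GGGAAACCC")
        q = RnaSequence("q", "GGGAAACCA")
        im = build_intermediate(t, align(q, tmpl), q)
        d = decompose(im.structure)
        labels = classify(d, im)
        assert any(l.inconsistent for l in labels)
        with pytest.raises(ValueError, match="refined"):
            assemble(im, d, labels, {})


class TestGeneratePipeline:
    def test_identity_invariant(self, random_structures):
        """generate(s, s, t) == t for fixture sequences realising t."""
        rng = np.random.default_rng(17)
        for s in random_structures[:25]:
            seq = make_template(s, rng)
            out = generate(seq, seq, s, engine=NussinovEngine())
            assert out.structure == s
            assert DE_NOVO not in out.provenance

    def test_conserved_elements_keep_template_pairing(self):
        rng = np.random.default_rng(23)
        s = random_nested_structure(80, rng)
        tmpl = make_template(s, rng)
        out = generate(tmpl, tmpl, s)
        for label, el in zip(out.labels, out.decomposition.elements):
            assert not label.inconsistent
            for i, j in el.member_pairs:
                assert out.structure.partner(i) == j

    def test_any_input_yields_a_valid_structure(self, random_structures):
        """Even unrelated random queries produce a well-formed nested result."""
        rng = np.random.default_rng(31)
        from retemplate.fixtures import random_sequence

        for s in random_structures[:10]:
            tmpl = make_template(s, rng)
            q = random_sequence(int(rng.integers(20, 140)), rng)
            out = generate(q, tmpl, s)
            assert out.structure.length == len(q)
            assert out.structure.is_nested

    def test_pseudoknotted_template_is_cleaned_or_rejected(self):
        from retemplate import SecondaryStructure

        pk = SecondaryStructure.from_pairs(12, [(0, 6), (3, 10)])
        seq = RnaSequence("t", "GGGAAACCCAAA")
        out = generate(seq, seq, pk)
        assert out.structure.is_nested
        with pytest.raises(ValueError, match="pseudoknot"):
            generate(seq, seq, pk, remove_pk=False)

    def test_thresholds_change_the_outcome(self):
        t = parse_dot_bracket("(((...)))")
        tmpl = RnaSequence("t", "GGGAAACCC")
        q = RnaSequence("q", "GGGAAACCA")
        lenient = generate(q, tmpl, t, thresholds=Thresholds(0.5, 0.5))
        assert to_dot_bracket(lenient.structure) == ".((...))."  # kept
        strict = generate(q, tmpl, t, thresholds=Thresholds(0.2, 0.1))
        assert set(strict.structure.pairs) == {(0, 7), (1, 6)}  # refolded
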