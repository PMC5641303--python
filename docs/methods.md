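# Methods

This note documents the model implemented by `retemplate`, the numerical and
design choices that were genuinely open, and what the synthetic-fixture tests
do and do not demonstrate.

## Structure representation

A secondary structure is a pair table: each position is unpaired or paired
with exactly one partner.  Coordinates are 0-based internally; all
human-facing reports (CLI output, CT files) are 1-based.  Pseudoknotted
input (extra bracket tiers `[] {} <>`) is accepted by the parsers, but the
pipeline operates on nested structures only.  `remove_pseudoknots` reduces a
crossing pair table to a maximum-cardinality crossing-free subset by interval
dynamic programming; ties are broken deterministically in favour of the pair
with the smaller opening index.  Other maximal subsets can exist — the choice
is a convention, stated here because downstream numbers depend on it.

## Alignment

The built-in aligner is a global Gotoh algorithm with affine gaps.
Parameters mirror a ClustalW2 nucleotide run with GAPOPEN = 7 and
GAPEXT = 0.5: match 1.9, mismatch 0, a gap of length L costs
`open + extend·L`, end gaps penalised.  Traceback ties resolve
diagonal > gap-in-template > gap-in-query, so alignments are deterministic.
ClustalW2 itself can be substituted via `align_clustalw` or by supplying any
precomputed alignment through `maps_from_aligned`; score-level identity with
a particular ClustalW build is not guaranteed (its internal matrix and
end-gap conventions vary by version), only parameter-level fidelity.

## Template transfer (the four cases)

For each query position `p` with template image `r = A_q(p)`:

| case | condition | intermediate | flag |
|------|-----------|--------------|------|
| 1 | `r` is a gap | unpaired | inconsistent |
| 2 | `r` unpaired in template | unpaired | consistent |
| 3 | `r` paired to `r'`, but `A_t(r')` gapped or query residues non-canonical | unpaired | inconsistent |
| 4 | `r` paired to `r'`, `A_t(r')` defined, query pair canonical | paired to `A_t(r')` | consistent |

Canonical means A·U, G·C or G·U; `N` never pairs.  The rule is evaluated
independently per position; because the maps are mutually inverse and
canonicity is symmetric, case 4 always fires for both ends of a preserved
pair, and a failed pair marks both mapped ends case 3 without any extra
propagation.  Template pairs whose two ends both map to gaps simply vanish.
No pair is invented at this stage, and since the alignment maps are
monotone, the intermediate structure is automatically nested.

## Decomposition into hairpins and stems

Hairpins are seeded at loop-closing pairs (only unpaired positions between
the ends) and extended outward pair-by-pair — through internal loops and
bulges — while the enclosing pair still encloses only that hairpin; extension
stops below multiloop junctions.  Unpaired runs flanking a hairpin's
outermost pair are attached to it; a run lying between two hairpins is split
at its midpoint, the left half (including the middle position of an
odd-length run) going to the upstream hairpin.  This includes runs at the
molecule's ends: a dangling end adjacent to a hairpin belongs to that
hairpin.  Stems claim the remaining pairs as maximal helix chains (bulges
allowed), processed outermost-first; they own pairing positions only and are
never extended with single-stranded neighbours.  Unpaired runs with no
hairpin neighbour — multiloop cores between stems — belong to no element and
are carried into the final structure unchanged.  Decomposition depends only
on the pair table; every paired position ends up in exactly one element (an
internal assertion, also exercised on 1,000 random structures).

## Consistency thresholds

An element is re-predicted when its fraction of inconsistent positions is
**strictly** greater than 0.20 (hairpins) or 0.10 (stems).  The denominator
is the element's owned position count — paired plus attached unpaired for
hairpins, paired only for stems.  The strict reading keeps elements at
exactly the boundary: a 10-position hairpin with 2 inconsistent positions is
kept, a third flips it.  Both thresholds are configurable
(`--hairpin-threshold`, `--stem-threshold`); the defaults are the published
operating point of the method and are not re-optimised here.

## Refinement engines

Two implementations of the folding contract:

* **vienna** — the production engine, via the ViennaRNA Python bindings:
  single-strand MFE folding (RNAfold), best two-strand duplex (RNAduplex,
  taken as-is, including interior loops), and free energy of a given
  structure (RNAeval), all in kcal/mol at default parameters.
* **stub** — a deterministic Nussinov maximum-canonical-pairing engine
  (minimum hairpin loop 3, tie-break pairing the leftmost position to its
  rightmost admissible partner), duplex as maximum antiparallel canonical
  matching, energy −1 per pair.  It exists so the entire pipeline, including
  the bootstrap, is exactly reproducible with no binary dependency; it is
  the default engine and the one used throughout the test suite.

Inconsistent hairpins are re-folded on their contiguous span (attached
unpaired positions included); inconsistent stems as a duplex over their two
strand intervals (bulge positions inside a strand interval may be recruited
into the new duplex).  Because element spans are disjoint and nested, the
assembled result is always a valid nested structure, whatever the engine
returns locally.  No constraint folding is used: elements are predicted
unconstrained, which is the point of the element-wise decomposition — the
fragments are small enough for de-novo prediction to be dependable.

## Tree edit distance

Structures are compared as rooted ordered trees in the full representation:
one internal `P` node per pair, one `U` leaf per unpaired base, a virtual
root.  Distances are computed with the Zhang–Shasha algorithm.  Costs follow
RNAdistance's full-structure mode, which is the reference implementation for
this metric: indel of `U` = 1, indel of `P` = 2 (a pair involves two bases),
relabel between different labels = sum of indels (never cheaper than
delete+insert).  The test suite verifies exact agreement with the
RNAdistance binary when it is on PATH, and exhaustive agreement with an
independent recursive forest-edit oracle for all structure pairs up to
length 10.  Distances are raw integers; they grow with structure size and
are not normalised, which is why the bootstrap standardises them instead of
interpreting them absolutely.

## Dinucleotide shuffle and bootstrap

Shuffles preserve the exact dinucleotide multiset (hence also length,
composition, and both terminal residues) using the Eulerian-walk method:
random last-out edges are drawn until they form an arborescence into the
terminal vertex, remaining out-edges are randomly ordered, and the walk is
read off.  This samples uniformly over all valid shuffles; for a small
8-mer test case the sampler's support provably equals the exhaustively
enumerated shuffle set.

The bootstrap reruns the full generation pipeline on the query and on `N`
shuffles (default `N = 100`).  Two statistics are standardised against the
null sample (sample standard deviation, n−1): the tree edit distance of the
generated structure to the template structure, and its free energy.  The
z-scores are oriented so that *better than the null is positive*:

    z = (mean(null) − observed) / sd(null).

With the distance written as `z_d = (d_gen − mean)/sd` a good structure
(small `d_gen`) would score negative; the orientation used here is the one
under which the reliability rule `z ≥ 2` behaves as intended — accurate
transfers score large positive `z_d`, shuffled or non-homologous queries
score near or below zero.  The decision metric is `z_d`; `z_e` is computed
and reported but is a poor discriminator because free energy is
position-independent (two very different structures with similar stacking
content have similar energies).  A degenerate null (zero spread, e.g. a
homopolymer query) yields undefined z-scores, an explicit flag, and an
unreliable verdict.  `repeated_bootstrap` reruns the whole scheme to expose
the sampling variance of the z-scores themselves.

`z_d ≥ 2` is a heuristic significance point, not a proof: for short or
sparsely paired templates the null distances are few and widely spread, and
even a perfect identity transfer can land below 2 occasionally.

## Synthetic fixtures

The generator exists so every stage is testable hermetically; it emulates
exactly the features the pipeline responds to and nothing else.

* `random_nested_structure`: uniform pair proposals with rejection of
  crossings, each accepted pair stacked into a helix with geometric run
  length (continuation 0.75).  Defaults give ≈55% paired positions and mean
  helix length 4, in the range of real structured RNAs (tRNA ≈ 62%, 5S
  ≈ 60%); minimum hairpin loop 3.
* `make_template` realises a structure with uniformly drawn canonical pair
  types and uniform unpaired residues.
* `mutate_homolog` applies per-position substitutions (default 10%), of
  which a set fraction at paired sites is compensatory (the pair is redrawn
  canonically; default 80%, typical of covarying RNA helices), plus
  single-position indels with geometric extension (p = 0.5; deletions never
  remove both members of a pair).

What passing tests on these fixtures show: the transfer, decomposition,
classification and bootstrap machinery behave correctly under controlled
divergence.  What they do not show: performance on real families, where
divergence is phylogenetically structured, indels cluster in loops,
non-canonical interactions exist, and experimental reference structures
carry their own errors.

## Problem sizes and numerical conventions

The shipped verification runs use: 200 random structures (lengths 20–120)
for identity transfer with bootstraps (N = 50) on a 10-structure subsample;
500 mapping triples; 1,000 structures for decomposition and shuffle
exactness; all structure pairs to length 10 for the tree-edit oracle; and
20 seeds × (homolog + permuted query) at N = 50 for bootstrap
discrimination — sizes chosen so the whole battery completes in minutes on
one CPU while keeping every estimate's sampling error well inside the
margins being asserted.  All randomness flows from a single seed through
`numpy.random.Generator`; seeded runs are bit-reproducible.

## Known limitations

* Single pairwise alignment: a poor alignment silently degrades the
  transfer; there is no alignment uncertainty handling.
* Pseudoknots are removed, never transferred or predicted.
* Stems re-predicted as duplexes cannot recover intra-strand pairing within
  a strand interval.
* The percent-correct metric requires both structures on the same sequence;
  cross-coordinate variants (via an alignment) are not implemented.
* Absolute tree-edit values depend on the representation and cost
  conventions above; compare distances only within one convention.
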