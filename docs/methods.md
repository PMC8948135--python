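# Methods

## Scope and data

The package analyses the mitogenome of *Polydesmus* sp. GZCS-2019 through
its published feature-annotation table (38 features on a 15,036 bp circle)
and models the rearrangement pathway from the ancestral arthropod gene
order to the derived, fully plus-strand arrangement. The real nucleotide
sequence (GenBank MZ677220) is not required: every sequence-level
computation is exercised on synthetic genomes generated from the
annotation blueprint. No phylogenetic inference, divergence dating, tRNA
structure folding or control-region motif discovery is attempted.

## Coordinates and table conventions

Feature coordinates are 1-based, fully closed intervals, as annotation
tables print them; 0-based half-open slices appear only at sequence-access
boundaries (`GeneFeature.slice0`). No feature wraps the origin. The signed
gap between consecutive-by-start features is
`downstream.start − upstream.end − 1`; negative gaps are overlaps. The
origin-spanning closing pair (here trnW → cox1, +1 bp) is carried in the
`SpacerReport` but flagged and excluded from the summary totals, because
the intergenic-length column of published tables covers only the linear
pairs — with the closing pair the identity
`Σ signed gaps + Σ feature lengths = genome length` holds exactly, and the
summary totals (351 bp / 19 regions of spacer, 27 bp / 5 overlaps) match
the published accounting.

Two published inconsistencies are resolved in favour of the coordinates:
the nad1 length is taken as 9968 − 9044 + 1 = 925 bp (the alternative
"952" is a typographic artifact), and the rrnS/rrnL sizes follow the
coordinate intervals (808 and 1054 bp; the prose swaps them). The deepest
overlaps derived from coordinates are nad4L/nad4 and trnH/nad5 (both
7 bp). Truncated stop codons ("TA", "T") are stored verbatim; their
completion to TAA by polyadenylation is a biological note, not a
computation.

## Skews and codon usage

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C). `skew_from_percentages`
applies the formulas to printed percentage rows without re-normalization;
because published rows are rounded to one decimal, skews recomputed from
them carry an input-rounding uncertainty of about ±0.002, which is the
tolerance the tests use for the PCG-partition value.

RSCU(c) = observed count of codon *c* divided by its family-uniform
expectation (family total / family size). Synonymous families are defined
under the invertebrate mitochondrial code by amino acid *and* first two
codon bases, so six-fold Leu and Ser split into their two-codon NNR and
four-codon NNN boxes (Leu(UUR) vs Leu(CUN), Ser(UCN) vs Ser(AGN)) — the
convention of mitogenome codon-usage reports. Codons of an unused family
carry RSCU 0; incomplete terminal codons are trimmed before counting.

## Gene-order algebra

A gene order is a circular sequence of signed genes; the control region
participates as an orientable element. Because a circular molecule has no
distinguished origin and may be read from either strand, arrangements are
compared up to rotation **and** reflection: the canonical form rotates the
anchor (cox1 by default) to the front, reflecting first if the anchor is
on the minus strand. Canonicalization is idempotent and invariant under
rotation and reflection (property-tested).

Breakpoint distance is computed on signed gene extremities: each gene
contributes a tail and a head end, each circular neighbour pair
contributes one adjacency of two ends, and for orders over the same label
set the distance is `n − shared adjacencies`. An in-place inversion of a
single gene therefore creates two breakpoints. Orders with unequal label
sets are restricted to their intersection, recorded in the report.

## The TD(N\R)L + RC scenario

The shipped scenario encodes the derivation as five events:

1. *Whole-genome tandem duplication.* The dimer is linearized at the
   CR–trnI junction (the ancestral fixture starts at trnI), matching the
   layout of the published monomer lists.
2. *Polarity loss* with the rule {+ → monomer 1, − → monomer 2}. Monomer 1
   keeps the 23 plus-strand genes (including trnT and CR), monomer 2 the
   15 minus-strand genes. The published monomer-2 list omits trnY and
   misprints nad1 as nad4L; the computed survivors restore both, and the
   verbatim printed lists are shipped as flagged fixtures.
3. *3′–3′ recombination join.* The minus-polarity monomer transcribes
   opposite to the plus monomer, so its 3′ end lies at the trnQ side;
   operationally the join reverses monomer 2's gene sequence and flips its
   polarity, then circularizes. The product is single-stranded — the
   model's defining outcome, property-tested on 1000 random mixed-polarity
   orders.
4. *TDRL for trnT.* A tandem duplication of the circular span
   trnT…nad4 (which covers the nad4L/trnP neighbourhood) followed by loss
   of the first trnT copy and the second copies of everything else moves
   trnT between nad4 and trnH — read in the ancestral direction,
   trnT-nad4-nad4L.
5. *trnC/trnQ swap.* The derived arrangement has …trnY, trnQ, trnC… where
   the join produces …trnY, trnC, trnQ…, with all four genes on the plus
   strand. A signed inversion of the two-gene segment would flip both
   genes to the minus strand and destroy the single-stranded state, so the
   event is encoded as an orientation-preserving position swap
   (recombination by duplication–excision, expressed through the TDRL
   operator on the two-gene span). The `invert` operator itself follows
   the standard signed convention (reverse + flip) and is used by the
   inversion enumerator and the property suite.

Replay applies the events in sequence, logs every intermediate state, and
declares a match iff the final canonical form equals the target's. The
target is the annotation-table order; the published final list (which
duplicates nad4L and omits nad1) is shipped verbatim and its differences
are reported, not silently corrected.

## Single-event search

`enumerate_tdrl` and `enumerate_inversions` try every contiguous segment
(TDRL additionally every kept-copy pattern, bounded by `max_span`,
default 6, since candidates grow as span·2^span) and deduplicate by
resulting canonical order — many loss patterns are biologically
indistinguishable, so a candidate records one representative event per
distinct outcome. Planted-event recovery is property-tested over 500
seeded trials on orders of 4–8 genes.

## Synthetic genomes

`synth_genome` realizes a blueprint (feature lengths, strands, signed gap
plan, per-partition composition targets, PCG start/stop codons)
deterministically per seed. Coordinates implement the gap plan exactly, so
a blueprint read off the bundled table reproduces its spacer/overlap
structure by construction. Base composition is realized per feature by
exact-count pools (largest-remainder apportionment of the target
proportions, then shuffling); printed percentage rows that sum to
99.8–100.2 after rounding are treated as proportions. Start and stop
codons are overwritten last, which perturbs composition slightly; the
documented guarantee is ±1% for partitions of at least 1 kb (measured
deviation ≈ 0.5%). Overlapping features are written in table order, later
features overwriting earlier ones in the shared bases. Seeds are mandatory
— there is no wall-clock default.

What the generator does *not* emulate: realistic substitution processes,
codon-level selection, tRNA secondary structure, or control-region motifs.
Tests passing on synthetic genomes therefore validate the statistics and
the coordinate algebra, not sequence-level biology.

`evolve_order` draws random inversions, TDRLs, and the
duplication/polarity-loss/join macro with caller-given probabilities
(default span bound 6 genes) and emits a fully explicit history — segments
and kept-copy patterns, no deferred randomness — so the history replays to
the final order exactly (tested over 100 random specifications).

## Numerical and design choices

- Event provenance is attached to every derived order (`history`),
  excluded from equality comparisons.
- Inversion segments are addressed by endpoint labels in reading
  direction; re-inverting the same physical span therefore uses swapped
  endpoints.
- The strand-homogeneity of a distance report is given for each order
  separately; the scalar property is the minimum of the two.
- Problem sizes in the randomized suites (orders of 2–40 genes for the
  single-strand theorem, 4–8 genes for exhaustive enumeration, 100
  evolution specs) keep every enumeration exact rather than sampled while
  the full suite runs in a few seconds.

## Known limitations

- The rearrangement calculus operates on gene orders only; it does not
  model sequence homology at breakpoints or duplication remnants
  (pseudogenes), which real recombination leaves behind.
- Only single-event search is provided; minimal multi-event scenario
  inference between arbitrary genomes is out of scope (the search space is
  exponential).
- The codon-usage statistics of the real genome require its sequence and
  are exercised only on synthetic data here.
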