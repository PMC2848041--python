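# Methods

`retrokit` annotates and analyses a family of plant non-LTR retroelements
(SINE-like, non-coding, poly(A)-terminated) of the kind typified by the
*Arabidopsis* Sadhu family. This note records the models implemented, the
parameters that matter, and the choices made where the design was open.

## The element model

A canonical full-length element is modeled as

```
5'-[CAATCGTTSC motif][~20 bp polypyrimidine patch][body][poly(A) tail]-3'
```

with a total length of roughly 900 bp. Because it integrates by
target-primed reverse transcription (TPRT), a copy is flanked by a 7–18 bp
target site duplication (TSD): two staggered nicks on the target strand
leave the intervening bases duplicated on either side of the insertion.
The pre-insertion ("empty") allele of a locus therefore carries a single
copy of the target site, and excising the element together with one TSD
copy from a filled locus reconstructs the empty allele exactly — this is
the inverse relationship `predict_empty_site ∘ simulate_tprt_insertion =
identity` that the genotyper and simulator are tested against.

## Structural scanning (`element_scan`)

Motif search uses positional IUPAC semantics (S = C or G) on both strands;
genome `N` matches nothing. Defaults: up to 1 mismatch (the motif is a
family consensus, not an invariant), poly(A) tail of ≥6 bp at ≥80% A,
polypyrimidine patch of ≥15 bp at ≥90% C/T within 120 bp of the motif
(annotated but not required for full-length status), and a canonical
element span of 700–1100 bp operationalizing "approximately 900 bp".

A poly(A) tail is the longest *A-anchored* window (first and last base A)
meeting the length/purity thresholds — a decayed-homopolymer model chosen
because genomic tails degrade by point mutation while remaining
recognizably A-rich. When pairing a motif hit with a downstream tail whose
implied element length is canonical, the scanner prefers the **longest**
qualifying tail rather than the nearest: chance ≥6 bp A-runs occur every
few hundred bases of random sequence, and "nearest" would truncate a few
percent of genuine elements at an internal run, whereas genuine tails
(≥10–12 bp) outlast chance runs essentially always. Motif hits with a tail
implying 350–700 bp are typed `partial`; motif-only hits are `fragment`.
Overlapping annotations on a strand are resolved longest-first, then
leftmost.

The element's 3' boundary is intrinsically ambiguous against a TSD that
begins with adenines (the tail and the duplicated target blend); span
comparisons against simulator truth therefore allow the annotated end to
extend by up to the TSD length. The same ambiguity motivates the TSD
detector's `boundary_slack`.

## TSD detection and nicking-site consensus (`tsd`)

Given an element span, the detector returns the maximal direct repeat
whose left copy ends within `boundary_slack` (default 3 bp) of the element
start and whose right copy starts within the slack of the element end.
Ties break by fewer mismatches, smaller boundary offset, then leftmost.
Matching is exact by default because sequenced empty sites show a single,
identical copy of the duplicated target; a mismatch budget is available
for old, diverged insertions. Length bounds default to 7–18 bp (the union
of the ranges observed within and between the two species analysed). The
detector is, by construction, equivalent to exhaustive enumeration over
all (left start, right start, length) triples — the tests assert this
against an independent brute-force oracle.

When flanking bases happen to coincide, the maximal repeat can properly
contain the biologically annotated TSD; the filled site alone cannot
disambiguate, so *containment* of the true TSD, not equality, is the
guaranteed property.

Nicking-site statistics use fixed windows: the 9 bases 5' of the left TSD
copy (5' nick), the first 7 bases of the repeat, and the 9 bases 3' of the
right copy (3' nick), orientation-normalized to the element strand.
Consensus profiles are plain per-position base counts with information
content `2 + Σ p·log2 p` (0·log 0 = 0) and no small-sample correction —
with n = 14 catalogued loci, matching the plain WebLogo formula keeps the
statistic reproducible.

## Classification and nomenclature (`classify`)

Pairwise identity is computed from a global alignment with free terminal
gaps (match +1, mismatch −1, gap open −5, extend −1), as matches over
columns where both sequences have residues. The pair is canonicalized
before aligning so that identity is exactly symmetric despite co-optimal
alignments. With free ends and positive match scores this alignment
behaves locally on unrelated sequences — any two sequences share a
perfect few-column match — so the classifier ranks references by
alignment *score* (the BLAST-style notion of "nearest") and requires at
least 50 aligned columns before a relation is assigned at all.

Relations: a structurally full-length candidate is a subfamily *member*;
otherwise identity > 0.75 to a unique best reference (best-vs-second
identity gap ≥ 0.02) makes it *derived*; anything else with a ≥50-column
alignment is *like*; below that, unclassified. The source material states
both ">75%" and ">80%" for the derivative threshold in different places;
0.75 is the default and the knob is exposed. Names follow `PrefixX-#`
(members, numbered per subfamily in input order), `PrefixX-#dK`
(derivatives, numbered per parent) and `PrefixXLK` (likes, numbered per
subfamily), and parse back losslessly.

Subfamily consensus is a star alignment: members are aligned to an anchor
(the longest member by default), residues projected onto anchor columns,
and each column resolved by plurality (ties A<C<G<T; columns with no
residues dropped; insertions relative to the anchor do not create
columns). A full progressive MSA is deliberately avoided: the consensus
only needs column-level plurality, and the star construction is exactly
testable.

## Distances, trees, bootstrap (`phylo`)

Distances are uncorrected p-distances (fraction of differing sites over
pairwise-comparable, gap-free columns). Trees are built by Saitou–Nei
neighbor joining with deterministic tie-breaking (smallest index pair);
negative branch-length estimates are clamped to zero and counted. NJ on
additive matrices provably recovers the generating tree, which the tests
exercise on random 5–8-taxon trees; an independent NJ implementation
(scikit-bio) serves as a cross-check on noisy matrices. Maximum-parsimony
search is out of scope — subfamily assignment needs only coarse
clustering, and the family's published divergence matrices are themselves
distance-based. Bootstrap support is the percentage of column-resampled
replicates containing each bipartition of the point tree; 100 replicates
by default (the published analyses used 500, available by flag), seeded
and reproducible.

## Homology closure (`closure`)

Local search is a self-contained seed-and-extend: exact 11-mer seeds on
both strands, diagonal clustering, then local-alignment refinement of each
candidate window; hits pass at ≥70% identity over ≥100 bp and merge within
50 bp. An 11-mer exact seed is expected every ~8 bp of a 900 bp copy at
85% identity and every ~30 bp at 75%, so family members within the
identity threshold are reliably seeded. The closure iterates search →
promote novel hits to queries → repeat, where *novel* means not ≥95%
identical over ≥90% of length to an existing member (the published
procedure's "self-referencing set" gives no threshold; these values
prevent duplicate-entry loops). The fixed point is order-invariant in the
seeds and contains the single-pass result by construction. Reported
elements (≥350 bp) are structurally typed by the scanner, searched for
TSDs (ND when flanks are short or no repeat qualifies), and named against
a reference panel with a species prefix.

## Genotyping and insertion age (`genotype`)

A strain's locus is compared by normalized edit distance (edlib) to the
filled reference and to the reconstructed empty allele; the closer model
wins if within tolerance (default 2%, matching the strain-level SNP
divergence the simulator emulates). When neither model fits, presence of
both flanks (infix edit distance ≤10%) indicates a non-TPRT absence
(`empty_other`); otherwise the call is undetermined. A locus with both
clean empty and filled strains is `recent_polymorphic`; filled in every
determined strain, `fixed_in_sample`. A locus empty in *every* determined
strain is also labeled recent, since the reference haplotype it was
defined from is filled. The bundled strain panel maps presence marks
(`X`, `X*`) to filled, `ES` to clean-empty, and blank/`Short`/`Long`
entries — never defined in the source — conservatively to undetermined.

## Simulator (`simulate`)

The generator produces the data regime the pipeline assumes: AT-rich
background (32/18/18/32), 900 ± 60 bp elements with intact motif,
polypyrimidine patch and 12 bp tail; TSD lengths uniform on [7, 16];
subfamily ancestors at 0.30 substitutions/site from a founder and members
at 0.10 within a subfamily; derivative modes (5' truncation, template
switch with a 10–30 bp foreign head, early polyadenylation, internal
deletion) matching the observed derivative structures; and an 8-strain
panel with 4 ancestral plus 3 recent loci, recent insertions carried per
strain with probability 0.5 and strains diverging at 1% — the scale of
the published strain survey. Point mutations follow a Jukes–Cantor
substitution process (per-site substitution probability
`3/4·(1 − e^(−4d/3))`); indels are not simulated by default, since the
family's divergence statistics are substitution-based p-distances. Truth
records store spans, TSD strings, pre-insertion sequence and derivative
mode; the radiation panel records the *realized* presence pattern as its
truth label (a recent insertion sampled into every strain is, from the
sample's point of view, fixed). Everything is reproducible from a single
seed.

What the simulator does **not** emulate: insertions into repetitive or
low-complexity targets, indel mutation, segmental duplication, selection,
and population structure. Passing tests therefore demonstrate correctness
of the annotation logic under the family's idealized mutational model,
not performance on raw plant genomes.

## Test and acceptance problem sizes

The acceptance-level properties run at desk scale: 500 random TPRT loci
for the detector-vs-oracle equivalence, 200 insert/reconstruct round
trips, 100 planted elements per scan-recall condition (five ~22 kb
genomes each at divergence 0 and 0.10), 50 random additive trees for NJ
recovery, a three-member divergence chain for the closure, and the
8-strain × 7-locus panel for end-to-end age calls. The divergence-0 scan
uses exact motif matching (undiverged copies match the consensus
exactly); the 10%-divergence scan allows 3 motif mismatches, i.e. the
expected one substitution per 10-mer plus roughly two standard
deviations.

## Known limitations

- The classifier's subfamily membership for new full-length elements uses
  best-scoring-reference adjacency rather than explicit tree placement;
  for the divergence levels in scope the two agree, and the NJ tree is
  available for inspection.
- `scan_elements` runs in O(genome × motif) per strand and is intended for
  loci to ~100 kb contigs, not whole chromosomes in one call.
- The closure's seed-and-extend is exact-seeded; family members below
  ~60% identity to every query are invisible to it, consistent with the
  iterative-search design it implements.
- TSD detection reports the maximal flanking repeat; where flank bases
  coincide with the repeat, the printed/biological TSD is recovered as a
  substring, not necessarily as the full call.
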