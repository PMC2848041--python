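# retrokit

Annotation and evolutionary analysis of **Sadhu-type non-LTR
retroelements** — a family of non-coding, poly(A)-terminated plant
retroposons that integrate by target-primed reverse transcription (TPRT)
and leave a 7–18 bp target site duplication (TSD) flanking each insertion.

The toolkit is for sequence analysts studying low-copy transposable
element families: it discovers candidate elements from structural
features, detects TSDs and builds integration-site sequence logos,
classifies copies into subfamilies with the field's `FamilyX-#` /
`FamilyX-#dK` / `FamilyXLK` nomenclature, builds neighbor-joining trees on
uncorrected distances with bootstrap support, expands a family in a new
genome by iterative homology search to a self-referencing set, and
genotypes insertion loci across strain panels as filled / clean-empty to
call insertions recent (polymorphic) or fixed. A seeded TPRT simulator
with machine-readable ground truth backs every stage's tests.

## The core models

**Element structure.** A full-length element runs
`CAATCGTTSC` motif → ~20 bp polypyrimidine patch → body → 3' poly(A)
tract, ~900 bp in total.

**TPRT insertion.** Integration duplicates the target bases
`g[pos−k … pos]` around the element, so a filled locus is
`flank + TSD + element + TSD + flank` and its pre-insertion allele is
recovered exactly by excising the element with one TSD copy. The detector
returns the maximal direct repeat consistent with the element boundaries
(±3 bp slack); tie-breaks are fewer mismatches, smaller boundary offset,
leftmost.

**Classification.** Candidates are related to a reference panel of named
full-length elements by global alignment with free end gaps (match +1,
mismatch −1, gap −5/−1). Identity is matches over both-residue columns;
`>75%` identity to a unique best reference makes a copy *derived* (`d`),
anything else attaches to its best-scoring match as *like* (`L`).

**Trees.** Uncorrected p-distances, Saitou–Nei neighbor joining,
bipartition bootstrap from column resampling.

## Worked example

Rebuild the catalogued Sadhu5-1 insertion locus from its printed flanking
strings, detect the TSD, and reconstruct the pre-insertion allele:

```python
from retrokit import find_tsd, predict_empty_site
from retrokit.tables import load_tsd_sites, reconstruct_tsd_locus

table = load_tsd_sites()
row = table[table["element"] == "Sadhu5-1"].iloc[0]
locus, element_span = reconstruct_tsd_locus(row)

call = find_tsd(locus, element_span)
print("detected TSD :", call.repeat_seq, f"({call.length} bp)")
print("left copy    :", call.left_span, " right copy:", call.right_span)
print("empty allele :", predict_empty_site(locus, element_span, call))
```

prints

```
detected TSD : AGTACTACTACT (12 bp)
left copy    : (9, 21)  right copy: (83, 95)
empty allele : CTGCAATATAGTACTACTACTAATGTTATC
```

— the detected repeat is the locus's 12 bp TSD, found once on each side
of the element, and the empty allele is the 5' nicking-site window, a
single TSD copy and the 3' window: exactly the structure sequenced
pre-insertion sites show.

The command line mirrors the library
(`retrokit scan | tsd | classify | tree | closure | age | simulate |
annotate`); `retrokit annotate --fasta genome.fa --out-dir out/` runs the
whole workflow and writes GFF3, TSV tables, a newick tree, and the
integration-site consensus matrices.

## Layout

```
src/retrokit/
  element_scan.py   structural discovery (motif, polypyrimidine, poly(A))
  tsd.py            TSD detection, nicking-site windows, consensus logos
  classify.py       pairwise identity, subfamily relations, nomenclature
  phylo.py          p-distances, neighbor joining, bootstrap
  closure.py        seed-and-extend search, iterative homology closure
  genotype.py       empty-site reconstruction, strain genotyping, age calls
  simulate.py       TPRT insertion simulator + strain panels with truth
  tables.py         bundled curated tables (element catalogue, TSD loci,
                    strain panel, A. lyrata elements)
  pipeline.py/cli.py  end-to-end workflow and the retrokit command
docs/methods.md     models, parameters, design choices, limitations
```
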