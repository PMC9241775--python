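# tnfuse

Design and analysis toolkit for **markerless mariner-transposon fluorescent
fusions**: enumerate TA target sites and their codon phases, build the three
open-reading-frame transposon architectures, construct insertions with
target-site duplication, predict the resulting sandwich-fusion proteins, map
junction tags back to insertion sites, design split-fluorophore BiFC bait
and prey constructs, and simulate the FACS gene-trap enrichment used to pull
on-target fusions out of a random library.

## The problem

A *mariner*/Himar transposase inserts its cargo at a TA dinucleotide and
duplicates it, so every insertion adds `len(cargo) + 2` bases.  If the cargo
is a promoterless, stop-less fluorescent reporter flanked by the two 27-bp
inverted terminal repeats (ITRs), a cooriented insertion into an expressed
gene can create an internal, in-frame "sandwich" fusion — provided the
reading frame survives the junctions.  A TA inside a codon frame falls in
one of three phases, each needing its own spacer arithmetic:

| phase | TA position            | variant | 5′ spacer | 3′ spacer |
|-------|------------------------|---------|-----------|-----------|
| P23   | codon positions 2–3 (`XTA`)     | open1 | 0 bp | 1 bp |
| P31   | straddling codons (`XXT-AXX`)   | open2 | 2 bp | 2 bp |
| P12   | codon positions 1–2 (`TAX`)     | open3 | 1 bp | 3 bp |

In every case `(|ITR| + spacer5 + |reporter| + spacer3 + |ITR| + 2) mod 3 = 0`,
so the downstream target frame is restored.  The P12 frame is special: the
duplicated TA occupies codon positions 1–2, so an ITR beginning with A forms
an immediate `TAA` stop at the junction — the canonical 27-bp Himar1 ITR
read in that frame carries three stop codons, which is why the open3
architecture requires ITR modification and is refused by default in the
BiFC prey builder.

Because selection is by fluorescence-activated cell sorting (FACS) rather
than antibiotic resistance, on-target fusions are enriched with a gene trap:
express the target from an inducible promoter, sort fluorescent cells
*with* inducer, regrow, then sort dark cells *without* inducer — only
fluorescence that co-varies with induction survives both sorts.

## Worked example

```python
from tnfuse import (CdsAnnotation, InsertionEvent, ItrSequence, ReporterCassette,
                    TransposonVariant, NucleotideSequence, build_cargo,
                    enumerate_ta_sites, predict_fusion_protein)

gene = NucleotideSequence("g", "ATGCTAGGCTAA")          # M-L-G-stop
ann = CdsAnnotation("g1", "g", 1, 12, "+")
open1 = TransposonVariant(name="open1", reporter=ReporterCassette("GGTGGC"),
                          itr_up=ItrSequence("A" * 27), itr_down=ItrSequence("A" * 27, "downstream"),
                          spacer5_seq="", spacer3_seq="A")
site = [s for s in enumerate_ta_sites(gene, [ann]) if s.t_coord == 5][0]
print(site.phase)                                        # P23
fusion = predict_fusion_protein(gene, ann, InsertionEvent(site=site, variant_name="open1"),
                                build_cargo(open1))
print(fusion.protein)                                    # MLKKKKKKKKKGGKKKKKKKKKIG
print(fusion.premature_stop)                             # None
print(fusion.segments)
```

prints

```
P23
MLKKKKKKKKKGGKKKKKKKKKIG
None
(('target_N', 1, 2), ('itr_up_linker', 3, 11), ('reporter', 12, 13),
 ('spacer', 14, 14), ('itr_down_linker', 15, 23), ('target_C', 24, 24))
```

Reading the 24-residue fusion: the target's first two residues (`ML`, the
second codon `CTA` carrying the target TA), nine lysines from the poly-A toy
ITR, the two reporter residues, the spacer/downstream-ITR/duplicated-TA
linker block, and finally `G` — the wild-type C-terminal residue, restored
because the cargo-plus-duplication length is a codon multiple.

The same operations are exposed on the command line:

```sh
tnfuse fixtures --n-codons 40 --phases P23:10 --out fixture.fasta
tnfuse scan genome.fasta genes.gff3 --out-prefix sites
tnfuse design-bifc fluorophore.fasta --split 154
tnfuse simulate-trap --seed 7 --out trap.tsv
```

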