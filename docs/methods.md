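# Methods

## Scope and model

`tnfuse` models the sequence-level consequences of mariner/Himar transposon
insertion: target-site selection (a TA dinucleotide, duplicated on
insertion), the reading-frame arithmetic that decides whether a promoterless
fluorescent reporter carried between the two ITRs is translated in frame
with the interrupted gene, and the downstream workflows that use that
arithmetic — genome scanning for productive sites, junction-tag mapping,
split-fluorophore (BiFC) construct design, and a stochastic simulation of
the inducer-coupled FACS gene trap.  It does not model transposase
biochemistry, insertion-site preference beyond the TA requirement, protein
folding or localization, or fluorophore photophysics.

## Coordinates and conventions

* All user-facing coordinates are 1-based inclusive (GFF convention);
  0-based arithmetic is confined to function bodies.
* A TA site is addressed by the coordinate of its T on the forward strand.
  TA is its own reverse complement, so forward enumeration covers both
  strands; orientation (cooriented vs antisense) is a property of an
  insertion event, not of a site.
* `cds_offset` anchors on the T of the target TA, with the first base of
  the start codon at +1 and the base immediately 5′ of it at −1 (there is
  no zero).  Negative offsets are classified by extending the codon grid
  leftward from the ATG.  This single rule reproduces both positive and
  negative insertion labels; the anchor is a convention and other choices
  (first duplicated base, first cargo base) would shift labels by one or
  two — the convention is documented here and applied uniformly.
* Codon-phase classes: position-in-codon `p = ((offset − 1) mod 3) + 1`;
  `p = 2 → P23`, `p = 3 → P31`, `p = 1 → P12`.
* Translation uses the standard bacterial code with full-frame-scan
  semantics: stops render as `*` and translation continues, so internal
  stops are visible to frame checks; `N`-containing codons render as `X`;
  only ATG is treated as a start anchor (GTG/TTG initiation is not
  modeled).

## Transposon architectures

The three variants differ only in spacer lengths: open1 (0/1, matches P23),
open2 (2/2, matches P31), open3 (1/3, matches P12).  The frame-balance
invariant `(2·|ITR| + spacer5 + |reporter| + spacer3 + 2) mod 3 = 0` is
checked by `validate_variant` and guarantees the downstream target frame is
restored for *any* insertion, matched or not; what distinguishes a matched
(productive) insertion is that the reporter itself is read in its own
frame 0 and no stop codon intervenes.

The default ITR is the canonical 27-bp Himar1 mariner repeat
(`ACAGGTTGGCTGATAAGTCCCCGGTCT`) with the downstream ITR its reverse
complement.  The ITR slot is fully configurable, and any configured ITR is
*scanned* for junction stops rather than assumed safe: read in the P23 or
P31 entry frame the default repeat is stop-free, while in the P12 frame it
contains three in-frame stops, the first being the immediate `TAA` formed
by the duplicated TA plus the ITR's leading A.  The generic ITR-variant
enumerator (`generate_itr_variants`) explores substitution combinations and
re-scans each; no specific published substitution set is reproduced because
those base identities are not derivable from available sources.

Spacer base identities default to stop-free choices against the default ITR
(open1: 3′ `A`; open2: `GG`/`GG`; open3: `G`/`GGG`); only the spacer
*lengths* carry scientific content, and the defaults are configurable.

## Productivity: two independent routes

An insertion event is **productive** when it is cooriented, its site phase
matches the variant, and translation runs from the target start through the
entire cargo and back into the target without a stop.  The package computes
this two ways:

1. *Brute force* (`predict_fusion_protein` / `verify_orf`): construct the
   mutated sequence base-for-base, translate, locate the first stop, and
   segment the protein (a residue belongs to the segment owning its first
   base).  Productive fusions provably restore the wild-type C-terminal
   residues, and the test suite asserts that string equality.
2. *Phase arithmetic* (`phase_arithmetic_productive`): phase match plus
   stop-scans of the two junction contexts — upstream, the entering TA
   bases + upstream ITR + 5′ spacer (after which the reporter sits at a
   codon boundary); downstream, the 3′ spacer + downstream ITR + duplicated
   TA (whose trailing partial codon reconstructs a wild-type codon and so
   cannot introduce a new stop).

The test suite holds the two routes to exact agreement over ≥ 10,000
(site, variant) pairs on random fixtures, with the brute-force route
implemented independently in the tests (biopython translation on
string-sliced constructs).

Insertions upstream of the start codon are supported when the upstream
phase (leftward frame extension) matches the variant: the predicted fusion
is then reporter-first with the full-length target restored after the
linker — the N-terminal-fusion topology.  The exact linker length of any
particular published upstream fusion depends on construct details that are
not reproducible from sequence-free descriptions, so no specific linker
length is asserted.

## Synthetic fixtures

`generate_fixture_gene` builds a CDS with TA sites at exactly the requested
codon phases and positions: codon 1 is ATG, the terminal codon is TGA
(which contains no TA dinucleotide), phase sites use template codons
(`CTA` for P23, `TAC` for P12, `GGT`+`AAG` for P31), and all other codons
come from a pool that is stop-free, TA-free, never ends in T and never
starts with A, so no accidental TA can form within or across codons.  The
generator re-runs the TA enumeration on its own output and fails loudly if
the realized sites differ from the request.  Fixtures are deterministic per
seed.  `synthetic_reporter_cds` uses the same pool to make stop-free
reporter stand-ins; these are synthetic sequences, not biological ones, so
tests exercise frame arithmetic, not codon usage of any real fluorophore.

## Junction tags

A tag is the duplicated TA plus the adjacent downstream reference bases on
the insertion's reading strand (default 10 nt total; 8–12 accepted,
covering both the nine-adjacent-bases reading and ten-character printed
tags).  Mapping is exact-match on both strands; multiple placements are
reported and flagged ambiguous, never resolved, and the tests assert that
repeats degrade recovery only to ambiguity, never to a wrong unique call.
On a fixture genome whose tag 10-mers are verified unique, round-trip
recovery of simulated insertions is 100%.

## BiFC constructs

`split_fluorophore` cuts a stop-free CDS after a chosen residue into
complementary fragments with no overlap or gap (default split after
residue 154: a 717-nt CDS gives a 462-bp N fragment and a 255-bp,
85-residue C fragment; the fragment concatenation identity is property-
tested over all split points).  The bait is target + linker + N fragment +
stop, validated by translation; the prey is a transposon variant whose
reporter is the C fragment, passing full variant validation.  The open3
prey is refused by default (its mandatory ITR modification makes it
impractical) but can be built with an explicit override.
`detect_self_insertion` reports the reordered segment topology when a prey
lands inside the bait itself, including the fragment-order swap diagnostic.

## Trap simulator

Cells are drawn i.i.d.: transposition with probability `p_transposition`;
given an insertion, the locus is the target gene (proportional to its TA
share of the genome), an expressed off-target, or silent; given an
expressed locus, the insertion is productive with probability
`p_coorient × p_phase_match × p_inframe_fluorescent` (defaults ½ × ⅓ × ½).
Fluorescence is two log-normal components (dark autofluorescence
`exp(N(0, 0.35))`, bright `exp(N(4, 0.5))`, arbitrary units, gate at 8).
The default `p_transposition = 0.005` makes a bright cell ≈ a 1-in-5,000
event, the order of magnitude seen for a single-frame library; this is a
calibrated default, not an asserted result.  The protocol is: sort above
the gate with inducer, multinomially resample to the original population
size (regrowth, which also reproduces sibling propagation), sort below the
gate without inducer.  A per-round dropout probability (default 0) models
cells going dark for reasons other than induction.

Verified properties: the bright fraction matches the closed-form product
within Monte Carlo error; in the zero-noise limit with only
inducer-dependent target signal the enrichment factor equals
1 / initial target fraction exactly; two rounds enrich at least as much as
one in ≥ 95% of paired seeds; results are bitwise reproducible per seed.
Simulation sizes in the test suite (2 × 10⁴ cells, 100 paired seeds) were
chosen to give stable statistics at interactive runtimes.

What the simulator does *not* capture: growth-rate fitness effects,
instrument recovery losses, lineage structure beyond resampling, and any
coupling between insertion position and expression level — so passing
tests validate the enrichment logic, not quantitative yields of any real
sorting experiment.

## Known limitations

* Exact published ITR/spacer base identities and specific modified-ITR
  construct sets are not reproduced (not derivable from available text);
  the slots are configurable and validated instead.
* Antisense insertions are constructed faithfully but always classified
  nonproductive for fusion purposes; promoter capture in antisense
  orientation is out of scope.
* Tag mapping is exact-match on assembled sequence; it is not a read
  aligner and does not model IPCR mechanics (restriction digestion,
  self-ligation, primers).
* The anchor convention for insertion offsets is one of several defensible
  choices; comparisons with labels produced under a different anchor may
  differ by 1–2 bp.
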