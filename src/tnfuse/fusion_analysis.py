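"""Reading-frame verification and fusion-protein prediction for transposon insertions.

A cooriented insertion whose TA-site phase matches the variant's compatible
phase is *productive*: translation runs from the target N-terminus through
the upstream ITR, the reporter, the downstream spacer/ITR and the duplicated
TA, and re-enters the target in the original frame, yielding an internal
"sandwich" fusion whose C-terminal residues equal the wild type's.  Any
phase mismatch shifts the frame; an unmodified ITR beginning with A read in
the P12 entry frame stops translation immediately (TA + A = TAA).

The module offers two independent routes to productivity — fast phase
arithmetic and brute-force translation of the fully constructed sequence —
and the test suite holds them to agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .insertion_engine import (
    InsertionEvent,
    TASite,
    apply_insertion,
    enumerate_ta_sites,
)
from .seqio import CdsAnnotation, NucleotideSequence, revcomp, translate
from .transposon_model import (
    ENTRY_CONSUMED,
    CargoSequence,
    TransposonVariant,
    build_cargo,
    validate_variant,
)

__all__ = [
    "FusionConstruct",
    "ScanReport",
    "verify_orf",
    "predict_fusion_protein",
    "phase_arithmetic_productive",
    "scan_gene",
    "scan_genome",
    "dedup_candidates",
]

# protein-level segment label for each nucleotide-level cargo segment
_NT_TO_PROTEIN_LABEL = {
    "target_N": "target_N",
    "itr_up": "itr_up_linker",
    "spacer5": "spacer",
    "reporter": "reporter",
    "spacer3": "spacer",
    "itr_down": "itr_down_linker",
    "ta_dup": "itr_down_linker",
    "upstream_remnant": "itr_down_linker",
    "target_C": "target_C",
}


@dataclass(frozen=True)
class FusionConstruct:
    """The predicted post-insertion fusion protein, segmented.

    ``segments`` are (label, first residue, last residue), 1-based
    inclusive, tiling the protein exactly.  ``premature_stop`` is the
    1-based residue position of the first stop encountered before the
    natural target stop, or None when the frame runs through.
    """

    gene_id: str
    site: TASite
    variant_name: str
    protein: str
    segments: tuple
    premature_stop: int | None = None
    nt_segments: tuple = ()  # (label, start, end) on the fused ORF, 1-based nt

    def nt_segment_length(self, label: str) -> int:
        for lab, s, e in self.nt_segments:
            if lab == label:
                return e - s + 1
        raise KeyError(label)

    def __post_init__(self) -> None:
        pos = 1
        for label, start, end in self.segments:
            if start > end:
                continue
            if start != pos:
                raise ValueError(
                    f"segment {label} starts at {start}, expected {pos}"
                )
            pos = end + 1
        if pos != len(self.protein) + 1:
            raise ValueError("segments do not tile the protein")

    def segment_residues(self, label: str) -> str:
        out = []
        for lab, start, end in self.segments:
            if lab == label:
                out.append(self.protein[start - 1 : end])
        if not out:
            raise KeyError(label)
        return "".join(out)

    @property
    def productive(self) -> bool:
        return self.premature_stop is None


def verify_orf(
    mutated: NucleotideSequence, cds_start: int, expected_len: int
) -> tuple[bool, int | None]:
    """Is the reading frame from ``cds_start`` continuous for ``expected_len`` residues?

    Translates from the 1-based ``cds_start`` (which must hold an ATG) with
    full-frame scan semantics and returns ``(continuous, first_stop)`` where
    ``first_stop`` is the 1-based residue position of the first stop codon,
    or None if none occurs within ``expected_len`` residues.
    """
    s = mutated.residues
    if s[cds_start - 1 : cds_start + 2] != "ATG":
        raise ValueError(f"no ATG at position {cds_start}")
    aa = translate(s[cds_start - 1 :])
    idx = aa.find("*")
    if 0 <= idx < expected_len:
        return False, idx + 1
    return True, None


def _canonical_plus(gene: NucleotideSequence, ann: CdsAnnotation, site: TASite):
    """Mirror a minus-strand gene onto the forward strand of its revcomp.

    TA is its own reverse complement, so the site survives the transform;
    the reading-strand T lands at ``len - t_coord`` (the forward A).
    """
    if ann.strand == "+":
        return gene, ann, site
    n = len(gene)
    gene2 = revcomp(gene)
    ann2 = CdsAnnotation(
        gene_id=ann.gene_id,
        contig_id=ann.contig_id,
        start=n - ann.end + 1,
        end=n - ann.start + 1,
        strand="+",
        partial=ann.partial,
    )
    site2 = TASite(
        contig_id=site.contig_id,
        t_coord=n - site.t_coord,
        in_cds=site.in_cds,
        gene_id=site.gene_id,
        cds_offset=site.cds_offset,
        phase=site.phase,
        upstream=site.upstream,
    )
    return gene2, ann2, site2


def predict_fusion_protein(
    gene: NucleotideSequence,
    ann: CdsAnnotation,
    event: InsertionEvent,
    cargo: CargoSequence,
    variant: TransposonVariant | None = None,
) -> FusionConstruct:
    """Construct the insertion and predict the full fusion protein.

    The mutated sequence is built base-for-base (insertion with TA
    duplication), translated, and segmented into target/linker/reporter
    parts at residue resolution (a residue belongs to the segment owning
    its first base).  Insertions upstream of the ATG produce a
    reporter-first, N-terminal-fusion topology.  Antisense events are
    rejected: the reverse-complemented reporter cannot be read in the
    target's frame.
    """
    if event.orientation != "coorient":
        raise ValueError(
            "antisense insertion cannot produce a translational fusion: "
            "the reporter reads antiparallel to the target frame"
        )
    site = event.site
    gene, ann, site = _canonical_plus(gene, ann, site)
    off = site.cds_offset
    if off is None:
        off = site.t_coord - ann.start + 1
        if off <= 0:
            off -= 1  # no zero: base 5' of the CDS start is -1
    if off < 0:
        return _predict_upstream_fusion(gene, ann, site, off, event, cargo)

    mutated = apply_insertion(gene, site, cargo, event.orientation)
    cds_len = ann.end - ann.start + 1
    fusion_nt_len = cds_len + len(cargo) + 2
    expected_len = fusion_nt_len // 3 - 1  # minus the natural stop

    aa = translate(mutated.residues[ann.start - 1 :])[: expected_len + 1]
    stop_idx = aa.find("*")
    premature = stop_idx + 1 if 0 <= stop_idx < expected_len else None
    protein = aa[:stop_idx] if premature else aa[:expected_len]

    # nucleotide segments relative to the CDS start (1-based)
    nt_segments = [("target_N", 1, off + 1)]
    pos = off + 2
    for label, s, e in cargo.segment_map:
        seg_len = e - s + 1 if e >= s else 0
        if seg_len:
            nt_segments.append((label, pos, pos + seg_len - 1))
            pos += seg_len
    nt_segments.append(("ta_dup", pos, pos + 1))
    nt_segments.append(("target_C", pos + 2, fusion_nt_len))

    segments = _residue_segments(nt_segments, len(protein))
    return FusionConstruct(
        gene_id=ann.gene_id,
        site=site,
        variant_name=event.variant_name,
        protein=protein,
        segments=segments,
        premature_stop=premature,
        nt_segments=tuple(nt_segments),
    )


def _predict_upstream_fusion(gene, ann, site, off, event, cargo):
    """Reporter-first topology for an insertion 5' of the start codon."""
    mutated = apply_insertion(gene, site, cargo, event.orientation)
    # first reporter base within the mutated sequence
    rep_start_in_cargo = next(
        s for lab, s, e in cargo.segment_map if lab == "reporter"
    )
    orf_start = site.t_coord + 2 + rep_start_in_cargo - 1
    k = -off  # T sits k bases 5' of the CDS start
    remnant_len = k - 2  # original bases between the duplicated TA and ATG
    cds_len = ann.end - ann.start + 1
    tail_lens = [
        (lab, e - s + 1 if e >= s else 0)
        for lab, s, e in cargo.segment_map
        if lab in ("spacer3", "itr_down")
    ]
    fusion_nt_len = (
        len(cargo.segment("reporter"))
        + sum(n for _, n in tail_lens)
        + 2
        + remnant_len
        + cds_len
    )
    expected_len = fusion_nt_len // 3 - 1
    aa = translate(mutated.residues[orf_start - 1 :])[: expected_len + 1]
    stop_idx = aa.find("*")
    premature = stop_idx + 1 if 0 <= stop_idx < expected_len else None
    protein = aa[:stop_idx] if premature else aa[:expected_len]

    nt_segments = [("reporter", 1, len(cargo.segment("reporter")))]
    pos = len(cargo.segment("reporter")) + 1
    for lab, n in tail_lens:
        if n:
            nt_segments.append((lab, pos, pos + n - 1))
            pos += n
    nt_segments.append(("ta_dup", pos, pos + 1))
    pos += 2
    if remnant_len:
        nt_segments.append(("upstream_remnant", pos, pos + remnant_len - 1))
        pos += remnant_len
    nt_segments.append(("target_C", pos, fusion_nt_len))
    segments = _residue_segments(nt_segments, len(protein))
    return FusionConstruct(
        gene_id=ann.gene_id,
        site=site,
        variant_name=event.variant_name,
        protein=protein,
        segments=segments,
        premature_stop=premature,
        nt_segments=tuple(nt_segments),
    )


def _residue_segments(nt_segments, n_residues):
    """Collapse nucleotide segments to residue segments by first-base ownership."""
    if n_residues == 0:
        return ()
    owner = {}
    for label, s, e in nt_segments:
        for nt in range(s, e + 1):
            owner[nt] = _NT_TO_PROTEIN_LABEL[label]
    out = []
    cur_label, cur_start = None, None
    for r in range(1, n_residues + 1):
        lab = owner.get(3 * r - 2)
        if lab != cur_label:
            if cur_label is not None:
                out.append((cur_label, cur_start, r - 1))
            cur_label, cur_start = lab, r
    out.append((cur_label, cur_start, n_residues))
    return tuple(out)


def phase_arithmetic_productive(phase: str, variant: TransposonVariant) -> bool:
    """Fast productivity prediction without constructing the insertion.

    A cooriented insertion is productive iff the site phase matches the
    variant, the variant is internally valid, and both junction contexts
    are stop-free when read in the matched frame: upstream, the entering
    TA bases + upstream ITR + 5' spacer (after which the reporter sits at
    a codon boundary); downstream, the 3' spacer + downstream ITR + the
    duplicated TA (the trailing partial codon reconstructs a wild-type
    codon and cannot introduce a new stop).
    """
    if variant.compatible_phase != phase:
        return False
    if not validate_variant(variant).ok:
        return False
    consumed = ENTRY_CONSUMED[phase]
    upstream_ctx = "TA"[2 - consumed :] + variant.itr_up.residues + variant.spacer5_seq
    if "*" in translate(upstream_ctx):
        return False
    downstream_ctx = variant.spacer3_seq + variant.itr_down.residues + "TA"
    return "*" not in translate(downstream_ctx)


@dataclass
class ScanReport:
    """Per-(site, variant) rows plus genome-level phase statistics."""

    rows: pd.DataFrame
    summary: dict = field(default_factory=dict)

    COLUMNS = (
        "gene_id",
        "contig_id",
        "t_coord",
        "cds_offset",
        "phase",
        "variant",
        "compatible",
        "productive",
        "premature_stop",
    )

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def to_gff_rows(self):
        """One GFF3 feature per productive (site, variant) row."""
        out = []
        for _, r in self.rows[self.rows["productive"]].iterrows():
            out.append(
                (
                    r["contig_id"],
                    "insertion_site",
                    int(r["t_coord"]),
                    int(r["t_coord"]) + 1,
                    "+",
                    {
                        "variant": r["variant"],
                        "phase": r["phase"],
                        "gene": r["gene_id"],
                    },
                )
            )
        return out


def scan_gene(
    gene: NucleotideSequence,
    ann: CdsAnnotation,
    variants,
) -> list[dict]:
    """Rows for every (in-CDS TA site, variant) pair of one gene.

    For the compatible variant the premature-stop status comes from full
    fusion prediction; incompatible pairs are nonproductive by definition.
    Partial CDSs are skipped with a warning.
    """
    if ann.partial:
        warnings.warn(
            f"gene {ann.gene_id}: partial CDS (length not a multiple of 3), "
            "skipped from phase analysis"
        )
        return []
    sites = [
        s
        for s in enumerate_ta_sites(gene, [ann])
        if s.in_cds and s.gene_id == ann.gene_id
    ]
    rows = []
    for site in sites:
        for variant in variants:
            compatible = variant.compatible_phase == site.phase
            productive = False
            premature = None
            if compatible:
                cargo = build_cargo(variant)
                event = InsertionEvent(
                    site=site, variant_name=variant.name, orientation="coorient"
                )
                fusion = predict_fusion_protein(gene, ann, event, cargo)
                premature = fusion.premature_stop
                productive = fusion.productive
            rows.append(
                {
                    "gene_id": ann.gene_id,
                    "contig_id": site.contig_id,
                    "t_coord": site.t_coord,
                    "cds_offset": site.cds_offset,
                    "phase": site.phase,
                    "variant": variant.name,
                    "compatible": compatible,
                    "productive": productive,
                    "premature_stop": premature,
                }
            )
    return rows


def scan_genome(
    genome,
    annotations,
    variants,
) -> ScanReport:
    """Scan every complete CDS of a genome; aggregate phase statistics.

    ``genome`` may be a single NucleotideSequence or a list of contigs.
    """
    contigs = genome if isinstance(genome, (list, tuple)) else [genome]
    by_id = {c.id: c for c in contigs}
    all_rows = []
    for ann in annotations:
        contig = by_id.get(ann.contig_id)
        if contig is None:
            raise ValueError(f"annotation {ann.gene_id}: no contig {ann.contig_id}")
        all_rows.extend(scan_gene(contig, ann, variants))
    df = pd.DataFrame(all_rows, columns=list(ScanReport.COLUMNS))
    site_df = df.drop_duplicates(subset=["gene_id", "t_coord"])
    summary = {
        "n_sites_in_cds": int(len(site_df)),
        "n_rows": int(len(df)),
        "n_productive": int(df["productive"].sum()) if len(df) else 0,
        "phase_counts": site_df["phase"].value_counts().to_dict()
        if len(df)
        else {},
        "per_gene_sites": site_df.groupby("gene_id").size().to_dict()
        if len(df)
        else {},
    }
    return ScanReport(rows=df, summary=summary)


def dedup_candidates(rows):
    """Unique candidates by (gene_id, cds_offset), stable by first occurrence.

    Accepts tuples/lists whose first two fields are gene_id and cds_offset,
    or dicts with those keys; sibling isolates recovered repeatedly during
    enrichment collapse to one entry each.
    """
    seen = set()
    out = []
    for row in rows:
        if isinstance(row, dict):
            key = (row["gene_id"], row["cds_offset"])
        else:
            key = (row[0], row[1])
        if key not in seen:
            seen.add(key)
            out.append(row)
    return out
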