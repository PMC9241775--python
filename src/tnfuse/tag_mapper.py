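"""Locating insertion sites from short junction tags.

An insertion's position is fully determined by the short stretch of genomic
sequence adjacent to the transposon junction: the duplicated TA followed by
the downstream reference bases on the insertion's reading strand.  Matching
is exact on both strands (tags derive from Sanger/WGS reads of the
junction); repeated placements are surfaced as ambiguity, never resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .insertion_engine import PHASE_TO_VARIANT, TASite, _site_for_cds
from .seqio import NucleotideSequence, revcomp

__all__ = ["TnTag", "TagHit", "map_tag", "extract_tag", "batch_map"]


@dataclass(frozen=True)
class TnTag:
    """A junction tag: the TA target plus adjacent reference bases.

    Tags must begin with TA and be 8-12 nt long (published tables print
    10-character tags while describing nine adjacent base pairs; both
    readings are accepted).
    """

    label: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues.startswith("TA"):
            raise ValueError(
                f"tag {self.label}: must begin with the TA target "
                f"(got {self.residues[:2]!r})"
            )
        if not 8 <= len(self.residues) <= 12:
            raise ValueError(
                f"tag {self.label}: length {len(self.residues)} outside 8-12"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TagHit:
    tag_label: str
    contig_id: str
    t_coord: int
    strand: str
    gene_id: str | None
    cds_offset: int | None
    phase: str | None
    compatible_variant: str | None
    n_hits_total: int

    @property
    def ambiguous(self) -> bool:
        return self.n_hits_total > 1


def _find_all(haystack: str, needle: str):
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1


def _annotate(contig_id, t_coord, strand, annotations, n_total, label):
    gene_id = cds_offset = phase = variant = None
    for ann in annotations:
        if ann.partial:
            continue
        site = _site_for_cds(contig_id, t_coord, ann)
        if site is not None:
            gene_id, cds_offset, phase = site.gene_id, site.cds_offset, site.phase
            variant = PHASE_TO_VARIANT[phase]
            break
    return TagHit(
        tag_label=label,
        contig_id=contig_id,
        t_coord=t_coord,
        strand=strand,
        gene_id=gene_id,
        cds_offset=cds_offset,
        phase=phase,
        compatible_variant=variant,
        n_hits_total=n_total,
    )


def map_tag(tag: TnTag, genome, annotations=()) -> list[TagHit]:
    """Exact-match a tag on both strands of the genome.

    Each match anchors the insertion at the tag's leading TA: a forward
    match at position p puts the T at p; a reverse-strand match puts the
    tag's TA at the far end of the matched span.  Every hit carries the
    total hit count so multi-copy placements are flagged ambiguous.
    """
    contigs = genome if isinstance(genome, (list, tuple)) else [genome]
    raw = []  # (contig_id, t_coord, strand)
    rc = revcomp(tag.residues)
    for contig in contigs:
        s = contig.residues
        for idx in _find_all(s, tag.residues):
            raw.append((contig.id, idx + 1, "+"))
        for idx in _find_all(s, rc):
            # tag's TA maps to the last two matched bases on the forward strand
            raw.append((contig.id, idx + len(tag) - 1, "-"))
    n = len(raw)
    return [
        _annotate(cid, t, strand, annotations, n, tag.label)
        for cid, t, strand in raw
    ]


def extract_tag(
    seq: NucleotideSequence, site: TASite, length: int = 10, strand: str = "+"
) -> TnTag:
    """Read the tag off the reference: TA plus downstream bases on the reading strand.

    For a forward-reading insertion the tag is ``seq[t .. t+length-1]``; for
    a reverse-reading one it is the reverse complement of the span ending at
    the A, which again begins with TA (the target is palindromic).
    """
    if not 2 <= length <= 12:
        raise ValueError("tag length must be 2-12")
    t0 = site.t_coord - 1
    s = seq.residues
    if s[t0 : t0 + 2] != "TA":
        raise ValueError(f"no TA at {site.t_coord}")
    if strand == "+":
        if t0 + length > len(s):
            raise ValueError(
                f"site {site.t_coord}: only {len(s) - t0} bases to sequence "
                f"end, cannot read a {length}-nt tag"
            )
        res = s[t0 : t0 + length]
    else:
        start = t0 + 2 - length
        if start < 0:
            raise ValueError(
                f"site {site.t_coord}: only {t0 + 2} bases from sequence "
                f"start, cannot read a {length}-nt tag"
            )
        res = revcomp(s[start : t0 + 2])
    label = f"{seq.id}:{site.t_coord}{strand}"
    if length >= 8:
        return TnTag(label=label, residues=res)
    # degenerate short read-off (e.g. length 2 -> "TA"): bypass the mapping
    # length invariant, which applies to tags meant for lookup
    tag = object.__new__(TnTag)
    object.__setattr__(tag, "label", label)
    object.__setattr__(tag, "residues", res)
    return tag


def batch_map(tags, genome, annotations=()):
    """Map a list of tags; returns (DataFrame of hits, summary dict).

    Summary counts unique loci (distinct (contig, t_coord) among all hits),
    ambiguous tags (more than one placement) and unmapped tags.
    """
    rows = []
    unmapped = []
    ambiguous = []
    loci = set()
    for tag in tags:
        hits = map_tag(tag, genome, annotations)
        if not hits:
            unmapped.append(tag.label)
            continue
        if hits[0].n_hits_total > 1:
            ambiguous.append(tag.label)
        for h in hits:
            loci.add((h.contig_id, h.t_coord))
            rows.append(
                {
                    "tag_label": h.tag_label,
                    "contig_id": h.contig_id,
                    "t_coord": h.t_coord,
                    "strand": h.strand,
                    "gene_id": h.gene_id,
                    "cds_offset": h.cds_offset,
                    "phase": h.phase,
                    "compatible_variant": h.compatible_variant,
                    "n_hits_total": h.n_hits_total,
                    "ambiguous": h.ambiguous,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "tag_label",
            "contig_id",
            "t_coord",
            "strand",
            "gene_id",
            "cds_offset",
            "phase",
            "compatible_variant",
            "n_hits_total",
            "ambiguous",
        ],
    )
    summary = {
        "n_tags": len(list(tags)),
        "n_unique_loci": len(loci),
        "n_ambiguous_tags": len(ambiguous),
        "n_unmapped_tags": len(unmapped),
        "unmapped": unmapped,
    }
    return df, summary


def read_tag_list(path) -> list[TnTag]:
    """Read tags from plain text (one per line) or two-column TSV (label, tag)."""
    tags = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                tags.append(TnTag(label=f"tag{i}", residues=parts[0]))
            else:
                tags.append(TnTag(label=parts[0], residues=parts[1]))
    return tags
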