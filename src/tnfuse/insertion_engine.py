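"""TA target-site enumeration, codon-phase classification, and insertion construction.

The mariner/Himar transposase targets TA dinucleotides and duplicates them on
insertion, so every insertion adds (cargo length + 2) bases.  Because TA is
its own reverse complement, forward-strand enumeration covers both strands;
orientation is a property of an insertion event, not of the site.

A TA inside a CDS occupies one of three codon phases, which determines the
transposon variant that preserves the reading frame:

* ``P23`` — TA at codon positions 2-3 (XTA) -> open1
* ``P31`` — TA straddling two codons (XXT-AXX) -> open2
* ``P12`` — TA at codon positions 1-2 (TAX) -> open3

``cds_offset`` anchors on the T of the target TA, with the A of the ATG at
+1 and the base immediately 5' of it at -1 (no zero), reproducing the
field's convention of labelling insertions by distance from the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import CdsAnnotation, NucleotideSequence, revcomp

__all__ = [
    "TASite",
    "InsertionEvent",
    "IntegrityError",
    "PHASE_TO_VARIANT",
    "classify_phase",
    "enumerate_ta_sites",
    "apply_insertion",
    "excise_insertion",
]

PHASE_TO_VARIANT = {"P23": "open1", "P31": "open2", "P12": "open3"}

_POS_TO_PHASE = {1: "P12", 2: "P23", 3: "P31"}


class IntegrityError(ValueError):
    """The sequence does not carry the expected bases at the site."""


@dataclass(frozen=True)
class TASite:
    """A TA dinucleotide occurrence on the forward strand.

    ``t_coord`` is the 1-based coordinate of the T.  For a site inside a
    CDS, ``cds_offset`` is the 1-based position of the T on the reading
    strand of that CDS (negative for upstream positions, no zero) and
    ``phase`` is the codon-phase class; otherwise both are None.
    """

    contig_id: str
    t_coord: int
    in_cds: bool = False
    gene_id: str | None = None
    cds_offset: int | None = None
    phase: str | None = None
    upstream: bool = False

    def __post_init__(self) -> None:
        if self.in_cds and self.phase is None:
            raise ValueError("in-CDS site must carry a phase")
        if not self.in_cds and self.phase is not None and not self.upstream:
            raise ValueError("phase requires in_cds or upstream")


@dataclass(frozen=True)
class InsertionEvent:
    """A transposon insertion at a site, with orientation.

    Only a cooriented event whose site phase matches the variant's
    compatible phase can be productive (yield an in-frame fusion).
    """

    site: TASite
    variant_name: str
    orientation: str = "coorient"

    def __post_init__(self) -> None:
        if self.orientation not in ("coorient", "antisense"):
            raise ValueError(f"bad orientation {self.orientation!r}")


def classify_phase(cds_offset: int) -> tuple[str, bool]:
    """Codon phase of the T at a CDS offset; returns (phase, upstream_flag).

    For positive offsets, position-in-codon p = ((offset - 1) mod 3) + 1;
    p=2 -> P23, p=3 -> P31, p=1 -> P12.  Negative offsets (upstream of the
    start codon, -1 is the base immediately 5' of the A of ATG) are
    classified by extending the codon grid leftward and flagged upstream.
    Offset 0 does not exist.
    """
    if cds_offset == 0:
        raise ValueError("cds_offset 0 is undefined (convention has no zero)")
    if cds_offset > 0:
        p = ((cds_offset - 1) % 3) + 1
        return _POS_TO_PHASE[p], False
    p = 3 - ((-cds_offset - 1) % 3)
    return _POS_TO_PHASE[p], True


def _site_for_cds(contig_id, t_coord, ann: CdsAnnotation) -> TASite | None:
    """Classify a forward-strand TA against one CDS, or None if outside."""
    a_coord = t_coord + 1
    if ann.strand == "+":
        if not (ann.start <= t_coord and a_coord <= ann.end):
            return None
        off = t_coord - ann.start + 1
    else:
        # reading-strand T of the palindromic TA sits at the forward A
        if not (ann.start <= t_coord and a_coord <= ann.end):
            return None
        off = ann.end - a_coord + 1
    phase, _ = classify_phase(off)
    return TASite(
        contig_id=contig_id,
        t_coord=t_coord,
        in_cds=True,
        gene_id=ann.gene_id,
        cds_offset=off,
        phase=phase,
    )


def enumerate_ta_sites(
    seq: NucleotideSequence, annotations=()
) -> list[TASite]:
    """Every TA occurrence on the forward strand, once per overlapping CDS.

    Sites not covered by any complete CDS are reported once with no phase.
    Partial CDSs are ignored for phase assignment.  Annotations outside the
    sequence bounds raise ``ValueError``.
    """
    for ann in annotations:
        if ann.end > len(seq) or ann.start < 1:
            raise ValueError(
                f"annotation {ann.gene_id} [{ann.start},{ann.end}] outside "
                f"sequence of length {len(seq)}"
            )
    s = seq.residues
    out = []
    for i in range(len(s) - 1):
        if s[i : i + 2] != "TA":
            continue
        t_coord = i + 1
        hits = []
        for ann in annotations:
            if ann.partial:
                continue
            site = _site_for_cds(seq.id, t_coord, ann)
            if site is not None:
                hits.append(site)
        if hits:
            out.extend(hits)
        else:
            out.append(TASite(contig_id=seq.id, t_coord=t_coord))
    return out


def apply_insertion(
    seq: NucleotideSequence,
    site: TASite,
    cargo,
    orientation: str = "coorient",
) -> NucleotideSequence:
    """Insert a cargo at a TA site with target-site duplication.

    Output = seq[..through the TA] + cargo (reverse-complemented if
    antisense) + TA + seq[after the TA..]; length grows by len(cargo) + 2.
    """
    s = seq.residues
    t0 = site.t_coord - 1
    if s[t0 : t0 + 2] != "TA":
        raise IntegrityError(
            f"site {site.t_coord}: reference bases are {s[t0:t0 + 2]!r}, not TA"
        )
    cargo_res = cargo if isinstance(cargo, str) else cargo.residues
    if orientation == "antisense":
        cargo_res = revcomp(cargo_res)
    elif orientation != "coorient":
        raise ValueError(f"bad orientation {orientation!r}")
    return NucleotideSequence(
        id=seq.id,
        residues=s[: t0 + 2] + cargo_res + "TA" + s[t0 + 2 :],
    )


def excise_insertion(
    seq: NucleotideSequence, site: TASite, cargo_len: int
) -> NucleotideSequence:
    """Remove a cargo and one TA copy; exact inverse of :func:`apply_insertion`.

    Verifies the junction bases (TA ... cargo ... TA) before cutting and
    raises :class:`IntegrityError` on any inconsistency.
    """
    s = seq.residues
    t0 = site.t_coord - 1
    if s[t0 : t0 + 2] != "TA":
        raise IntegrityError(f"no TA at upstream junction {site.t_coord}")
    dup_start = t0 + 2 + cargo_len
    if s[dup_start : dup_start + 2] != "TA":
        raise IntegrityError(
            f"no duplicated TA at offset {dup_start + 1} "
            f"(cargo_len {cargo_len} inconsistent with an insertion here)"
        )
    return NucleotideSequence(
        id=seq.id, residues=s[: t0 + 2] + s[dup_start + 2 :]
    )
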