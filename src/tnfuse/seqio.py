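"""Sequence and annotation I/O, core nucleotide operations, and synthetic fixtures.

All user-facing coordinates are 1-based inclusive (GFF convention); any
0-based arithmetic is confined to function bodies.  Sequences are stored
upper-case over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "CdsAnnotation",
    "FixtureSpec",
    "ParseError",
    "ConstructionError",
    "read_fasta",
    "write_fasta",
    "read_gff_cds",
    "write_gff",
    "translate",
    "revcomp",
    "generate_fixture_gene",
    "synthetic_reporter_cds",
]

_ALPHABET = set("ACGTN")

# Stop codons of the standard bacterial code.
STOP_CODONS = {"TAA", "TAG", "TGA"}


class ParseError(ValueError):
    """Malformed input file."""


class ConstructionError(ValueError):
    """A fixture request that cannot be satisfied."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over {A, C, G, T, N}.

    Input residues are normalized to upper case; anything outside the
    alphabet raises ``ValueError``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper()
        bad = set(norm) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class CdsAnnotation:
    """A CDS feature, 1-based inclusive coordinates as in GFF3.

    ``partial`` is set when the span length is not a multiple of 3; such
    records are excluded from codon-phase analysis but still returned.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"CDS {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.gene_id}: bad strand {self.strand!r}")
        if (self.end - self.start + 1) % 3 != 0 and not self.partial:
            object.__setattr__(self, "partial", True)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FixtureSpec:
    """Request for a synthetic CDS with TA sites at prescribed codon phases.

    ``requested_phases`` is a list of (phase, codon_index) pairs, codon
    indices 1-based with codon 1 the ATG and codon ``n_codons`` the stop.
    """

    n_codons: int
    requested_phases: tuple = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 3:
            raise ValueError("n_codons must be >= 3 (start + internal + stop)")
        object.__setattr__(
            self, "requested_phases", tuple(self.requested_phases)
        )


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a (possibly multi-record) FASTA file.

    IDs are taken from the header up to the first whitespace; residues are
    normalized to upper case.  An empty file yields an empty list.
    """
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(NucleotideSequence(id=rec.id, residues=str(rec.seq)))
    except ValueError as exc:  # biopython signals malformed records
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fasta(path, seqs) -> None:
    """Write sequences as FASTA wrapped at 70 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


def read_gff_cds(path) -> list[CdsAnnotation]:
    """Extract CDS features from a GFF3 file.

    Returns only CDS-typed features, coordinates kept 1-based inclusive.
    The gene_id is taken from the ID attribute, falling back to Parent,
    then to gene.  A CDS whose length is not a multiple of 3 is returned
    with its partial flag set.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: not a parseable GFF3 file ({exc})") from exc
    out = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype != "CDS":
            continue
        gene_id = (
            feat.attributes.get("ID")
            or feat.attributes.get("Parent")
            or feat.attributes.get("gene")
            or [feat.id]
        )[0]
        out.append(
            CdsAnnotation(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return out


def write_gff(path, rows, source: str = "tnfuse") -> None:
    """Write GFF3 feature rows.

    ``rows`` are (contig, ftype, start, end, strand, attributes-dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, ftype, start, end, strand, attrs in rows:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{contig}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr_s}\n"
            )


def translate(seq, frame_offset: int = 0) -> str:
    """Translate with the standard bacterial code, full-frame scan semantics.

    Translation proceeds codon by codon from ``frame_offset``; stop codons
    are rendered ``*`` and translation continues (so internal stops are
    visible to callers); a trailing partial codon is dropped; any codon
    containing N becomes ``X``.
    """
    if not 0 <= frame_offset <= 2:
        raise ValueError("frame_offset must be 0..2")
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    s = s[frame_offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    aa = str(Seq(s).translate(table=11))
    # biopython renders N-containing codons as X already
    return aa


def revcomp(seq):
    """Reverse complement; an involution.  Accepts str or NucleotideSequence."""
    if isinstance(seq, NucleotideSequence):
        return NucleotideSequence(
            id=seq.id, residues=str(Seq(seq.residues).reverse_complement())
        )
    return str(Seq(seq.upper()).reverse_complement())


# Filler codons for fixture genes: no internal TA, never end in T (so no
# cross-codon TA with a following A), never start with A (so no cross-codon
# TA after a T), not stops.
_FILLER_CODONS = ("GGC", "GCC", "CTG", "CAG", "GTG", "CGC", "TCC", "GAC")

# Codon templates that realize each phase.  P31 constrains two consecutive
# codons (T at position 3, A at position 1 of the next).
_P23_CODON = "CTA"
_P12_CODON = "TAC"
_P31_CODON = "GGT"
_P31_NEXT = "AAG"


def generate_fixture_gene(spec: FixtureSpec):
    """Build a synthetic CDS with TA sites at exactly the requested phases.

    The gene starts ATG, ends TGA, has no internal stop, and contains TA
    dinucleotides only where requested (the TGA stop contains none).
    Returns ``(NucleotideSequence, sites)`` where sites is a list of
    (phase, t_coord) with t_coord the 1-based coordinate of the T.

    Deterministic for a given seed.  Raises :class:`ConstructionError` for
    unsatisfiable requests (sites in the start/stop codon, overlapping
    constraints, out-of-range codons).
    """
    rng = random.Random(spec.seed)
    n = spec.n_codons
    codons: list = [None] * (n + 1)  # 1-based
    codons[1] = "ATG"
    codons[n] = "TGA"

    constrained: dict[int, str] = {}

    def claim(idx: int, codon: str, what: str) -> None:
        if not 2 <= idx <= n - 1:
            raise ConstructionError(
                f"{what}: codon {idx} outside internal range 2..{n - 1}"
            )
        if idx in constrained and constrained[idx] != codon:
            raise ConstructionError(
                f"{what}: codon {idx} already constrained to {constrained[idx]}"
            )
        constrained[idx] = codon

    sites = []
    for phase, idx in spec.requested_phases:
        if phase == "P23":
            claim(idx, _P23_CODON, "P23 site")
            sites.append((phase, 3 * (idx - 1) + 2))
        elif phase == "P12":
            claim(idx, _P12_CODON, "P12 site")
            sites.append((phase, 3 * (idx - 1) + 1))
        elif phase == "P31":
            claim(idx, _P31_CODON, "P31 site")
            claim(idx + 1, _P31_NEXT, "P31 site (next codon)")
            sites.append((phase, 3 * (idx - 1) + 3))
        else:
            raise ConstructionError(f"unknown phase {phase!r}")

    for idx, codon in constrained.items():
        codons[idx] = codon
    for idx in range(2, n):
        if codons[idx] is None:
            codons[idx] = rng.choice(_FILLER_CODONS)

    seq = "".join(codons[1:])
    gene = NucleotideSequence(id=f"fixture_seed{spec.seed}", residues=seq)

    # self-check: exactly the requested TA sites before the stop codon
    found = {
        i + 1
        for i in range(len(seq) - 1)
        if seq[i : i + 2] == "TA" and i + 1 < 3 * (n - 1) + 1
    }
    if found != {t for _, t in sites}:
        raise ConstructionError(
            f"fixture self-check failed: TA at {sorted(found)} vs requested "
            f"{sorted(t for _, t in sites)}"
        )
    return gene, sorted(sites, key=lambda x: x[1])


def synthetic_reporter_cds(n_residues: int, seed: int = 0) -> str:
    """A stop-free coding fragment usable as a reporter cassette stand-in.

    Synthetic: built from the fixture codon pool, so it is stop-free in
    frame 0, does not end in a stop, and is deterministic per seed.  It is
    a placeholder for a real fluorophore CDS, not a biological sequence.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = random.Random(seed)
    return "".join(rng.choice(_FILLER_CODONS) for _ in range(n_residues))
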