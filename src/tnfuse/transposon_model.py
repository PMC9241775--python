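"""The three open-frame transposon architectures and their frame arithmetic.

Each variant carries a promoterless fluorescent reporter (no stop codon)
between two 27-bp mariner ITRs, plus short spacers sized so that the whole
cargo plus the 2-bp target-site duplication is a multiple of 3 — the
condition for the reading frame downstream of the insertion to be restored:

======= ========= ========= ================
variant 5' spacer 3' spacer matching phase
======= ========= ========= ================
open1   0 bp      1 bp      P23 (XTA)
open2   2 bp      2 bp      P31 (XXT-AXX)
open3   1 bp      3 bp      P12 (TAX)
======= ========= ========= ================

For a P12 entry the duplicated TA occupies codon positions 1-2, so an ITR
beginning with A immediately creates a TAA stop at the junction — the
hazard that makes the open3 frame require ITR modification.  The default
ITR is the canonical 27-bp Himar1 mariner repeat; any configured ITR is
validated by :func:`scan_itr_stops` rather than assumed stop-free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .seqio import STOP_CODONS, revcomp, translate

__all__ = [
    "ItrSequence",
    "ReporterCassette",
    "TransposonVariant",
    "CargoSequence",
    "ValidationReport",
    "HIMAR1_ITR",
    "VARIANT_SPACERS",
    "default_variant",
    "build_cargo",
    "validate_variant",
    "scan_itr_stops",
    "generate_itr_variants",
]

# Canonical 27-bp Himar1 mariner inverted terminal repeat.  It begins with
# A, so an unmodified ITR entering in the P12 frame forms TAA at the
# junction with the duplicated TA.
HIMAR1_ITR = "ACAGGTTGGCTGATAAGTCCCCGGTCT"

# (spacer5_len, spacer3_len, compatible phase) per variant; the lengths are
# what the frame arithmetic depends on.
VARIANT_SPACERS = {
    "open1": (0, 1, "P23"),
    "open2": (2, 2, "P31"),
    "open3": (1, 3, "P12"),
}

# Default spacer bases, chosen stop-free against the default ITR in the
# matching entry frame (base identities are a configurable slot).
_DEFAULT_SPACER_SEQS = {
    "open1": ("", "A"),
    "open2": ("GG", "GG"),
    "open3": ("G", "GGG"),
}

# Codon offset of the first upstream-ITR base for each entry phase: P23
# completes a codon with the TA; P31 consumes one base (the duplicated A);
# P12 consumes two (the duplicated TA).
ENTRY_CONSUMED = {"P23": 0, "P31": 1, "P12": 2}


@dataclass(frozen=True)
class ItrSequence:
    """One inverted terminal repeat, upstream or downstream of the cargo."""

    residues: str
    side: str = "upstream"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"bad side {self.side!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReporterCassette:
    """A promoterless, stop-less fluorescent reporter coding fragment.

    Invariants: length a multiple of 3, no stop codon in frame 0, and no
    terminal stop — the reporter must be read through so translation can
    re-enter the target gene downstream.
    """

    cds: str
    name: str = "reporter"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", self.cds.upper())

    def problems(self) -> list[str]:
        out = []
        if len(self.cds) % 3 != 0:
            out.append(f"reporter length {len(self.cds)} not a multiple of 3")
        else:
            aa = translate(self.cds)
            if aa.endswith("*"):
                out.append("reporter ends in a stop codon")
            if "*" in aa[:-1]:
                out.append(
                    f"reporter has internal stop at residue {aa.index('*') + 1}"
                )
        return out

    def __len__(self) -> int:
        return len(self.cds)


@dataclass(frozen=True)
class TransposonVariant:
    name: str
    reporter: ReporterCassette
    itr_up: ItrSequence = field(
        default_factory=lambda: ItrSequence(HIMAR1_ITR, "upstream")
    )
    itr_down: ItrSequence = field(
        default_factory=lambda: ItrSequence(revcomp(HIMAR1_ITR), "downstream")
    )
    spacer5_seq: str = ""
    spacer3_seq: str = ""

    def __post_init__(self) -> None:
        if self.name not in VARIANT_SPACERS:
            raise ValueError(
                f"unknown variant {self.name!r}; expected one of "
                f"{sorted(VARIANT_SPACERS)}"
            )
        object.__setattr__(self, "spacer5_seq", self.spacer5_seq.upper())
        object.__setattr__(self, "spacer3_seq", self.spacer3_seq.upper())

    @property
    def spacer5_len(self) -> int:
        return len(self.spacer5_seq)

    @property
    def spacer3_len(self) -> int:
        return len(self.spacer3_seq)

    @property
    def compatible_phase(self) -> str:
        return VARIANT_SPACERS[self.name][2]


def default_variant(name: str, reporter: ReporterCassette) -> TransposonVariant:
    """A stock variant with the canonical ITRs and default spacer bases."""
    s5, s3 = _DEFAULT_SPACER_SEQS[name]
    return TransposonVariant(
        name=name, reporter=reporter, spacer5_seq=s5, spacer3_seq=s3
    )


@dataclass(frozen=True)
class CargoSequence:
    """The mobilized DNA: itr_up + spacer5 + reporter + spacer3 + itr_down.

    ``segment_map`` tiles the cargo exactly with 1-based inclusive spans.
    """

    residues: str
    variant_name: str
    segment_map: tuple

    def __post_init__(self) -> None:
        pos = 1
        for label, start, end in self.segment_map:
            if start != pos and not (start > end):  # empty segments allowed
                raise ValueError(
                    f"segment {label} starts at {start}, expected {pos}"
                )
            pos = max(pos, end + 1)
        if pos != len(self.residues) + 1:
            raise ValueError("segment map does not tile the cargo")

    def segment(self, label: str) -> str:
        for lab, start, end in self.segment_map:
            if lab == label:
                return self.residues[start - 1 : end]
        raise KeyError(label)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ValidationReport:
    """Pass/fail per rule; ``ok`` iff every rule passed."""

    checks: tuple  # (rule name, passed, detail)

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def failures(self) -> list[str]:
        return [f"{name}: {detail}" for name, passed, detail in self.checks if not passed]


def validate_variant(variant: TransposonVariant) -> ValidationReport:
    """Check reporter invariants, spacer lengths, and frame balance.

    Frame balance: |itr_up| + spacer5 + |reporter| + spacer3 + |itr_down|
    + 2 (the TA duplication) must be divisible by 3, the necessary
    condition for downstream frame restoration.
    """
    checks = []
    rep_problems = variant.reporter.problems()
    checks.append(
        ("reporter", not rep_problems, "; ".join(rep_problems) or "ok")
    )
    want5, want3, _ = VARIANT_SPACERS[variant.name]
    checks.append(
        (
            "spacer5_len",
            variant.spacer5_len == want5,
            f"{variant.spacer5_len} (expected {want5} for {variant.name})",
        )
    )
    checks.append(
        (
            "spacer3_len",
            variant.spacer3_len == want3,
            f"{variant.spacer3_len} (expected {want3} for {variant.name})",
        )
    )
    total = (
        len(variant.itr_up)
        + variant.spacer5_len
        + len(variant.reporter)
        + variant.spacer3_len
        + len(variant.itr_down)
        + 2
    )
    checks.append(
        (
            "frame_balance",
            total % 3 == 0,
            f"cargo + TA duplication = {total} ({total % 3} mod 3)",
        )
    )
    return ValidationReport(checks=tuple(checks))


def build_cargo(variant: TransposonVariant) -> CargoSequence:
    """Assemble the mobilized cargo with its segment map."""
    report = validate_variant(variant)
    if not report.ok:
        raise ValueError(
            "invalid variant: " + "; ".join(report.failures())
        )
    parts = [
        ("itr_up", variant.itr_up.residues),
        ("spacer5", variant.spacer5_seq),
        ("reporter", variant.reporter.cds),
        ("spacer3", variant.spacer3_seq),
        ("itr_down", variant.itr_down.residues),
    ]
    segmap = []
    pos = 1
    for label, res in parts:
        segmap.append((label, pos, pos + len(res) - 1))
        pos += len(res)
    return CargoSequence(
        residues="".join(res for _, res in parts),
        variant_name=variant.name,
        segment_map=tuple(segmap),
    )


def scan_itr_stops(
    itr: ItrSequence | str,
    entry_phase: str,
    preceded_by_ta: bool = True,
) -> list[tuple[int, str]]:
    """Stop codons read through the upstream junction for a given entry phase.

    Translates the junction context (the duplicated TA when present,
    then the ITR) in the frame the entry phase implies and returns
    (1-based ITR codon-start offset, codon) for every stop encountered
    before the reporter; offset 0 denotes the TA-spanning junction codon.
    For P12 entry the junction codon is T + A + itr[0], so an ITR starting
    with A yields an immediate TAA stop.
    """
    res = itr.residues if isinstance(itr, ItrSequence) else itr.upper()
    consumed = ENTRY_CONSUMED[entry_phase]
    context = ("TA"[2 - consumed :] if preceded_by_ta else "") + res
    # context starts at a codon boundary by construction
    stops = []
    for i in range(0, len(context) - 2, 3):
        codon = context[i : i + 3]
        if codon in STOP_CODONS:
            itr_offset = i - (consumed if preceded_by_ta else 0)
            stops.append((itr_offset + 1 if itr_offset >= 0 else 0, codon))
    return stops


def generate_itr_variants(
    itr: ItrSequence,
    mutable_positions,
    allowed_substitutions,
) -> list[dict]:
    """Enumerate ITR substitution combinations and score their P12 junction.

    ``mutable_positions`` are 1-based positions within the ITR;
    ``allowed_substitutions`` gives the base set per position (parallel
    list).  Every combination is returned annotated with its substitution
    set and the stop codons it leaves for a P12 entry; combinations
    retaining a junction stop are flagged.
    """
    if len(mutable_positions) != len(allowed_substitutions):
        raise ValueError("one substitution set required per mutable position")
    for pos, subs in zip(mutable_positions, allowed_substitutions):
        if not 1 <= pos <= len(itr):
            raise ValueError(f"position {pos} outside ITR of length {len(itr)}")
        if not subs:
            raise ValueError(f"empty substitution set at position {pos}")
    out = []
    for combo in itertools.product(*allowed_substitutions):
        bases = list(itr.residues)
        for pos, base in zip(mutable_positions, combo):
            bases[pos - 1] = base.upper()
        new = ItrSequence("".join(bases), itr.side)
        stops = scan_itr_stops(new, "P12", preceded_by_ta=True)
        out.append(
            {
                "itr": new,
                "substitutions": tuple(zip(mutable_positions, combo)),
                "p12_stops": stops,
                "has_junction_stop": bool(stops),
            }
        )
    return out


def load_variants(path, reporter_dir=None) -> list[TransposonVariant]:
    """Load variant definitions from a YAML config file.

    Schema::

        variants:
          - name: open1
            itr_up: ACAGGT...        # optional; default Himar1 repeat
            itr_down: ...            # optional; default revcomp of itr_up
            spacer5: ""              # optional; stock default per name
            spacer3: "A"
            reporter_fasta: rep.fasta   # first record used
            reporter: GGTGGC...         # inline alternative

    Paths in ``reporter_fasta`` are resolved relative to ``reporter_dir``
    (default: the config file's directory).
    """
    import pathlib

    import yaml

    from .seqio import read_fasta

    path = pathlib.Path(path)
    base = pathlib.Path(reporter_dir) if reporter_dir else path.parent
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = []
    for entry in cfg.get("variants", []):
        name = entry["name"]
        if "reporter" in entry:
            rep_cds = entry["reporter"]
        elif "reporter_fasta" in entry:
            recs = read_fasta(base / entry["reporter_fasta"])
            if not recs:
                raise ValueError(f"{entry['reporter_fasta']}: no records")
            rep_cds = recs[0].residues
        else:
            raise ValueError(f"variant {name}: needs reporter or reporter_fasta")
        s5_default, s3_default = _DEFAULT_SPACER_SEQS[name]
        itr_up = entry.get("itr_up", HIMAR1_ITR)
        itr_down = entry.get("itr_down", revcomp(itr_up))
        out.append(
            TransposonVariant(
                name=name,
                reporter=ReporterCassette(rep_cds, name=entry.get("reporter_name", "reporter")),
                itr_up=ItrSequence(itr_up, "upstream"),
                itr_down=ItrSequence(itr_down, "downstream"),
                spacer5_seq=entry.get("spacer5", s5_default),
                spacer3_seq=entry.get("spacer3", s3_default),
            )
        )
    return out
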