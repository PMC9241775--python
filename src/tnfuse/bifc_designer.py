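"""Split-fluorophore constructs for bimolecular fluorescence complementation.

A fluorophore CDS is cut after a chosen residue into a proximal (N-terminal)
and a distal (C-terminal) coding fragment with no overlap or gap.  The bait
fuses a protein of interest in frame to the N fragment (nonfluorescent on
its own); the prey is a transposon whose reporter cassette is the C
fragment, delivered at random TA sites.  An interaction between bait and
prey fusion partners brings the two fragments into proximity and restores
fluorescence — photophysics is not modeled here, only construct validity.

The default split after residue 154 mirrors the split-Venus convention:
a 717-nt CDS yields a 462-bp N fragment and a 255-bp (85-residue) C
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import translate
from .transposon_model import (
    ReporterCassette,
    TransposonVariant,
    _DEFAULT_SPACER_SEQS,
    validate_variant,
)

__all__ = [
    "SplitFluorophore",
    "BaitConstruct",
    "DEFAULT_SPLIT_RESIDUE",
    "split_fluorophore",
    "build_bait",
    "build_prey_transposon",
    "detect_self_insertion",
]

DEFAULT_SPLIT_RESIDUE = 154


@dataclass(frozen=True)
class SplitFluorophore:
    """A fluorophore CDS cut into complementary coding fragments.

    ``frag_n_cds + frag_c_cds == full_cds`` exactly; the N fragment encodes
    ``split_residue`` residues.
    """

    full_cds: str
    split_residue: int
    frag_n_cds: str
    frag_c_cds: str

    @property
    def n_len_bp(self) -> int:
        return len(self.frag_n_cds)

    @property
    def c_len_bp(self) -> int:
        return len(self.frag_c_cds)

    @property
    def c_len_residues(self) -> int:
        return len(self.frag_c_cds) // 3


@dataclass(frozen=True)
class BaitConstruct:
    """target + linker + N-terminal fluorophore fragment + stop, in frame."""

    target_cds: str
    linker: str
    frag_n_cds: str
    stop_codon: str = "TAA"

    @property
    def residues(self) -> str:
        return self.target_cds + self.linker + self.frag_n_cds + self.stop_codon

    def segment_spans(self):
        """1-based inclusive nucleotide spans of target/linker/fragN/stop."""
        spans = []
        pos = 1
        for label, s in (
            ("target", self.target_cds),
            ("linker", self.linker),
            ("frag_n", self.frag_n_cds),
            ("stop", self.stop_codon),
        ):
            if s:
                spans.append((label, pos, pos + len(s) - 1))
                pos += len(s)
        return spans

    def __len__(self) -> int:
        return len(self.residues)


def split_fluorophore(cds: str, split_residue: int = DEFAULT_SPLIT_RESIDUE) -> SplitFluorophore:
    """Cut a stop-free fluorophore CDS after ``split_residue`` residues.

    The CDS length must be a multiple of 3 and the split strictly internal
    (0 < split_residue < length/3).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    n_res = len(cds) // 3
    if not 0 < split_residue < n_res:
        raise ValueError(
            f"split_residue {split_residue} outside open range (0, {n_res})"
        )
    cut = 3 * split_residue
    return SplitFluorophore(
        full_cds=cds,
        split_residue=split_residue,
        frag_n_cds=cds[:cut],
        frag_c_cds=cds[cut:],
    )


def build_bait(
    target_cds: str, split: SplitFluorophore, linker: str = ""
) -> BaitConstruct:
    """In-frame target + linker + N fragment + stop, validated by translation.

    The target CDS is given with its stop removed (it would arrest
    translation before the fluorophore fragment); an internal stop anywhere
    in the fused frame is a build error naming the residue.
    """
    target_cds = target_cds.upper()
    linker = linker.upper()
    if len(target_cds) % 3 != 0:
        raise ValueError(f"target CDS length {len(target_cds)} not a multiple of 3")
    if len(linker) % 3 != 0:
        raise ValueError(f"linker length {len(linker)} not a multiple of 3")
    bait = BaitConstruct(
        target_cds=target_cds, linker=linker, frag_n_cds=split.frag_n_cds
    )
    aa = translate(bait.residues)
    internal = aa[:-1]
    if "*" in internal:
        raise ValueError(
            f"internal stop at residue {internal.index('*') + 1} of the bait frame"
        )
    if not aa.endswith("*"):
        raise ValueError("bait construct does not end in a stop codon")
    return bait


def build_prey_transposon(
    variant_name: str,
    split: SplitFluorophore,
    allow_open3: bool = False,
    **variant_kwargs,
) -> TransposonVariant:
    """A transposon variant whose reporter is the C-terminal fragment.

    The open3 frame is refused by default (its mandatory ITR modification
    makes it nonfunctional in practice); pass ``allow_open3=True`` to build
    it anyway.  The resulting variant passes full validation.
    """
    if variant_name == "open3" and not allow_open3:
        raise ValueError(
            "open3 prey refused: the P12 frame requires ITR modification and "
            "transposes too rarely to screen; pass allow_open3=True to override"
        )
    reporter = ReporterCassette(cds=split.frag_c_cds, name="fragC")
    s5, s3 = _DEFAULT_SPACER_SEQS[variant_name]
    variant_kwargs.setdefault("spacer5_seq", s5)
    variant_kwargs.setdefault("spacer3_seq", s3)
    variant = TransposonVariant(
        name=variant_name, reporter=reporter, **variant_kwargs
    )
    report = validate_variant(variant)
    if not report.ok:
        raise ValueError("invalid prey variant: " + "; ".join(report.failures()))
    return variant


def detect_self_insertion(bait: BaitConstruct, t_coord: int) -> dict:
    """Topology of a prey insertion landing inside the bait construct.

    Given the 1-based coordinate of the target TA's T within the bait ORF,
    reports the segment order of the resulting primary sequence — e.g. an
    insertion within the bait's target region yields
    [target_N, fragC, target_C, fragN], and one within fragN puts the two
    fluorophore fragments in swapped order.  Coordinates outside the bait
    return ``{"within_bait": False}``.
    """
    spans = bait.segment_spans()
    if not 1 <= t_coord <= len(bait):
        return {"within_bait": False, "topology": ()}
    hit = None
    for label, s, e in spans:
        if s <= t_coord <= e:
            hit = label
            break
    part_names = {"target": ("target_N", "target_C")}
    topology = []
    for label, s, e in spans:
        if label == "stop":
            continue
        if label == hit:
            p1, p2 = part_names.get(label, (f"{label}_part1", f"{label}_part2"))
            topology.append(p1 if t_coord > s else label)
            topology.append("frag_c")
            if t_coord + 1 < e:
                topology.append(p2)
        else:
            topology.append(label)
    frag_c_pos = topology.index("frag_c")
    frag_n_pos = max(
        i for i, lab in enumerate(topology) if lab.startswith("frag_n")
    )
    return {
        "within_bait": True,
        "hit_segment": hit,
        "topology": tuple(topology),
        "fragments_swapped": frag_c_pos < frag_n_pos,
    }
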