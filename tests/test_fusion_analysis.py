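"""Fusion-protein prediction, frame verification, scanning, and deduplication."""

import random

import pytest
from Bio.Seq import Seq

from tnfuse import (
    CdsAnnotation,
    FixtureSpec,
    InsertionEvent,
    ItrSequence,
    NucleotideSequence,
    ReporterCassette,
    TransposonVariant,
    build_cargo,
    dedup_candidates,
    default_variant,
    enumerate_ta_sites,
    generate_fixture_gene,
    phase_arithmetic_productive,
    predict_fusion_protein,
    scan_gene,
    scan_genome,
    synthetic_reporter_cds,
    verify_orf,
)

PHASE_TO_VARIANT = {"P23": "open1", "P31": "open2", "P12": "open3"}


def oracle_translate(nt: str) -> str:
    """Independent translation route for oracle checks (not tnfuse.translate)."""
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate(table=11)) if nt else ""


def make_event(gene, ann, t_coord, variant):
    (site,) = [
        s for s in enumerate_ta_sites(gene, [ann]) if s.t_coord == t_coord and s.in_cds
    ]
    return InsertionEvent(site=site, variant_name=variant.name)


class TestWorkedExample:
    """The hand-derivable toy fusion: M-L-G gene, open1 at the P23 site,
    27xA ITRs, 6-nt reporter -> a 24-residue fusion protein."""

    @pytest.fixture
    def toy_open1(self):
        return TransposonVariant(
            name="open1",
            reporter=ReporterCassette("GGTGGC"),
            itr_up=ItrSequence("A" * 27, "upstream"),
            itr_down=ItrSequence("A" * 27, "downstream"),
            spacer5_seq="",
            spacer3_seq="A",
        )

    def test_toy_fusion_protein(self, toy_gene, toy_open1):
        seq, ann = toy_gene
        cargo = build_cargo(toy_open1)
        event = make_event(seq, ann, 5, toy_open1)
        fusion = predict_fusion_protein(seq, ann, event, cargo)
        assert fusion.protein == "ML" + "K" * 9 + "GG" + "K" * 9 + "IG"
        assert len(fusion.protein) == 24
        assert fusion.premature_stop is None
        # independent oracle: translate the constructed nucleotide sequence
        mutated = seq.residues[:6] + cargo.residues + "TA" + seq.residues[6:]
        assert oracle_translate(mutated)[:-1] == fusion.protein

    def test_segments_tile_and_restore_target(self, toy_gene, toy_open1):
        seq, ann = toy_gene
        cargo = build_cargo(toy_open1)
        fusion = predict_fusion_protein(seq, ann, make_event(seq, ann, 5, toy_open1), cargo)
        rebuilt = "".join(fusion.protein[s - 1 : e] for _, s, e in fusion.segments)
        assert rebuilt == fusion.protein
        assert fusion.segment_residues("target_N") == "ML"
        assert fusion.segment_residues("reporter") == "GG"
        assert fusion.segment_residues("target_C") == "G"  # wild-type tail

    def test_antisense_event_rejected(self, toy_gene, toy_open1):
        seq, ann = toy_gene
        cargo = build_cargo(toy_open1)
        (site,) = [s for s in enumerate_ta_sites(seq, [ann]) if s.t_coord == 5]
        event = InsertionEvent(site=site, variant_name="open1", orientation="antisense")
        with pytest.raises(ValueError, match="antisense"):
            predict_fusion_protein(seq, ann, event, cargo)


class TestVerifyOrf:
    def test_productive_p23_open1_is_continuous(self, variants):
        gene, sites = generate_fixture_gene(
            FixtureSpec(n_codons=20, requested_phases=(("P23", 6),), seed=1)
        )
        ann = CdsAnnotation("g", gene.id, 1, len(gene), "+")
        cargo = build_cargo(variants["open1"])
        from tnfuse import apply_insertion
        from tnfuse.insertion_engine import TASite

        mutated = apply_insertion(gene, TASite(gene.id, sites[0][1]), cargo)
        expected_len = (len(gene) + len(cargo) + 2) // 3 - 1
        continuous, stop = verify_orf(mutated, 1, expected_len)
        assert continuous and stop is None

    def test_unmodified_itr_at_p12_stops_immediately_at_junction(self, variants):
        """The duplicated TA + leading A of the ITR forms TAA right away."""
        gene, sites = generate_fixture_gene(
            FixtureSpec(n_codons=20, requested_phases=(("P12", 6),), seed=1)
        )
        ann = CdsAnnotation("g", gene.id, 1, len(gene), "+")
        cargo = build_cargo(variants["open3"])
        event = make_event(gene, ann, sites[0][1], variants["open3"])
        fusion = predict_fusion_protein(gene, ann, event, cargo)
        assert fusion.premature_stop is not None
        # the junction codon is the one holding the duplicated TA: codon 6
        assert fusion.premature_stop == 6

    def test_requires_atg_at_start(self):
        with pytest.raises(ValueError, match="ATG"):
            verify_orf(NucleotideSequence("x", "GGGTAA"), 1, 1)


class TestMismatchLemma:
    """A variant at an incompatible phase never reads the reporter in frame."""

    @pytest.mark.parametrize(
        "phase,vname",
        [
            (p, v)
            for p in ("P23", "P31", "P12")
            for v in ("open1", "open2", "open3")
            if PHASE_TO_VARIANT[p] != v
        ],
    )
    def test_reporter_in_frame_iff_phase_matches(self, phase, vname, variants):
        variant = variants[vname]
        gene, sites = generate_fixture_gene(
            FixtureSpec(n_codons=30, requested_phases=((phase, 8),), seed=4)
        )
        t_coord = sites[0][1]
        cargo = build_cargo(variant)
        mutated = gene.residues[: t_coord + 1] + cargo.residues + "TA" + gene.residues[t_coord + 1 :]
        fused_aa = oracle_translate(mutated)
        reporter_aa = oracle_translate(variant.reporter.cds)
        assert reporter_aa not in fused_aa
        assert not phase_arithmetic_productive(phase, variant)


class TestOracleEquivalence:
    def _brute_force_productive(self, gene, t_coord, variant):
        """Oracle: construct by string surgery, translate with biopython,
        demand an unbroken frame with the reporter peptide in frame and the
        wild-type tail restored."""
        cargo = build_cargo(variant)
        mutated = (
            gene.residues[: t_coord + 1] + cargo.residues + "TA" + gene.residues[t_coord + 1 :]
        )
        aa = oracle_translate(mutated)
        n_res = len(mutated) // 3 - 1
        if "*" in aa[:n_res]:
            return False
        reporter_aa = oracle_translate(variant.reporter.cds)
        return reporter_aa in aa[:n_res]

    def test_phase_arithmetic_matches_brute_force_translation(self, variants):
        """Fast phase arithmetic equals brute-force translation over many
        random fixtures and all 9 (phase, variant) combinations."""
        rng = random.Random(77)
        n_checked = 0
        for trial in range(30):
            phases = tuple(
                (rng.choice(["P23", "P31", "P12"]), i) for i in range(2, 60, 4)
            )
            try:
                gene, sites = generate_fixture_gene(
                    FixtureSpec(n_codons=64, requested_phases=phases, seed=trial)
                )
            except Exception:
                continue
            for _, t_coord in sites:
                phase = __import__("tnfuse").classify_phase(t_coord)[0]
                for variant in variants.values():
                    fast = phase_arithmetic_productive(phase, variant)
                    brute = self._brute_force_productive(gene, t_coord, variant)
                    assert fast == brute, (trial, t_coord, phase, variant.name)
                    n_checked += 1
        assert n_checked >= 1000


class TestScan:
    def test_one_productive_pair_per_phase(self, variants):
        gene, _ = generate_fixture_gene(
            FixtureSpec(
                n_codons=20,
                requested_phases=(("P23", 3), ("P31", 8), ("P12", 13)),
                seed=2,
            )
        )
        ann = CdsAnnotation("g1", gene.id, 1, len(gene), "+")
        rows = scan_gene(gene, ann, list(variants.values()))
        assert len(rows) == 9  # 3 sites x 3 variants
        productive = [(r["phase"], r["variant"]) for r in rows if r["productive"]]
        # open3's unmodified ITR stops at the junction, so only 2 of the 3
        # matched pairs read through
        assert ("P23", "open1") in productive
        assert ("P31", "open2") in productive
        assert ("P12", "open3") not in productive
        compat = [(r["phase"], r["variant"]) for r in rows if r["compatible"]]
        assert len(compat) == 3

    def test_gene_without_ta_sites_yields_no_rows(self, variants):
        gene, _ = generate_fixture_gene(FixtureSpec(n_codons=10, seed=6))
        ann = CdsAnnotation("g1", gene.id, 1, len(gene), "+")
        assert scan_gene(gene, ann, list(variants.values())) == []

    def test_partial_cds_skipped_with_warning(self, variants):
        gene = NucleotideSequence("g", "ATGCTAGGCTAAG")
        ann = CdsAnnotation("g1", "g", 1, 13, "+")
        with pytest.warns(UserWarning, match="partial"):
            rows = scan_gene(gene, ann, list(variants.values()))
        assert rows == []

    def test_genome_scan_is_additive_over_genes(self, variants):
        g1, _ = generate_fixture_gene(
            FixtureSpec(n_codons=15, requested_phases=(("P23", 4),), seed=3)
        )
        g2, _ = generate_fixture_gene(
            FixtureSpec(n_codons=15, requested_phases=(("P31", 5),), seed=8)
        )
        genome = NucleotideSequence("chr", g1.residues + g2.residues)
        anns = [
            CdsAnnotation("gA", "chr", 1, len(g1), "+"),
            CdsAnnotation("gB", "chr", len(g1) + 1, len(g1) + len(g2), "+"),
        ]
        report = scan_genome(genome, anns, list(variants.values()))
        per_gene = report.rows.groupby("gene_id").size().to_dict()
        only_a = scan_gene(genome, anns[0], list(variants.values()))
        assert per_gene["gA"] == len(only_a)
        assert report.summary["n_sites_in_cds"] == 2


class TestUpstreamInsertion:
    def test_reporter_first_topology(self, variants):
        """An in-frame insertion 5' of the ATG yields an N-terminal fusion:
        reporter residues first, full-length target restored after the linker."""
        gene, _ = generate_fixture_gene(FixtureSpec(n_codons=10, seed=12))
        # put a TA upstream so that its phase (extended leftward) matches open1
        # offset -2 -> position-in-codon 2 -> P23
        full = NucleotideSequence("c", "GGCCT" + "A" + gene.residues)
        # T at coord 5, A at 6; CDS starts at 7 -> offset -2
        ann = CdsAnnotation("g1", "c", 7, 6 + len(gene), "+")
        sites = enumerate_ta_sites(full, [ann])
        (site,) = [s for s in sites if s.t_coord == 5]
        assert not site.in_cds
        variant = variants["open1"]
        cargo = build_cargo(variant)
        event = InsertionEvent(site=site, variant_name="open1")
        fusion = predict_fusion_protein(full, ann, event, cargo)
        assert fusion.premature_stop is None
        labels = [lab for lab, *_ in fusion.segments]
        assert labels[0] == "reporter"
        assert labels[-1] == "target_C"
        from tnfuse import translate

        wt = translate(gene.residues)[:-1]
        assert fusion.segment_residues("target_C").endswith(wt)


class TestDedup:
    def test_screen_candidates_collapse_to_unique_sites(self):
        rows = [("ftsZ", 114), ("ftsZ", 114), ("ftsZ", 372), ("ftsZ", -4)]
        out = dedup_candidates(rows)
        assert out == [("ftsZ", 114), ("ftsZ", 372), ("ftsZ", -4)]

    def test_empty_and_identical(self):
        assert dedup_candidates([]) == []
        assert dedup_candidates([("g", 5)] * 7) == [("g", 5)]

    def test_dict_rows(self):
        rows = [
            {"gene_id": "a", "cds_offset": 1, "note": "x"},
            {"gene_id": "a", "cds_offset": 1, "note": "y"},
        ]
        assert dedup_candidates(rows) == [rows[0]]
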