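import pytest

from tnfuse import (
    CdsAnnotation,
    NucleotideSequence,
    ReporterCassette,
    default_variant,
    synthetic_reporter_cds,
)

PHASES = ("P23", "P31", "P12")
PHASE_TO_VARIANT = {"P23": "open1", "P31": "open2", "P12": "open3"}


@pytest.fixture
def toy_gene():
    """ATG CTA GGC TAA: M-L-G-stop with a P23 site at 5 and a P12 site at 10."""
    seq = NucleotideSequence("g", "ATGCTAGGCTAA")
    ann = CdsAnnotation(gene_id="g1", contig_id="g", start=1, end=12, strand="+")
    return seq, ann


@pytest.fixture
def reporter():
    return ReporterCassette(cds=synthetic_reporter_cds(80, seed=11), name="rep")


@pytest.fixture
def variants(reporter):
    return {name: default_variant(name, reporter) for name in ("open1", "open2", "open3")}
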