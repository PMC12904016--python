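import numpy as np
import pytest

from ncsplice.reference import GenomeRef, TranscriptModel, build_transcript
from ncsplice.simulate import SimulationConfig, gen_transcriptome


@pytest.fixture(scope="session")
def toy_genome_transcripts():
    """A small deterministic transcriptome shared across tests."""
    cfg = SimulationConfig(seed=42, n_transcripts=8, n_variants=0)
    return gen_transcriptome(cfg)


@pytest.fixture(scope="session")
def toy_transcript(toy_genome_transcripts):
    genome, transcripts = toy_genome_transcripts
    return transcripts[0]


@pytest.fixture()
def three_exon_mk():
    """Minimal 3-exon gene whose CDS 'ATG AAA TAA' is split across exons."""
    #           exon1       intron      exon2    intron    exon3
    seq = "TTTT" + "ATGA" + "GTCCAG" + "AAT" + "GTTTAG" + "AA" + "TTTT"
    genome = GenomeRef({"c1": seq})
    model = TranscriptModel(
        transcript_id="MK",
        gene="MK",
        contig="c1",
        strand="+",
        exons=[(5, 8), (15, 17), (24, 25)],
        cds_start=5,
        cds_end=25,
    )
    return genome, build_transcript(genome, model)
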