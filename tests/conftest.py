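import pytest

from mtrkit.simulate import SimulationConfig, simulate_standing_variation, simulate_transcript
from mtrkit.transcripts import TranscriptModel


@pytest.fixture
def mini_model() -> TranscriptModel:
    """ATG AAA TGC CTG (TAA): 4 protein codons on one exon, plus strand."""
    return TranscriptModel(
        transcript_id="TX1",
        gene_symbol="G1",
        chromosome="1",
        strand="+",
        exon_blocks=((101, 115),),
        cds_sequence="ATGAAATGCCTGTAA",
    )


@pytest.fixture(scope="session")
def sim_model_and_sites():
    """A 400-codon simulated transcript with depleted region and its variation."""
    cfg = SimulationConfig(seed=11)
    model = simulate_transcript(cfg)
    sites = simulate_standing_variation(model, cfg)
    return cfg, model, sites
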