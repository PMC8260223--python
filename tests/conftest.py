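import numpy as np
import pytest

from afexon.core import ExonModel, GenomeInterval, TranscriptModel
from afexon.events import build_events
from afexon.simulate import make_toy_annotation, simulate_junction_counts


def tx(tid, gene, blocks, strand="+", source="reference"):
    """Build a transcript from genomic exon blocks given in transcription order."""
    ivs = [GenomeInterval("chr1", s, e, strand) for s, e in blocks]
    return TranscriptModel(tid, gene, [ExonModel(iv, i + 1) for i, iv in enumerate(ivs)], source=source)


@pytest.fixture(scope="session")
def toy_annotation():
    return make_toy_annotation(n_genes=28, afe_fraction=0.5, n_first_exons=2, seed=3)


@pytest.fixture(scope="session")
def toy_counts(toy_annotation):
    transcripts, truth = toy_annotation
    counts = simulate_junction_counts(transcripts, truth, seed=4)
    return counts


@pytest.fixture(scope="session")
def toy_events(toy_annotation):
    transcripts, _ = toy_annotation
    return build_events(transcripts)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
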