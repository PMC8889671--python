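import numpy as np
import pytest

from cas13guide.pipeline import assemble_study
from cas13guide.seq_io import TranscriptRecord
from cas13guide.simulate import FixtureConfig, PlantedRule


def random_transcript(rng: np.random.Generator, tid: str, length: int) -> TranscriptRecord:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return TranscriptRecord(transcript_id=tid, sequence=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_study():
    """A small noisy compositional study shared by read-only tests."""
    config = FixtureConfig(n_transcripts=4, n_total_guides=80, seed=11)
    return assemble_study(config)


@pytest.fixture(scope="session")
def planted_study():
    """Class is a deterministic function of the spacer nucleotide at one
    position; replicate noise is low. Used for signal-recovery tests."""
    config = FixtureConfig(
        n_transcripts=6,
        n_total_guides=200,
        planted_rule=PlantedRule(kind="nucleotide_at", position=8),
        replicate_noise_sd=0.02,
        seed=5,
    )
    return assemble_study(config)
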