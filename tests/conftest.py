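"""Shared fixtures: a small deterministic viability table and transcriptome."""

import pytest

from riscfrag.io_formats import SmallRead
from riscfrag.synthetic_data import (
    SimulationConfig,
    generate_transcriptome,
    generate_viability_table,
)


@pytest.fixture(scope="session")
def viability_table():
    """Synthetic 4096-seed viability table, fixed seed."""
    return generate_viability_table(7)


@pytest.fixture(scope="session")
def small_config():
    """A small but complete simulation configuration."""
    return SimulationConfig(
        seed=11,
        n_transcripts=2,
        transcript_length_range=(300, 500),
        n_clusters_per_transcript=3,
        cluster_length=60,
        reads_per_cluster=40,
        mirna_fraction=0.2,
    )


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return generate_transcriptome(small_config)


def make_read(sequence, count=1, replicate="rep1", sample_id=""):
    """Convenience constructor for a single-replicate read."""
    return SmallRead(sequence, {replicate: count}, sample_id)
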