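import numpy as np
import pytest

from methylcall import (
    SimulationConfig,
    assign_true_methylome,
    simulate_bisulfite_reads,
    simulate_gene_models,
    simulate_genome,
    tally_counts,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=3,
        n_contigs=1,
        contig_length=60_000,
        spike_in_length=8_000,
        n_genes=20,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One fully simulated dataset shared across the suite."""
    genome, _ = simulate_genome(small_config)
    models = simulate_gene_models(genome, small_config)
    methylome = assign_true_methylome(genome, models, small_config)
    reads = simulate_bisulfite_reads(genome, methylome, small_config)
    return {
        "config": small_config,
        "genome": genome,
        "models": models,
        "methylome": methylome,
        "reads": reads,
    }


@pytest.fixture(scope="session")
def small_counts(small_dataset):
    return tally_counts(small_dataset["reads"], small_dataset["genome"])


def make_read(contig, start0, strand, sequence, qualities, read_id="r1"):
    """Hand-built read for tally tests."""
    from methylcall.simulate import SimulatedRead

    return SimulatedRead(
        id=read_id,
        contig=contig,
        start0=start0,
        strand=strand,
        sequence=sequence if isinstance(sequence, bytes) else sequence.encode(),
        phred_qualities=np.asarray(qualities, dtype=np.int16),
        truth=sequence if isinstance(sequence, bytes) else sequence.encode(),
    )
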