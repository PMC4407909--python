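import numpy as np
import pytest

from ucekit import synth


@pytest.fixture(scope="session")
def genome_pair_50():
    """Planted study system: 50 elements (60-200 bp), 15% background."""
    return synth.make_genome_pair(synth.SynthSpec(seed=7, n_elements=50))


@pytest.fixture(scope="session")
def genome_pair_dup():
    """As above, but the first 5 elements carry a planted ~90% copy."""
    return synth.make_genome_pair(
        synth.SynthSpec(seed=7, n_elements=50, n_duplicated_elements=5)
    )


@pytest.fixture(scope="session")
def harvest_system():
    """40-locus system with one chimera and one duplicated-contig locus."""
    spec = synth.SynthSpec(
        seed=7, n_elements=40, n_chimeric_contigs=1, n_split_loci=1, n_decoy_contigs=10
    )
    pair = synth.make_genome_pair(spec)
    contigs, truth = synth.make_contigs(pair.genome_a, pair.truth_bed, spec, taxon="taxon1")
    return spec, pair, contigs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
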