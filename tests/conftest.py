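"""Shared fixtures: toy genomes, a small signature catalogue, simulated cohorts."""

import numpy as np
import pytest

from somascape import synthetic
from somascape.io_formats import MutationRecord
from somascape.signatures import SignatureCatalogue


@pytest.fixture(scope="session")
def toy_genome_50bp() -> dict[str, str]:
    """A fixed 50-bp single-contig genome used by brute-force overlap oracles."""
    rng = np.random.default_rng(20_240_501)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=50))}


@pytest.fixture(scope="session")
def small_catalogue() -> SignatureCatalogue:
    """A 6-signature random catalogue with peaky, well-separated columns."""
    return synthetic.simulate_signature_catalogue(n_signatures=6, seed=11)


@pytest.fixture(scope="session")
def sim_bundle():
    """One seeded genome + mutation cohort reused across read-only tests."""
    cfg = synthetic.SimulationConfig(seed=7, genome_length=60_000, n_samples=6,
                                     mutations_per_sample=2_000,
                                     remodeler_samples=(0, 1))
    genome = synthetic.simulate_genome(cfg)
    catalogue = synthetic.simulate_signature_catalogue(n_signatures=6, seed=11)
    cfg.exposures_true = synthetic.cohort_exposures(6, 6, [0, 2, 4], [0.5, 0.3, 0.2])
    mutations, manifest = synthetic.simulate_mutations(cfg, genome, catalogue)
    return cfg, genome, catalogue, mutations, manifest


def group_by_sample(mutations: list[MutationRecord]) -> dict[str, list[MutationRecord]]:
    grouped: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        grouped.setdefault(m.sample_id, []).append(m)
    return grouped


@pytest.fixture
def by_sample(sim_bundle):
    return group_by_sample(sim_bundle[3])
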