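"""Shared fixtures: the default synthetic community and one full pipeline run.

The community and pipeline are session-scoped because the CNN training
stage dominates runtime; every test that needs the default fixture shares
the same run.
"""

import numpy as np
import pytest

import hostgraph as hg

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def taxonomy():
    return hg.generate_taxonomy(5, (2, 2, 1, 1), DEFAULT_SEED)


@pytest.fixture(scope="session")
def community(taxonomy):
    return hg.generate_community(hg.CommunityParams(), taxonomy)


@pytest.fixture(scope="session")
def pipeline_result(community):
    return hg.run_pipeline(
        community.viruses,
        community.hosts,
        community.known_pairs,
        community.host_taxonomy,
        truth=community.truth,
        proteins=community.proteins,
    )


@pytest.fixture(scope="session")
def mini_community():
    """A small, fast community for integration tests."""
    tree = hg.generate_taxonomy(2, (1, 1, 1, 1), 0)
    params = hg.CommunityParams(
        n_genera=2,
        hosts_per_genus=1,
        viruses_per_genus=4,
        genes_per_genus_pool=8,
        genes_per_virus=4,
        shared_noise_genes=1,
        global_noise_pool=6,
        virus_genome_len=6000,
        host_genome_len=20000,
        rng_seed=3,
    )
    return hg.generate_community(params, tree)
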