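"""Shared fixtures: small, deterministically simulated study replicates.

All fixtures are desk-scale shrinks of the study design (fewer
chromosomes, shorter sequences, smaller effective size and family counts)
so the whole suite runs in minutes; the full-scale defaults are exercised
by the acceptance tests and the analysis scripts.
"""

import numpy as np
import pytest

from forestgs.popsim import GenomeSpec
from forestgs.experiment import simulate_replicate

SMALL_CCLONES = dict(n_founders=20, n_families=25, family_mean=8,
                     family_sd=3, total_range=(180, 220))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_spec():
    return GenomeSpec(n_chromosomes=4, n_marker_loci=400, n_qtl=30,
                      chrom_length_bp=200_000, effective_size=2000)


@pytest.fixture(scope="session")
def small_rep(small_spec):
    """One oligogenic medium-dominance replicate, ~200 genotyped individuals."""
    return simulate_replicate(small_spec, "oligogenic", "medium", seed=11,
                              n_base=200, n_select=40, n_cycle=200,
                              cclones_kwargs=SMALL_CCLONES)


@pytest.fixture(scope="session")
def small_rep_additive(small_spec):
    """A polygenic no-dominance replicate on the same genome scale."""
    import dataclasses
    spec = dataclasses.replace(small_spec, n_qtl=200)
    return simulate_replicate(spec, "polygenic", "none", seed=13,
                              n_base=200, n_select=40, n_cycle=200,
                              cclones_kwargs=SMALL_CCLONES)
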