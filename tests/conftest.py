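"""Shared fixtures: a desk-scale simulated study and its mapped reads.

The ``small_study`` fixture is deliberately reduced (2 chromosomes of
50 kb, 30k reads per library) so the whole unit suite stays fast; the
full-scale reference simulation used by the acceptance tests lives in
``test_acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pytest

from smrnapipe import read_mapping
from smrnapipe.io_formats import Interval
from smrnapipe.synthetic_data import (
    PlantedCluster,
    SimulationConfig,
    simulate_study,
)


def small_config(seed: int = 7) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=50_000,
        n_library_reads=30_000,
        n_genes_per_chrom=12,
        n_known_mirna_per_chrom=4,
        n_te_per_family=4,
        n_bisulfite_clones=12,
    )


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def small_index(small_study):
    return read_mapping.build_index(small_study.genome)


@pytest.fixture(scope="session")
def small_placements(small_study, small_index):
    return {
        genotype: read_mapping.map_reads(library, small_index)
        for genotype, library in small_study.libraries.items()
    }


@pytest.fixture(scope="session")
def small_candidates(small_study, small_placements):
    from smrnapipe.mirna_analysis import discover_novel

    placements = small_placements["mut"] + small_placements["wt"]
    return discover_novel(placements, small_study.annotation, small_study.genome)


def random_genome(rng: np.random.Generator, lengths) -> list:
    from smrnapipe.io_formats import GenomeSequence

    bases = np.array(list("ACGT"))
    return [
        GenomeSequence(f"chr{i + 1}", "".join(rng.choice(bases, size=n)))
        for i, n in enumerate(lengths)
    ]
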