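"""Shared fixtures: small hand-built genomes and simulated individuals.

Expensive simulations are session-scoped so the whole suite pays for
them once.
"""

from __future__ import annotations

import pytest

from lumenstrain.genome import AnnotatedGenome, Gene
from lumenstrain.syndata import SimScenario, simulate_individual


@pytest.fixture(scope="session")
def clean_individual():
    """Error-free simulation: no minor lineage, no sequencing error.

    Under these conditions every implanted substitution should be
    recovered exactly, which makes this the oracle for the recovery
    tests.
    """
    scenario = SimScenario(
        seed=42,
        genome_length=60_000,
        per_site_substitutions=25,
        shared_substitutions=10,
        minor_lineage_freq=0.0,
        error_rate=0.0,
        ptr_true=1.5,
        mean_depth=50,
    )
    return simulate_individual(scenario)


@pytest.fixture(scope="session")
def default_individual():
    """Study-condition defaults (minor lineage, error, gradient)."""
    return simulate_individual(SimScenario(seed=7))


@pytest.fixture
def toy_genome() -> AnnotatedGenome:
    """30 bp contig with one forward gene at [3, 15) and one reverse
    gene at [18, 27).

    Forward gene codons: ATG AAA GAA TAA (Met-Lys-Glu-stop).
    Reverse gene reads TTACATCAT on the contig, i.e. ORF
    ATG ATG TAA (Met-Met-stop) on the minus strand.
    """
    seq = "CCC" + "ATGAAAGAATAA" + "GGG" + "TTACATCAT" + "CCC"
    genes = [
        Gene("fwd1", "c1", 3, 15, "+"),
        Gene("rev1", "c1", 18, 27, "-"),
    ]
    return AnnotatedGenome({"c1": seq}, genes)
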