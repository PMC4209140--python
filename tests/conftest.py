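"""Shared fixtures.

The expensive simulation experiments (null calibration, nesting, parameter
recovery, BEB discrimination) are session-scoped so the acceptance checks
and any unit test that inspects them run them exactly once.
"""

import numpy as np
import pytest

from codonsel import CodonAlignment, read_newick
from codonsel.experiments import (
    beb_discrimination_experiment,
    m2a_recovery_experiment,
    nesting_experiment,
    type_one_error_experiment,
)

SEED = 1


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61.0)


@pytest.fixture()
def four_taxon_tree():
    return read_newick("((A:0.2,B:0.35):0.15,(C:0.1,D:0.4):0.25):0.0;")


@pytest.fixture()
def small_alignment():
    # 4 taxa x 6 codons, gaps and one ambiguous codon included
    return CodonAlignment(
        ["A", "B", "C", "D"],
        [
            "ATGAAACCTTGGGAGTTT",
            "ATGAAGCCATGGGAGTTC",
            "ATGAAACCT---GAGTTT",
            "ATGCGACCTTGGNNNTTT",
        ],
    )


@pytest.fixture(scope="session")
def type1_result():
    return type_one_error_experiment(n_reps=100, n_taxa=8, n_codons=300, seed=SEED)


@pytest.fixture(scope="session")
def nesting_result():
    return nesting_experiment(n_datasets=10, n_taxa=6, n_codons=200, seed=SEED)


@pytest.fixture(scope="session")
def m2a_recovery():
    return m2a_recovery_experiment(seed=SEED)


@pytest.fixture(scope="session")
def beb_discrimination():
    return beb_discrimination_experiment(seed=SEED)
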