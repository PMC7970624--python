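"""Shared fixtures: small synthetic target sets and designed libraries.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

import numpy as np
import pandas as pd
import pytest

from transcreen import (
    DesignRules,
    GenomeIndex,
    design_library,
    random_orfs,
)


@pytest.fixture(scope="session")
def rules():
    return DesignRules()


@pytest.fixture(scope="session")
def small_library(rules):
    """8 random 600 nt genes and their designed library (no genome)."""
    rng = np.random.default_rng(42)
    orfs = random_orfs(8, rng, cds_length=600)
    library, qc = design_library(orfs, rules)
    return orfs, library, qc


@pytest.fixture(scope="session")
def genome50(rules):
    """50 random 900 nt genes, one per contig, with a genome index and the
    library designed against it (off-target distances known)."""
    rng = np.random.default_rng(77)
    orfs = random_orfs(50, rng, cds_length=900)
    genome = GenomeIndex({o.chrom: o.cds_seq for o in orfs})
    library, qc = design_library(orfs, rules, genome)
    return orfs, genome, library, qc


@pytest.fixture(scope="session")
def members50(genome50):
    """gene_id -> adaptored amplicon sequence for the 50-gene library."""
    _, _, library, _ = genome50
    return dict(zip(library["gene_id"], library["adaptored_seq"]))
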