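"""Shared fixtures: small planted cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pancanhub import synthetic as syn


@pytest.fixture(scope="session")
def standard_cohort():
    """The standard planted-module cohort: 3 modules x 50 genes at loading
    0.9, 100 samples, 500 background genes, fixed seed."""
    universe = syn.generate_universe(650, coding_fraction=1.0, seed=10)
    matrix, truth = syn.generate_expression(
        universe, 100, modules=[(50, 0.9)] * 3, seed=11
    )
    return universe, matrix, truth


@pytest.fixture(scope="session")
def clique_cohort():
    """Five planted 12-cliques among 800 coding genes, background edge
    probability 0.002, fixed seed."""
    rng = np.random.default_rng(0)
    universe = syn.generate_universe(800, coding_fraction=1.0, seed=50)
    coding = sorted(universe.coding_genes)
    chosen = rng.choice(coding, size=60, replace=False)
    planted = [set(chosen[i * 12 : (i + 1) * 12]) for i in range(5)]
    truth = syn.ComplexTruth(planted, p_in=1.0, p_out=0.002)
    edges = syn.generate_ppi(universe, truth, seed=51)
    return universe, edges, truth


@pytest.fixture(scope="session")
def small_universe():
    return syn.generate_universe(
        200,
        coding_fraction=0.7,
        flag_rates={"PCD1": 0.05, "known_cancer": 0.03},
        release_member_rate=0.95,
        seed=1,
    )
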