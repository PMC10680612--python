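"""Shared fixtures: small genic layouts, rate maps, and cached forward
replicate sets (session-scoped; the expensive desk-scale sets are built
once and shared by the acceptance tests)."""

import numpy as np
import pytest

import ratehet as rh
from ratehet.experiment import (DESK, MU_FIXED, REC_FIXED_CM_MB, Profile,
                                Scenario, simulate_scenario_reps)


@pytest.fixture(scope="session")
def paper_structure():
    return rh.GenicStructure()


@pytest.fixture(scope="session")
def paper_layout(paper_structure):
    return rh.build_layout(paper_structure)


@pytest.fixture(scope="session")
def small_layout():
    """Three-gene chromosome (~23.6 kb) for fast forward runs."""
    return rh.build_layout(rh.GenicStructure(n_genes=3))


def fixed_maps(layout):
    L = layout.total_length
    return (rh.make_rate_map("mutation", L, MU_FIXED),
            rh.make_rate_map("recombination", L, REC_FIXED_CM_MB))


@pytest.fixture(scope="session")
def small_maps(small_layout):
    return fixed_maps(small_layout)


def run_small_neutral(layout, maps, seeds, Q=14000.0, sample_n=20):
    """Neutral equilibrium replicates at N = 1.4e6 / Q diploids."""
    mut, rec = maps
    dem = rh.DemographyPlan.equilibrium(1.4e6, sample_n=sample_n)
    return [rh.simulate_replicate(layout, mut, rec, None, dem, Q=Q, seed=s)
            for s in seeds]


@pytest.fixture(scope="session")
def neutral_small_reps(small_layout, small_maps):
    """20 neutral equilibrium replicates at N = 100 (n = 20)."""
    return run_small_neutral(small_layout, small_maps, range(20))


def desk_neutral_reps(demography: str, n_reps: int = 20):
    sc = Scenario("fixed_theta_fixed_rho", demography, None,
                  n_reps, 5, seed=_DESK_SEEDS[demography])
    return simulate_scenario_reps(sc, DESK)


_DESK_SEEDS = {"equilibrium": 101, "expansion100": 102,
               "contraction50": 103}


@pytest.fixture(scope="session")
def desk_equilibrium(request):
    return desk_neutral_reps("equilibrium")


@pytest.fixture(scope="session")
def desk_expansion(request):
    return desk_neutral_reps("expansion100")


@pytest.fixture(scope="session")
def desk_contraction(request):
    return desk_neutral_reps("contraction50")
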