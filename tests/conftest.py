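import numpy as np
import pytest
from hypothesis import settings

import msrecap as m

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_design():
    """Five occasions, one species, a skipped fourth occasion."""
    return m.StudyDesign(
        occasion_labels=(1990, 1991, 1992, 1993, 1994),
        skipped_occasions=frozenset({1993}),
        species=("A",),
        cockchafer_years={"N": frozenset({1991})},
    )


@pytest.fixture
def plain_design():
    """Five occasions, one species, nothing skipped."""
    return m.StudyDesign(occasion_labels=(1, 2, 3, 4, 5), species=("A",))


@pytest.fixture
def two_species_design():
    return m.StudyDesign(occasion_labels=(1, 2, 3, 4), species=("A", "B"))


def random_rateset(design, rng, p=None):
    vals = rng.uniform(0.05, 0.95, 9)
    return m.RateSet.constant(
        design,
        phi_juv=vals[0],
        phi_ad=vals[1],
        alpha1=vals[2],
        alpha2=vals[3],
        alpha3=vals[4],
        natal_NR=vals[5],
        natal_RN=vals[6],
        breeding_NR=vals[7],
        breeding_RN=vals[8],
        p=rng.uniform(0.2, 0.9) if p is None else p,
    )


def random_history(design, rng, individual_id="x"):
    """A random structurally valid capture history for species[0]."""
    T = design.n_occasions
    age = rng.choice([m.JUVENILE, m.ADULT])
    occs = [t for t in range(T - 1) if not design.is_skipped(t)]
    r = int(rng.choice(occs))
    obs = [0] * T
    breeder = age == m.ADULT
    obs[r] = int(rng.integers(3, 5)) if breeder else int(rng.integers(1, 3))
    for t in range(r + 1, T):
        if design.is_skipped(t):
            continue
        c = int(rng.integers(0, 5))
        if breeder and c in (1, 2):
            c = 0
        if c in (3, 4):
            breeder = True
        obs[t] = c
    return m.CaptureHistory(individual_id, design.species[0], age, tuple(obs))
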