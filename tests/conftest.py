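import numpy as np
import pandas as pd
import pytest

from admixgs import simulate as sim


@pytest.fixture(scope="session")
def small_map():
    return sim.GeneticMap.uniform(2, 60, 100.0)


@pytest.fixture(scope="session")
def founders(small_map):
    return sim.simulate_founders(sim.FounderModel(2, 0.2), small_map, 30, seed=11)


@pytest.fixture(scope="session")
def small_pop(founders, small_map):
    """Two-generation admixed population with full-sib families."""
    design = sim.BreedingDesign(
        n_generations=2, n_sires=12, n_dams=12, n_families=14,
        offspring_per_family=6, offspring_per_family_intermediate=4)
    return sim.breed_population(founders, design, small_map, seed=12)


@pytest.fixture(scope="session")
def sib_pop(small_map):
    """One generation of monogamous full-sib families from unrelated founders."""
    f = sim.simulate_founders(sim.FounderModel(2, 0.25), small_map, 30, seed=21)
    design = sim.BreedingDesign(
        n_generations=1, n_sires=15, n_dams=15, n_families=15,
        offspring_per_family=8, mating="monogamous")
    return sim.breed_population(f, design, small_map, seed=22)


@pytest.fixture()
def toy_pedigree():
    """Six individuals: two founders, two full sibs, their offspring."""
    return pd.DataFrame({
        "id": [1, 2, 3, 4, 5, 6],
        "sire": [0, 0, 1, 1, 3, 3],
        "dam": [0, 0, 2, 2, 4, 4],
        "generation": [0, 0, 1, 1, 2, 2],
        "sex": ["M", "F", "M", "F", "M", "F"],
    })
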