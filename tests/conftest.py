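from __future__ import annotations

import numpy as np
import pytest

from pseudoevo.seqio import back_translate_alignment
from pseudoevo.synth import (
    PlantedSectorSpec,
    SelectionProfile,
    SpeciesTreeSpec,
    evolve_family,
    generate_sector_msa,
    simulate_species_tree,
)


@pytest.fixture(scope="session")
def small_tree():
    return simulate_species_tree(SpeciesTreeSpec(8, seed=10, height_scale=0.1))


@pytest.fixture(scope="session")
def neutral_family(small_tree):
    fam = evolve_family(
        small_tree, 300, SelectionProfile(default_omega=1.0), seed=7
    )
    msa = {r.species: r.protein_seq for r in fam.records}
    return back_translate_alignment(msa, fam)


@pytest.fixture(scope="session")
def purifying_family(small_tree):
    fam = evolve_family(
        small_tree, 200, SelectionProfile(default_omega=0.1), seed=8
    )
    msa = {r.species: r.protein_seq for r in fam.records}
    return back_translate_alignment(msa, fam)


@pytest.fixture(scope="session")
def two_sector_msa():
    spec = PlantedSectorSpec(
        350,
        250,
        (
            (frozenset(range(30, 42)), 3, 0.9),
            (frozenset(range(120, 132)), 3, 0.9),
        ),
        seed=5,
    )
    return generate_sector_msa(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
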