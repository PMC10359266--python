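import pytest

from poregraph.synthetic import FixtureSpec, PlantedBond, make_fixture, make_paralog_pair

# Planted truth used across the suite: 3 H-bonds, one water-mediated,
# spread over different helices and z-levels so no accidental contacts
# can arise.
BASIC_BONDS = [
    PlantedBond(2, 21, 2.8),
    PlantedBond(6, None, 2.9),
    PlantedBond(40, 59, 3.2, comp_a="THR", atom_a="OG1", comp_b="GLN", atom_b="OE1"),
]


def basic_spec(seed: int = 11) -> FixtureSpec:
    return FixtureSpec(
        seed=seed,
        n_helices=4,
        residues_per_helix=18,
        planted_hbonds=list(BASIC_BONDS),
        n_decoy_waters=2,
        n_decoy_ions=1,
    )


@pytest.fixture(scope="session")
def basic_fixture():
    return make_fixture(basic_spec())


@pytest.fixture(scope="session")
def paralog_pair():
    """Pair differing by one substitution and a 1.4 Å shift of one helix."""
    return make_paralog_pair(
        basic_spec(), mutations=[(30, "ALA")], displacement=(50, 1.4)
    )
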