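import pytest

from qhelix.builder import build_ideal_helix
from qhelix.synthetic import plant_rotamer_ensemble, synth_strips


@pytest.fixture(scope="session")
def helix_llllq():
    """Ideal helix with an mt-like Gln8 whose side chain bonds Leu4 O."""
    return build_ideal_helix(
        "LLLLQQQQQ", -57.0, -47.0, rotamers={8: {1: -60.0, 2: 150.0, 3: 75.0}}
    )


@pytest.fixture(scope="session")
def planted_mixture():
    """0.8/0.2 mt/tp ensemble over all chi-bearing residues, 400 frames."""
    return plant_rotamer_ensemble("LLLLQQQQQ", {"mt": 0.8, "tp": 0.2}, 400, seed=2)


@pytest.fixture(scope="session")
def planted_strips(planted_mixture):
    return synth_strips(planted_mixture.ensemble, owners=[(8, "HE21")], seed=3)


@pytest.fixture(scope="session")
def diverse_pool():
    """Small pool spanning four rotamer classes; planted frames identifiable."""
    return plant_rotamer_ensemble(
        "LLLLQQQQQ",
        {"mt": 0.4, "tp": 0.2, "pt": 0.2, "tt": 0.2},
        60,
        seed=11,
        residues=[8],
    )
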