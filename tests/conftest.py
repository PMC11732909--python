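import pytest

from xenotherm import TaxonSpec, default_taxa
from xenotherm.heatbalance import FurLayer, geometry_from_mass


@pytest.fixture(scope="session")
def taxa():
    return default_taxa()


@pytest.fixture(scope="session")
def megatherium():
    return TaxonSpec(name="Megatherium", mass=3706.0, T_core=31.0)


@pytest.fixture(scope="session")
def fur_grid():
    """The study's fur factorial: 3 depths × dense/sparse."""
    return [
        FurLayer(depth, density, label=f"{int(depth * 1000)}mm@{density:g}")
        for depth in (0.01, 0.03, 0.05)
        for density in (2000.0, 8.5)
    ]


@pytest.fixture(scope="session")
def mega_geometry(megatherium):
    return geometry_from_mass(megatherium.mass)
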