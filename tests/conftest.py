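import numpy as np
import pytest

from apfbss.apf_core import EnergyModel
from apfbss.superpose import MCConfig
from apfbss.synthetic import FixtureSpec, generate_site


def pdb_line(
    record="ATOM",
    serial=1,
    name="N",
    altloc=" ",
    resname="ALA",
    chain="A",
    resid=1,
    x=0.0,
    y=0.0,
    z=0.0,
    occ=1.0,
    element="N",
):
    """One wwPDB v3.3 fixed-column coordinate record."""
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} "
        f"{chain}{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def site30():
    """A default-sized synthetic pocket (30 atoms, 7 A extent)."""
    return generate_site(FixtureSpec(seed=1, label="site30"))


@pytest.fixture(scope="session")
def small_site():
    """A small pocket for cheap energy/optimization tests."""
    return generate_site(FixtureSpec(n_atoms=12, extent=5.0, seed=11, label="small"))


@pytest.fixture
def fast_config():
    """Reduced evaluation budget for unit tests of the MC machinery."""
    return MCConfig(max_evaluations=1500, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
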