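import numpy as np
import pytest

from molfrag import (
    ExclusionModel,
    FixtureRecipe,
    FragmentSpec,
    SoftCoreParams,
    build_bridge_fragment,
    make_helix_bundle,
)


@pytest.fixture(scope="session")
def bundle():
    """Four-helix bundle fixture with its bridge-site catalog."""
    return make_helix_bundle(FixtureRecipe(helix_length=12))


@pytest.fixture()
def bundle_copy(bundle):
    system, catalog = bundle
    return system.copy(), catalog


@pytest.fixture()
def bridged_bundle(bundle):
    """Bundle with a Cd and an Mg bridge fragment plus exclusion model."""
    system, catalog = bundle
    system = system.copy()
    frag_cd = build_bridge_fragment(system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites))
    frag_mg = build_bridge_fragment(system, FragmentSpec(kind="mg_bridge", host_sites=catalog[2].sites))
    model = ExclusionModel.from_system(system, [frag_cd, frag_mg])
    return system, frag_cd, frag_mg, model


@pytest.fixture(scope="session")
def softcore_params():
    return SoftCoreParams(delta=1.0, switch_on=10.0, cutoff=12.0)


def finite_difference_forces(energy_fn, positions, atoms, h=1e-5):
    """Central-difference force oracle on selected atoms."""
    out = {}
    for a in atoms:
        g = np.zeros(3)
        for k in range(3):
            pp = positions.copy()
            pm = positions.copy()
            pp[a, k] += h
            pm[a, k] -= h
            g[k] = -(energy_fn(pp) - energy_fn(pm)) / (2 * h)
        out[a] = g
    return out
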