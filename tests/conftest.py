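"""Shared fixtures: synthetic structures are generated once per session."""
import numpy as np
import pytest

from templateprobe.synthetic import (
    BackboneSpec,
    RotamerSpec,
    attach_sidechains,
    make_backbone,
    make_globule,
)


@pytest.fixture(scope="session")
def helix_full():
    """20-residue helix with ideal side chains (all 20 residue types)."""
    return attach_sidechains(make_backbone(BackboneSpec(20, "helix")),
                             RotamerSpec("ideal_single", seed=0))


@pytest.fixture(scope="session")
def mixed_full():
    """80-residue mixed-secondary-structure chain with side chains."""
    return attach_sidechains(make_backbone(BackboneSpec(80, "mixed", seed=3)),
                             RotamerSpec("ideal_single", seed=3))


@pytest.fixture(scope="session")
def globule_small():
    """Compact 60-residue globule."""
    return make_globule(60, seed=11)


@pytest.fixture(scope="session")
def globule_150():
    """Compact 150-residue globule (large enough for the lDDT asymptotics)."""
    return make_globule(150, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
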