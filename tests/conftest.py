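"""Shared fixtures: a small two-element basis and helpers for random
environments/configurations.  Expensive builds are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from aceff.bbasis import BasisSelection, build_basis
from aceff.density import DensityIndex
from aceff.potential import LinearACEModel
from aceff.radial import RadialSpec, build_orthogonal_polynomials
from aceff.structures import AtomicConfiguration


@pytest.fixture(scope="session")
def small_setup():
    """Two-element (C, H) nu_max = 3 machinery shared across test modules."""
    selection = BasisSelection(
        elements=("C", "H"), nu_max=3, degree_caps=((1, 8), (2, 7), (3, 6))
    )
    radial = RadialSpec(r_in=0.7, r_out=4.0, n_max=selection.n_max)
    polys = build_orthogonal_polynomials(radial)
    basis = build_basis(selection, radial, polys)
    index = DensityIndex(selection.elements, radial.n_max, selection.l_max)
    return {
        "selection": selection,
        "radial": radial,
        "polys": polys,
        "basis": basis,
        "index": index,
    }


@pytest.fixture(scope="session")
def planted_model(small_setup):
    """A LinearACEModel with fixed random coefficients on the shared basis."""
    model = LinearACEModel.zeros(
        small_setup["basis"], small_setup["radial"], small_setup["polys"]
    )
    rng = np.random.default_rng(42)
    model.theta = rng.normal(size=model.n_features) * 0.05
    model.one_body = {"C": -100.0, "H": -13.0}
    return model


def random_cluster(rng, elements=("C", "H"), n_atoms=None, box=2.3, min_dist=0.85):
    """A random well-separated cluster for force/energy consistency tests."""
    n = int(rng.integers(3, 9)) if n_atoms is None else n_atoms
    els = [elements[int(k)] for k in rng.integers(len(elements), size=n)]
    while True:
        pos = rng.uniform(-box, box, size=(n, 3))
        config = AtomicConfiguration(els, pos)
        if config.min_distance() > min_dist:
            return config


@pytest.fixture
def rng():
    return np.random.default_rng(0)
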