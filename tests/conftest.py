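import warnings

import numpy as np
import pytest

from ligandqc import (
    ToyComplexSpec,
    make_toy_complex,
    neighbourhood,
    select_ligand,
)
from ligandqc.density import GridSpec


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def toy():
    """A standard synthetic complex: structure, dictionary, selected ligand."""
    s, d = make_toy_complex(ToyComplexSpec(seed=2))
    lig = select_ligand(s, d)
    assert lig
    return s, d, lig


@pytest.fixture(scope="session")
def toy_grid(toy):
    s, _, _ = toy
    return GridSpec.around_atoms(s.atoms, spacing=0.5)


@pytest.fixture(scope="session")
def toy_env(toy):
    s, _, lig = toy
    return neighbourhood(s, lig, 4.0)


def brute_force_points(grid, lig_atoms, env_atoms, spec=None):
    """Independent all-grid-points double loop for the ligand mask."""
    from ligandqc.density import MaskSpec, mask_radius

    spec = spec or MaskSpec()
    out = set()
    heavy_lig = [a for a in lig_atoms if a.element.upper() != "H"]
    heavy_env = [a for a in env_atoms if a.element.upper() != "H"]
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                p = np.asarray(grid.origin) + grid.spacing * np.array([i, j, k])
                inside = any(
                    np.linalg.norm(p - a.pos) <= mask_radius(a.element, a.b, spec)
                    for a in heavy_lig
                )
                if not inside:
                    continue
                excl = any(
                    np.linalg.norm(p - a.pos)
                    <= mask_radius(a.element, a.b, spec) + spec.neighbour_radius_inflation
                    for a in heavy_env
                )
                if not excl:
                    out.add((i, j, k))
    return out
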