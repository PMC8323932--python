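import numpy as np
import pytest

import afmrigid as ar


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_blob():
    """A 20-sphere anisotropic blob, grounded on the stage."""
    return ar.ground_on_stage(ar.make_blob(20, (6.0, 4.0, 2.5), seed=7))


@pytest.fixture
def probe():
    return ar.ProbeShape(2.0, 15.0)


@pytest.fixture
def random_map(rng):
    """A 10x10 height map with strictly positive seeded heights."""
    return ar.HeightMap(rng.uniform(0.1, 5.0, (10, 10)), 1.0)


def write_minimal_pdb(path, coords_ang, elements=None):
    """Write a hand-rolled minimal PDB file (coordinates in Angstrom)."""
    elements = elements or ["C"] * len(coords_ang)
    with open(path, "w") as fh:
        for i, ((x, y, z), el) in enumerate(zip(coords_ang, elements), start=1):
            fh.write(
                f"ATOM  {i:5d}  {el:<3s}GLY A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
            )
        fh.write("END\n")
    return path
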