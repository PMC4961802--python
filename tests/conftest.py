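import numpy as np
import pytest

from sproutsim import LatticeConfig, ScenarioConfig, build_sprout
from sproutsim.lattice import SproutMesh, EMPTY


@pytest.fixture
def default_config():
    return LatticeConfig()


@pytest.fixture
def default_mesh(default_config):
    return build_sprout(default_config)


@pytest.fixture
def two_cell_config():
    """Smallest legal sprout: one band, two half-cylinder cells."""
    return LatticeConfig(n_cells=2, axial_length=30)


@pytest.fixture
def two_cell_mesh(two_cell_config):
    return build_sprout(two_cell_config)


def random_two_cell_mesh(rng, size=6):
    """Random connected 2-cell tiling of a small cylinder (for Hamiltonian
    oracles).  Grown by seeded region expansion so both territories are
    4-connected."""
    cfg = LatticeConfig(circumference=size, axial_length=size + 1,
                        cells_per_cross_section=2, n_cells=2, band_length=2)
    owner = np.full((cfg.axial_length, cfg.circumference), EMPTY,
                    dtype=np.int32)
    seeds = [(0, 0), (size - 1, size // 2)]
    frontier = {0: [seeds[0]], 1: [seeds[1]]}
    owner[seeds[0]] = 0
    owner[seeds[1]] = 1
    target = size * size // 3
    counts = [1, 1]
    while any(c < target and frontier[i] for i, c in enumerate(counts)):
        for c in (0, 1):
            if counts[c] >= target or not frontier[c]:
                continue
            x, y = frontier[c][rng.integers(len(frontier[c]))]
            nbs = [(x + 1, y), (x - 1, y), (x, (y + 1) % size),
                   (x, (y - 1) % size)]
            rng.shuffle(nbs)
            for nx, ny in nbs:
                if 0 <= nx < cfg.axial_length and owner[nx, ny] == EMPTY:
                    owner[nx, ny] = c
                    frontier[c].append((nx, ny))
                    counts[c] += 1
                    break
            else:
                frontier[c].remove((x, y))
    return SproutMesh(cfg, owner, np.zeros(2, dtype=np.int8))
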