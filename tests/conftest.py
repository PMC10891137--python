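"""Shared fixtures: synthetic landscapes and a trained pipeline."""

import numpy as np
import pytest

import lulcsim as L


@pytest.fixture(scope="session")
def default_cfg():
    """Reference study conditions: 100x100 grid, 6 classes, 4 steps, seed 7."""
    return L.LandscapeConfig()


@pytest.fixture(scope="session")
def landscape(default_cfg):
    return L.generate_landscape(default_cfg)


@pytest.fixture(scope="session")
def trained_pipeline(landscape):
    """Balanced+augmented sample and a trained network on the default landscape."""
    maps, stack, truth = landscape
    table = L.balanced_change_sample(maps[:3], maps[3], stack,
                                     window_cells=5, seed=11)
    table = L.augment_changing(table, k=5, seed=12)
    model, history = L.train(table, L.ModelSpec(seed=3),
                             class_ids=maps[0].codebook.modelled_ids,
                             window_cells=5)
    return table, model, history


@pytest.fixture
def tiny_codebook():
    return L.synthetic_codebook(3)


def make_map(codes, codebook, cell_size=100.0, valid=None):
    codes = np.asarray(codes, dtype=np.int32)
    grid = L.Grid(codes.shape[0], codes.shape[1], cell_size,
                  2600000.0, 1200000.0, "EPSG:2056")
    return L.LULCMap(grid, codes, codebook, valid)


@pytest.fixture
def map_factory():
    return make_map
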