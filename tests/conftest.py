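"""Shared fixtures: small synthetic orchards and hand-built rasters."""

import numpy as np
import pytest

from orchardyield.io import CANONICAL_BANDS, BandStack, GeoTransform
from orchardyield.synthetic import OrchardParams, generate_orchard


def make_stack(data: np.ndarray, pixel_size: float = 0.3) -> BandStack:
    """Wrap a (rows, cols, 4) array with a trivial geotransform."""
    n_rows = data.shape[0]
    return BandStack(
        data=data,
        band_names=CANONICAL_BANDS,
        transform=GeoTransform(0.0, n_rows * pixel_size, pixel_size),
    )


def uniform_stack(
    n_rows: int, n_cols: int, green=0.1, red=0.1, red_edge=0.1, nir=0.1
) -> BandStack:
    data = np.empty((n_rows, n_cols, 4))
    for i, v in enumerate((green, red, red_edge, nir)):
        data[:, :, i] = v
    return make_stack(data)


@pytest.fixture(scope="session")
def small_orchard():
    """A 4x6-tree default-parameter orchard shared across read-only tests."""
    params = OrchardParams(n_rows=4, trees_per_row=6, seed=42)
    stack, inventory, truth = generate_orchard(params)
    return params, stack, inventory, truth


@pytest.fixture(scope="session")
def medium_orchard():
    """A 6x15-tree orchard, big enough for feature/CV exercises."""
    params = OrchardParams(n_rows=6, trees_per_row=15, seed=7)
    stack, inventory, truth = generate_orchard(params)
    return params, stack, inventory, truth
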