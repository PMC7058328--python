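"""Shared fixtures: toy rasters, toy patch layouts, published count summaries."""
import numpy as np
import pytest
from shapely.geometry import box

from patchscape.data import DetectionTable
from patchscape.grid import Grid

#: Detection summaries printed for the two study regions: number of patches
#: by how many of the two surveys detected the species.
CORE_HISTORY_COUNTS = {"11": 17, "10": 4, "01": 3, "00": 18}        # 42 patches, 24 occupied
PERIPHERY_HISTORY_COUNTS = {"11": 5, "10": 1, "01": 1, "00": 26}    # 33 patches, 7 occupied


@pytest.fixture
def core_table() -> DetectionTable:
    return DetectionTable.from_history_counts(CORE_HISTORY_COUNTS)


@pytest.fixture
def periphery_table() -> DetectionTable:
    return DetectionTable.from_history_counts(PERIPHERY_HISTORY_COUNTS)


@pytest.fixture
def toy_grid() -> Grid:
    """20×20 raster at 5 m: habitat block, urban column, crop elsewhere."""
    data = np.full((20, 20), 11, dtype=int)  # crop_pas
    data[8:12, 8:12] = 3                     # habitat (grass) patch block
    data[:, 17] = 12                         # urban column
    data[0, :] = 13                          # river row along the top
    return Grid(data, cellsize=5.0)


@pytest.fixture
def toy_patches() -> dict:
    """Three hand-placed rectangles with known pairwise distances."""
    return {
        "a": box(40, 40, 60, 60),    # focal 20×20 m
        "b": box(70, 40, 80, 50),    # 10 m to the right of a
        "c": box(90, 40, 110, 50),   # 30 m right of a, 10 m right of b
    }
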