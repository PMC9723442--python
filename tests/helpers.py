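"""Shared builders for small in-memory grids and masks."""

from __future__ import annotations

import numpy as np

from sbrteval import DoseGrid, ROIMask


def make_grid(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), frame="f"):
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:  # convenience: a flat voxel list as an Nx1x1 grid
        values = values.reshape(-1, 1, 1)
    return DoseGrid(origin, spacing, values, frame)


def full_mask(grid: DoseGrid, name: str = "roi") -> ROIMask:
    return ROIMask.on_grid(name, np.ones(grid.dims, dtype=bool), grid)


def mask_on(grid: DoseGrid, occupancy, name: str = "roi") -> ROIMask:
    occ = np.asarray(occupancy, dtype=bool)
    if occ.ndim == 1:
        occ = occ.reshape(-1, 1, 1)
    return ROIMask.on_grid(name, occ, grid)


def sphere_mask(grid: DoseGrid, center_mm, radius_mm, name="sphere") -> ROIMask:
    axes = [grid.axis_centers(a) for a in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    cx, cy, cz = center_mm
    occ = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm**2
    return ROIMask.on_grid(name, occ, grid)


def random_dose_and_mask(rng, dims=(17, 13, 11), spacing=(2.0, 2.0, 2.5),
                         max_dose=60.0, mask_fraction=0.4):
    grid = DoseGrid((0, 0, 0), spacing, rng.uniform(0, max_dose, size=dims), "rand")
    occ = rng.random(dims) < mask_fraction
    occ.flat[0] = True  # never empty
    return grid, ROIMask.on_grid("roi", occ, grid)
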