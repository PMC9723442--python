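"""Voxel-grid data model: dose grids, structure masks, mask algebra, plan superposition.

Conventions used throughout the package
---------------------------------------
* Axis order is ``(x, y, z)`` with 0-based indices; the physical position of
  voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` in millimetres.
* Dose and occupancy are point samples at voxel centres: a voxel belongs to a
  structure iff its centre lies inside the contour solid (no partial-volume
  weighting).
* Doses are absorbed dose in Gy, totalled over all fractions, and are held in
  64-bit floats regardless of the dtype of any input file.
* Dose summation never resamples implicitly; :func:`resample_like` is a
  separate, explicit step so that plan superposition stays auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "DoseGrid",
    "ROIMask",
    "StructureSet",
    "PlanDose",
    "CANONICAL_STRUCTURES",
    "same_geometry",
    "sum_doses",
    "resample_like",
    "union_masks",
    "mask_volume_cc",
    "expand_margin",
]

#: Canonical structure names understood by the evaluation modules.
CANONICAL_STRUCTURES = (
    "ptv1",
    "ptv2",
    "ptv12",
    "lungs",
    "heart",
    "cord",
    "trachea",
    "bronchus",
    "trachea_bronchus",
    "esophagus",
    "body",
)


class GeometryError(ValueError):
    """Two voxel objects do not share the same grid geometry."""


def _triple(value, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have three components, got {value!r}")
    return t


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D absorbed-dose distribution (Gy, total over all fractions)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray
    frame_id: str = "frame-0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 3:
            raise ValueError("dose values must be a 3-D array in (x, y, z) order")
        if not np.all(np.isfinite(vals)):
            raise ValueError("dose values must be finite")
        if vals.size and float(vals.min()) < 0.0:
            raise ValueError("dose values must be >= 0 Gy")
        object.__setattr__(self, "values", vals)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical centre coordinates (mm) of voxels along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(self.origin, self.spacing, values, self.frame_id)

    def zeros_like(self) -> "DoseGrid":
        return self.with_values(np.zeros(self.dims))


@dataclass(frozen=True)
class ROIMask:
    """Boolean voxel occupancy of one structure on a dose-grid geometry."""

    name: str
    occupancy: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    frame_id: str = "frame-0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.ndim != 3:
            raise ValueError("mask occupancy must be a 3-D array in (x, y, z) order")
        object.__setattr__(self, "occupancy", occ)

    @classmethod
    def on_grid(cls, name: str, occupancy: np.ndarray, grid: DoseGrid) -> "ROIMask":
        m = cls(name, occupancy, grid.origin, grid.spacing, grid.frame_id)
        if m.dims != grid.dims:
            raise GeometryError(
                f"mask '{name}' dims {m.dims} do not match grid dims {grid.dims}"
            )
        return m

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def volume_cc(self) -> float:
        return int(self.occupancy.sum()) * self.voxel_volume_cc

    def renamed(self, name: str) -> "ROIMask":
        return replace(self, name=name)


def same_geometry(a, b) -> None:
    """Raise :class:`GeometryError` naming the first differing geometry field.

    Accepts any mix of :class:`DoseGrid` and :class:`ROIMask`.
    """
    if a.frame_id != b.frame_id:
        raise GeometryError(f"frame_id mismatch: {a.frame_id!r} vs {b.frame_id!r}")
    if a.dims != b.dims:
        raise GeometryError(f"dims mismatch: {a.dims} vs {b.dims}")
    for field_name in ("spacing", "origin"):
        va, vb = getattr(a, field_name), getattr(b, field_name)
        if any(abs(x - y) > 1e-6 for x, y in zip(va, vb)):
            raise GeometryError(f"{field_name} mismatch: {va} vs {vb}")


@dataclass(frozen=True)
class PlanDose:
    """A deliverable plan: total dose grid plus fractionation and prescription.

    ``arm`` distinguishes a single plan covering both targets ("single"), the
    superposition of two independently optimized plans ("double"), and one of
    the two components before superposition ("component").
    """

    grid: DoseGrid
    n_fractions: int = 5
    prescription_dose_gy: float = 50.0
    arm: str = "single"

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.prescription_dose_gy <= 0:
            raise ValueError("prescription_dose_gy must be > 0")
        if self.arm not in ("single", "double", "component"):
            raise ValueError(f"unknown arm {self.arm!r}")


class StructureSet(Mapping[str, ROIMask]):
    """Masks keyed by canonical structure names, with derived unions.

    ``ptv12`` is derived as the voxelwise union of ``ptv1`` and ``ptv2`` and
    ``trachea_bronchus`` as the union of ``trachea`` and ``bronchus`` when not
    supplied explicitly; if supplied, they are validated against the unions.
    Every mask must be contained in ``body`` when a body mask is present.
    """

    def __init__(self, masks: Mapping[str, ROIMask], derive_unions: bool = True):
        masks = dict(masks)
        ref = next(iter(masks.values()), None)
        for m in masks.values():
            if ref is not None:
                same_geometry(ref, m)
        if derive_unions:
            if "ptv12" not in masks and {"ptv1", "ptv2"} <= masks.keys():
                masks["ptv12"] = union_masks(masks["ptv1"], masks["ptv2"], name="ptv12")
            if "trachea_bronchus" not in masks and {"trachea", "bronchus"} <= masks.keys():
                masks["trachea_bronchus"] = union_masks(
                    masks["trachea"], masks["bronchus"], name="trachea_bronchus"
                )
        for combined, parts in (
            ("ptv12", ("ptv1", "ptv2")),
            ("trachea_bronchus", ("trachea", "bronchus")),
        ):
            if combined in masks and all(p in masks for p in parts):
                expected = np.logical_or(
                    masks[parts[0]].occupancy, masks[parts[1]].occupancy
                )
                if not np.array_equal(masks[combined].occupancy, expected):
                    raise ValueError(
                        f"{combined} must equal the union of {parts[0]} and {parts[1]}"
                    )
        if "body" in masks:
            body = masks["body"].occupancy
            for name, m in masks.items():
                if name != "body" and np.any(m.occupancy & ~body):
                    raise ValueError(f"structure '{name}' is not contained in body")
        self._masks = masks

    def __getitem__(self, key: str) -> ROIMask:
        return self._masks[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    def __contains__(self, key: object) -> bool:
        return key in self._masks


def sum_doses(a: PlanDose, b: PlanDose) -> PlanDose:
    """Voxelwise superposition of two plan doses computed on one geometry.

    This is the "double plannings" operation: each target is optimized in its
    own plan and the two dose distributions are then summed.  The grids must
    agree exactly in frame, dims, spacing and origin — resample explicitly
    first if they do not.
    """
    if a.n_fractions != b.n_fractions:
        raise ValueError(
            f"fractionation mismatch: {a.n_fractions} vs {b.n_fractions} fractions"
        )
    if a.prescription_dose_gy != b.prescription_dose_gy:
        raise ValueError(
            "prescription mismatch: "
            f"{a.prescription_dose_gy} vs {b.prescription_dose_gy} Gy"
        )
    same_geometry(a.grid, b.grid)
    total = a.grid.values + b.grid.values
    return PlanDose(
        grid=a.grid.with_values(total),
        n_fractions=a.n_fractions,
        prescription_dose_gy=a.prescription_dose_gy,
        arm="double",
    )


def resample_like(src: DoseGrid, target_geometry: DoseGrid) -> DoseGrid:
    """Trilinearly interpolate ``src`` onto the voxel centres of ``target_geometry``.

    Points outside the source extent receive 0 Gy.  The output carries the
    target's frame_id.  Exact for affine (linear) dose fields at interior
    voxel centres.
    """
    frac = [
        (target_geometry.axis_centers(ax) - src.origin[ax]) / src.spacing[ax]
        for ax in range(3)
    ]
    ii, jj, kk = np.meshgrid(*frac, indexing="ij")
    out = ndimage.map_coordinates(
        src.values, [ii, jj, kk], order=1, mode="constant", cval=0.0
    )
    out = np.maximum(out, 0.0)  # guard float round-off below zero
    return DoseGrid(
        target_geometry.origin, target_geometry.spacing, out, target_geometry.frame_id
    )


def union_masks(a: ROIMask, b: ROIMask, name: str | None = None) -> ROIMask:
    """Voxelwise logical OR of two masks on the same geometry."""
    same_geometry(a, b)
    out = np.logical_or(a.occupancy, b.occupancy)
    return ROIMask(name or f"{a.name}+{b.name}", out, a.origin, a.spacing, a.frame_id)


def mask_volume_cc(m: ROIMask) -> float:
    """Structure volume in cc: true-voxel count times voxel volume."""
    return m.volume_cc


def expand_margin(mask: ROIMask, margin_mm: float) -> ROIMask:
    """Isotropically expand a mask by a Euclidean margin in millimetres.

    Implements the GTV→PTV margin: the output contains every voxel whose
    centre lies within ``margin_mm`` of the input mask.  ``margin_mm == 0``
    returns the mask unchanged.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0 mm")
    occ = mask.occupancy
    if margin_mm == 0 or not occ.any():
        return mask
    # Work on a padded bounding box: the exact Euclidean distance transform on
    # the full grid would be wasted on voxels that cannot possibly flip.
    pad = [int(math.ceil(margin_mm / s)) + 1 for s in mask.spacing]
    idx = np.nonzero(occ)
    slices = tuple(
        slice(max(int(ix.min()) - p, 0), min(int(ix.max()) + p + 1, n))
        for ix, p, n in zip(idx, pad, occ.shape)
    )
    sub = occ[slices]
    dist = ndimage.distance_transform_edt(~sub, sampling=mask.spacing)
    out = occ.copy()
    out[slices] = sub | (dist <= margin_mm + 1e-9)
    return replace(mask, occupancy=out)
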