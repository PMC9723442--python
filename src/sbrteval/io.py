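"""File formats: native grid/mask files, DVH CSV, and DICOM RT readers.

Native format: a flat binary array (``.npy``) next to a JSON sidecar holding
origin/spacing/dims/frame_id/units — doses in Gy, masks as boolean payloads
on the same geometry sidecar.

DVH CSV: a one-line header ``structure,total_volume_cc,bin_width_gy`` with
its values on the second line, then ``dose_gy,volume_cc`` rows (cumulative,
at-or-above).  Round-trips exactly enough that the radiobiology and
plan-quality modules can run from DVH files alone.

DICOM: RTDOSE grids are accepted when DoseUnits is GY, DoseGridScaling is
present, the orientation is axis-aligned and the frame offsets are uniform;
anything else raises a named unsupported-dialect error (never a silent
guess).  RTSTRUCT planar contours are rasterized to masks by a
centre-in-polygon test per slice.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .dvh import CumulativeDVH
from .grid import DoseGrid, PlanDose, ROIMask

__all__ = [
    "UnsupportedDicomError",
    "save_grid",
    "load_grid",
    "save_mask",
    "load_mask",
    "write_dvh_csv",
    "read_dvh_csv",
    "read_rtdose",
    "rasterize_rtstruct",
]


class UnsupportedDicomError(ValueError):
    """The DICOM object uses a dialect this reader deliberately rejects."""


def _sidecar(obj, units: str) -> dict:
    return {
        "origin_mm": list(obj.origin),
        "spacing_mm": list(obj.spacing),
        "dims": list(obj.dims),
        "frame_id": obj.frame_id,
        "units": units,
    }


def save_grid(grid: DoseGrid, path_prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write ``<prefix>.npy`` + ``<prefix>.json``; returns both paths."""
    prefix = Path(path_prefix)
    npy, sidecar = prefix.with_suffix(".npy"), prefix.with_suffix(".json")
    np.save(npy, grid.values)
    sidecar.write_text(json.dumps(_sidecar(grid, "Gy"), indent=1, sort_keys=True))
    return npy, sidecar


def load_grid(path_prefix: str | os.PathLike) -> DoseGrid:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if meta.get("units") != "Gy":
        raise ValueError(f"expected dose units 'Gy', found {meta.get('units')!r}")
    values = np.load(prefix.with_suffix(".npy"))
    return DoseGrid(meta["origin_mm"], meta["spacing_mm"], values, meta["frame_id"])


def save_mask(mask: ROIMask, path_prefix: str | os.PathLike) -> tuple[Path, Path]:
    prefix = Path(path_prefix)
    npy, sidecar = prefix.with_suffix(".npy"), prefix.with_suffix(".json")
    np.save(npy, mask.occupancy)
    meta = _sidecar(mask, "boolean")
    meta["name"] = mask.name
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return npy, sidecar


def load_mask(path_prefix: str | os.PathLike) -> ROIMask:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    occ = np.load(prefix.with_suffix(".npy"))
    return ROIMask(
        meta.get("name", prefix.stem), occ, meta["origin_mm"], meta["spacing_mm"], meta["frame_id"]
    )


def write_dvh_csv(dvh: CumulativeDVH, path: str | os.PathLike) -> Path:
    path = Path(path)
    lines = ["structure,total_volume_cc,bin_width_gy"]
    lines.append(f"{dvh.structure},{float(dvh.total_volume_cc)!r},{dvh.bin_width!r}")
    lines.append("dose_gy,volume_cc")
    lines.extend(
        f"{float(e)!r},{float(v)!r}" for e, v in zip(dvh.bin_edges, dvh.volume_cc)
    )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_dvh_csv(path: str | os.PathLike) -> CumulativeDVH:
    lines = Path(path).read_text().strip().splitlines()
    if lines[0].split(",")[0] != "structure" or lines[2] != "dose_gy,volume_cc":
        raise ValueError(f"{path}: not a DVH CSV file")
    structure, total_cc, _bin_width = lines[1].split(",")
    rows = np.array([[float(v) for v in ln.split(",")] for ln in lines[3:]])
    return CumulativeDVH(
        structure=structure,
        bin_edges=rows[:, 0],
        volume_cc=rows[:, 1],
        total_volume_cc=float(total_cc),
    )


# --------------------------------------------------------------------------
# DICOM RT
# --------------------------------------------------------------------------

_AXIS_ALIGNED = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def read_rtdose(
    path: str | os.PathLike,
    n_fractions: int = 5,
    prescription_dose_gy: float = 50.0,
    arm: str = "single",
) -> PlanDose:
    """Read a DICOM RTDOSE grid into a :class:`PlanDose` (values in Gy)."""
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise UnsupportedDicomError(f"{path}: not an RTDOSE object")
    if getattr(ds, "DoseUnits", None) != "GY":
        raise UnsupportedDicomError(
            f"{path}: unsupported DoseUnits {getattr(ds, 'DoseUnits', None)!r} (need GY)"
        )
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise UnsupportedDicomError(f"{path}: missing DoseGridScaling")
    iop = tuple(float(v) for v in ds.ImageOrientationPatient)
    if any(abs(a - b) > 1e-6 for a, b in zip(iop, _AXIS_ALIGNED)):
        raise UnsupportedDicomError(f"{path}: tilted orientation {iop} unsupported")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size < 2 or np.any(np.abs(dz - dz[0]) > 1e-6) or dz[0] <= 0:
        raise UnsupportedDicomError(f"{path}: non-uniform frame offsets unsupported")
    values = ds.pixel_array.astype(np.float64) * float(scaling)  # (z, y, x)
    values = values.transpose(2, 1, 0)  # -> (x, y, z)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    origin = (origin[0], origin[1], origin[2] + float(offsets[0]))
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), float(dz[0]))
    grid = DoseGrid(origin, spacing, values, frame_id=str(ds.FrameOfReferenceUID))
    return PlanDose(grid, n_fractions=n_fractions, prescription_dose_gy=prescription_dose_gy, arm=arm)


def rasterize_rtstruct(
    path: str | os.PathLike, geometry: DoseGrid
) -> dict[str, ROIMask]:
    """Rasterize RTSTRUCT planar contours onto a grid (centre-in-polygon).

    Each contour's points are assigned to the nearest z slice; multiple
    contours of one ROI are OR-ed (holes are not subtracted).
    """
    import pydicom
    from matplotlib.path import Path as MplPath

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise UnsupportedDicomError(f"{path}: not an RTSTRUCT object")
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    xs = geometry.axis_centers(0)
    ys = geometry.axis_centers(1)
    zs = geometry.axis_centers(2)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    plane_points = np.column_stack([xx.ravel(), yy.ravel()])
    masks: dict[str, ROIMask] = {}
    for roi_contour in ds.ROIContourSequence:
        name = roi_names.get(int(roi_contour.ReferencedROINumber), "unknown")
        occ = np.zeros(geometry.dims, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            k = int(np.argmin(np.abs(zs - pts[0, 2])))
            inside = MplPath(pts[:, :2]).contains_points(plane_points)
            occ[:, :, k] |= inside.reshape(len(xs), len(ys))
        masks[name] = ROIMask.on_grid(name, occ, geometry)
    return masks
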