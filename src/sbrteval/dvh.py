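"""Dose-volume histograms and the DVH-derived metric families.

All point metrics (Dmax/Dmean/Dmin, Vx, Dx-cc, coverage) are computed
voxel-exactly from the raw member doses of a structure, never from histogram
bins.  "Receiving x Gy" uses the closed comparison ``dose >= x``; the
complementary "receiving less than x Gy" uses the strict ``dose < x``, so
``v_dose_cc(x) + v_below_cc(x)`` equals the structure volume exactly.

Dose-at-volume queries (``d_at_cc``, ``d_at_pct``) sort the member doses in
descending order, cumulate volume in voxel steps and interpolate linearly
between voxel boundaries, which makes them exact at integer multiples of the
voxel volume.

A :class:`CumulativeDVH` (default bin width 0.01 Gy) backs the radiobiology
module and the DVH-file-only workflow; curve-based metric extraction for that
workflow is provided by the ``dvh_*`` functions and is accurate to one bin
width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import DoseGrid, ROIMask, same_geometry

__all__ = [
    "EmptyStructureError",
    "CumulativeDVH",
    "DVHMetricSet",
    "compute_cumulative_dvh",
    "dvh_metrics",
    "structure_doses",
    "dose_stats",
    "v_dose_pct",
    "v_dose_cc",
    "v_below_cc",
    "d_at_cc",
    "d_at_pct",
    "coverage",
    "dvh_volume_at",
    "dvh_dose_at_cc",
    "dvh_mean_dose",
    "dvh_max_dose",
    "dvh_min_dose",
]

DEFAULT_BIN_WIDTH_GY = 0.01


class EmptyStructureError(ValueError):
    """A metric was requested for a structure with no voxels."""


def structure_doses(dose: DoseGrid, mask: ROIMask) -> np.ndarray:
    """Member doses (Gy) of a structure; raises if the mask is empty."""
    same_geometry(dose, mask)
    d = dose.values[mask.occupancy]
    if d.size == 0:
        raise EmptyStructureError(f"structure '{mask.name}' contains no voxels")
    return d


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: volume (cc) receiving at least each bin-edge dose."""

    structure: str
    bin_edges: np.ndarray  # Gy, ascending from 0, constant width
    volume_cc: np.ndarray  # cc at or above each edge, non-increasing
    total_volume_cc: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        vol = np.asarray(self.volume_cc, dtype=np.float64)
        if edges.ndim != 1 or edges.size < 2 or edges[0] != 0.0:
            raise ValueError("bin_edges must be a 1-D ascending grid starting at 0")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin_edges must have a constant positive width")
        if vol.shape != edges.shape:
            raise ValueError("volume_cc must align with bin_edges")
        if np.any(np.diff(vol) > 1e-9):
            raise ValueError("cumulative volume must be non-increasing")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "volume_cc", vol)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin-centre doses Gy, bin volumes cc); any residual volume beyond
        the last edge is assigned to a final half-bin."""
        centres = self.bin_edges[:-1] + self.bin_width / 2.0
        vols = self.volume_cc[:-1] - self.volume_cc[1:]
        if self.volume_cc[-1] > 0:
            centres = np.append(centres, self.bin_edges[-1] + self.bin_width / 2.0)
            vols = np.append(vols, self.volume_cc[-1])
        return centres, vols


def compute_cumulative_dvh(
    dose: DoseGrid, mask: ROIMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> CumulativeDVH:
    """Exact voxel-counting cumulative DVH of one structure."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0 Gy")
    d = structure_doses(dose, mask)
    vv = mask.voxel_volume_cc
    n_edges = int(np.floor(float(d.max()) / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    d_sorted = np.sort(d)
    counts_at_or_above = d.size - np.searchsorted(d_sorted, edges, side="left")
    return CumulativeDVH(
        structure=mask.name,
        bin_edges=edges,
        volume_cc=counts_at_or_above * vv,
        total_volume_cc=d.size * vv,
    )


# --------------------------------------------------------------------------
# voxel-exact point metrics
# --------------------------------------------------------------------------

def dose_stats(dose: DoseGrid, mask: ROIMask) -> tuple[float, float, float]:
    """(d_min, d_mean, d_max) in Gy, true voxel extrema (no percentile surrogates)."""
    d = structure_doses(dose, mask)
    return float(d.min()), float(d.mean()), float(d.max())


def v_dose_pct(dose: DoseGrid, mask: ROIMask, x_gy: float) -> float:
    """Percent of structure volume receiving at least ``x_gy`` (closed)."""
    d = structure_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(d >= x_gy)) / d.size


def v_dose_cc(dose: DoseGrid, mask: ROIMask, x_gy: float) -> float:
    """Absolute volume (cc) receiving at least ``x_gy`` (closed)."""
    d = structure_doses(dose, mask)
    return float(np.count_nonzero(d >= x_gy)) * mask.voxel_volume_cc


def v_below_cc(dose: DoseGrid, mask: ROIMask, x_gy: float) -> float:
    """Absolute volume (cc) receiving strictly less than ``x_gy``."""
    d = structure_doses(dose, mask)
    return float(np.count_nonzero(d < x_gy)) * mask.voxel_volume_cc


def d_at_cc(dose: DoseGrid, mask: ROIMask, volume_cc: float) -> float:
    """Minimum dose (Gy) to the hottest ``volume_cc`` of the structure.

    Member doses are sorted descending; ties are broken by linear voxel index
    (the sort is stable), volume cumulates in voxel steps and the dose is
    interpolated linearly between voxel boundaries.
    """
    if volume_cc < 0:
        raise ValueError("queried volume must be >= 0 cc")
    d = structure_doses(dose, mask)
    vv = mask.voxel_volume_cc
    total = d.size * vv
    if volume_cc > total + 1e-9:
        raise ValueError(
            f"queried volume {volume_cc} cc exceeds structure volume {total:.3f} cc"
        )
    d_desc = np.sort(d, kind="stable")[::-1]
    boundaries = np.arange(1, d.size + 1) * vv
    return float(np.interp(min(volume_cc, total), boundaries, d_desc))


def d_at_pct(dose: DoseGrid, mask: ROIMask, pct: float) -> float:
    """Minimum dose (Gy) to the hottest ``pct`` percent of the structure."""
    if not 0 <= pct <= 100:
        raise ValueError("percentage must be in [0, 100]")
    d = structure_doses(dose, mask)
    return d_at_cc(dose, mask, pct / 100.0 * d.size * mask.voxel_volume_cc)


def coverage(dose: DoseGrid, target: ROIMask, prescription_dose_gy: float) -> float:
    """Percent of the target volume inside the prescription isodose (closed)."""
    if prescription_dose_gy <= 0:
        raise ValueError("prescription dose must be > 0 Gy")
    return v_dose_pct(dose, target, prescription_dose_gy)


@dataclass(frozen=True)
class DVHMetricSet:
    """Bundle of the DVH-derived metrics reported for one structure."""

    structure: str
    total_volume_cc: float
    d_max: float
    d_mean: float
    d_min: float
    v_dose_pct: dict[float, float] = field(default_factory=dict)
    v_dose_cc: dict[float, float] = field(default_factory=dict)
    v_below_cc: dict[float, float] = field(default_factory=dict)
    d_at_cc: dict[float, float] = field(default_factory=dict)
    d_at_pct: dict[float, float] = field(default_factory=dict)
    coverage_pct: float | None = None


def dvh_metrics(
    dose: DoseGrid,
    mask: ROIMask,
    v_pct_queries: tuple[float, ...] = (),
    v_cc_queries: tuple[float, ...] = (),
    v_below_cc_queries: tuple[float, ...] = (),
    d_cc_queries: tuple[float, ...] = (),
    d_pct_queries: tuple[float, ...] = (),
    prescription_dose_gy: float | None = None,
) -> DVHMetricSet:
    """Evaluate a set of V/D queries voxel-exactly for one structure."""
    d_min, d_mean, d_max = dose_stats(dose, mask)
    return DVHMetricSet(
        structure=mask.name,
        total_volume_cc=mask.volume_cc,
        d_max=d_max,
        d_mean=d_mean,
        d_min=d_min,
        v_dose_pct={x: v_dose_pct(dose, mask, x) for x in v_pct_queries},
        v_dose_cc={x: v_dose_cc(dose, mask, x) for x in v_cc_queries},
        v_below_cc={x: v_below_cc(dose, mask, x) for x in v_below_cc_queries},
        d_at_cc={v: d_at_cc(dose, mask, v) for v in d_cc_queries},
        d_at_pct={p: d_at_pct(dose, mask, p) for p in d_pct_queries},
        coverage_pct=(
            coverage(dose, mask, prescription_dose_gy)
            if prescription_dose_gy is not None
            else None
        ),
    )


# --------------------------------------------------------------------------
# curve-based metrics for the DVH-file-only workflow (one-bin-width accuracy)
# --------------------------------------------------------------------------

def dvh_volume_at(dvh: CumulativeDVH, dose_gy: float) -> float:
    """Volume (cc) at or above a dose, linearly interpolated on the curve."""
    if dose_gy <= 0:
        return float(dvh.volume_cc[0])
    if dose_gy >= dvh.bin_edges[-1]:
        return float(dvh.volume_cc[-1])
    return float(np.interp(dose_gy, dvh.bin_edges, dvh.volume_cc))


def dvh_dose_at_cc(dvh: CumulativeDVH, volume_cc: float) -> float:
    """Dose (Gy) whose at-or-above volume equals ``volume_cc`` (inverse curve)."""
    if volume_cc < 0 or volume_cc > dvh.total_volume_cc + 1e-9:
        raise ValueError("queried volume outside [0, total structure volume]")
    # volume is non-increasing in dose: interpolate on the reversed curve
    vols = dvh.volume_cc[::-1]
    edges = dvh.bin_edges[::-1]
    return float(np.interp(volume_cc, vols, edges))


def dvh_mean_dose(dvh: CumulativeDVH) -> float:
    centres, vols = dvh.differential()
    return float(np.sum(centres * vols) / dvh.total_volume_cc)


def dvh_max_dose(dvh: CumulativeDVH) -> float:
    nonzero = np.nonzero(dvh.volume_cc > 0)[0]
    return float(dvh.bin_edges[nonzero[-1]]) if nonzero.size else 0.0


def dvh_min_dose(dvh: CumulativeDVH) -> float:
    full = np.nonzero(dvh.volume_cc >= dvh.total_volume_cc - 1e-9)[0]
    return float(dvh.bin_edges[full[-1]]) if full.size else 0.0
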