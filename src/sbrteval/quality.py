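"""Target-centric plan-quality indices for SBRT plan evaluation.

Conventions (the CyberKnife/Multiplan family):

* ``CI  = PIV / TV_PIV`` — prescription isodose volume over the covered part
  of the target.
* ``nCI = (TV x PIV) / TV_PIV**2 = CI / (coverage / 100)`` — penalizes both
  spill and under-coverage; equals CI at 100 % coverage.
* ``HI  = Dmax / PD`` — maximum target dose over the prescription dose.
* ``GI  = V(PD/2) / V(PD)`` — Paddick gradient index, half-prescription
  isodose volume over the prescription isodose volume, measured over the
  body.  A variant referenced to half the maximum dose is available via
  ``half_of="max"``.
* ``PIDL = 100 x PD / Dmax`` — the prescription isodose line, the reciprocal
  of HI as a percentage (a plan normalized to its ~70 % isodose line has
  HI ~ 1.43).

Alternative families (RTOG CI = PIV/TV, Paddick CN/COIN) are deliberately not
implemented; see docs/methods.md for why this convention set was chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dvh import structure_doses
from .grid import DoseGrid, ROIMask, same_geometry

__all__ = [
    "ConformitySet",
    "conformity_indices",
    "homogeneity_index",
    "gradient_index",
    "pidl",
]


@dataclass(frozen=True)
class ConformitySet:
    """Conformity/homogeneity/gradient indices of one plan for one target.

    ``defined`` is False when no target voxel reaches the prescription dose,
    in which case CI/nCI/GI are NaN (flagged, never silently extrapolated).
    """

    structure: str
    coverage_pct: float
    piv_cc: float
    tv_cc: float
    tv_piv_cc: float
    ci: float
    nci: float
    hi: float
    gi: float
    pidl_pct: float
    defined: bool = True


def homogeneity_index(d_max_gy: float, prescription_dose_gy: float) -> float:
    """HI = Dmax / PD (dimensionless, >= 1 for a covered target)."""
    if d_max_gy <= 0 or prescription_dose_gy <= 0:
        raise ValueError("d_max and prescription dose must be > 0 Gy")
    return d_max_gy / prescription_dose_gy


def pidl(d_max_gy: float, prescription_dose_gy: float) -> float:
    """Prescription isodose line as a percent of Dmax (reciprocal of HI)."""
    if d_max_gy <= 0 or prescription_dose_gy <= 0:
        raise ValueError("d_max and prescription dose must be > 0 Gy")
    return 100.0 * prescription_dose_gy / d_max_gy


def gradient_index(
    dose: DoseGrid,
    body: ROIMask,
    prescription_dose_gy: float,
    half_of: str = "prescription",
) -> float:
    """Paddick gradient index V(half dose) / V(PD) over the body.

    ``half_of`` selects the numerator's reference: half the prescription dose
    (default) or half the maximum body dose.  Returns NaN when no body voxel
    reaches the prescription dose.
    """
    if prescription_dose_gy <= 0:
        raise ValueError("prescription dose must be > 0 Gy")
    if half_of not in ("prescription", "max"):
        raise ValueError("half_of must be 'prescription' or 'max'")
    d = structure_doses(dose, body)
    n_piv = int(np.count_nonzero(d >= prescription_dose_gy))
    if n_piv == 0:
        return math.nan
    half = (prescription_dose_gy if half_of == "prescription" else float(d.max())) / 2.0
    return float(np.count_nonzero(d >= half)) / n_piv


def conformity_indices(
    dose: DoseGrid,
    target: ROIMask,
    body: ROIMask,
    prescription_dose_gy: float,
    half_of: str = "prescription",
) -> ConformitySet:
    """Coverage, CI, nCI, HI, GI and PIDL for one target on one plan dose.

    PIV is measured on the total (for superimposed plans: summed) dose over
    the body mask; TV_PIV on the target mask.
    """
    if prescription_dose_gy <= 0:
        raise ValueError("prescription dose must be > 0 Gy")
    same_geometry(dose, target)
    same_geometry(dose, body)
    vv = target.voxel_volume_cc
    d_target = structure_doses(dose, target)
    d_body = structure_doses(dose, body)
    n_tv = d_target.size
    n_tv_piv = int(np.count_nonzero(d_target >= prescription_dose_gy))
    n_piv = int(np.count_nonzero(d_body >= prescription_dose_gy))
    tv_cc = n_tv * vv
    tv_piv_cc = n_tv_piv * vv
    piv_cc = n_piv * vv
    cov = 100.0 * (n_tv_piv / n_tv)  # ratio of counts: exact at full coverage
    d_max = float(d_target.max())
    hi = homogeneity_index(d_max, prescription_dose_gy)
    if tv_piv_cc == 0:
        return ConformitySet(
            structure=target.name,
            coverage_pct=0.0,
            piv_cc=piv_cc,
            tv_cc=tv_cc,
            tv_piv_cc=0.0,
            ci=math.nan,
            nci=math.nan,
            hi=hi,
            gi=math.nan,
            pidl_pct=pidl(d_max, prescription_dose_gy),
            defined=False,
        )
    ci = n_piv / n_tv_piv
    nci = n_tv * n_piv / n_tv_piv**2
    gi = gradient_index(dose, body, prescription_dose_gy, half_of=half_of)
    return ConformitySet(
        structure=target.name,
        coverage_pct=cov,
        piv_cc=piv_cc,
        tv_cc=tv_cc,
        tv_piv_cc=tv_piv_cc,
        ci=ci,
        nci=nci,
        hi=hi,
        gi=gi,
        pidl_pct=pidl(d_max, prescription_dose_gy),
        defined=True,
    )
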