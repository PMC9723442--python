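"""Fractionation-corrected generalized equivalent uniform dose (gEUD).

Model
-----
Each volume element's total physical dose ``D`` (delivered in ``n_f`` equal
fractions) is first converted to its 2-Gy-per-fraction equivalent with the
linear-quadratic model,

    EQD = D * (alpha/beta + D/n_f) / (alpha/beta + d_ref),    d_ref = 2 Gy,

and the structure's gEUD is the generalized (power) mean of those equivalent
doses with the tissue-specific volume-effect exponent ``a``:

    gEUD = ( sum_i v_i * EQD_i**a ) ** (1/a),   sum_i v_i = 1.

``a = 1`` gives the volume-weighted mean EQD (parallel organs such as lung);
large positive ``a`` approaches the maximum EQD (serial organs such as spinal
cord).  The default parameter table ships in ``data/eud_params.yaml``:
PTV (a=10, alpha/beta=10), lung (1, 4), heart (3, 3.7), spinal cord (20, 3),
esophagus (16.67, 4.9).  No validated parameters exist here for trachea or
bronchus, so gEUD for those structures is refused rather than guessed.

The percent-reduction statistic used for headline plan comparisons is
``100 * (S - D) / S`` — positive when the superimposed double plan delivers
less than the single plan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .dvh import CumulativeDVH, structure_doses
from .grid import DoseGrid, ROIMask

__all__ = [
    "EUDParams",
    "EUDResult",
    "eqd_correct",
    "geud",
    "geud_voxelwise",
    "percent_reduction",
    "default_eud_params",
    "eud_params_for",
    "STRUCTURE_PARAM_KEY",
]

#: Floor applied to zero-dose elements when ``a < 0`` (keeps the power mean
#: finite; irrelevant for the all-positive default exponents).
EPS_DOSE_GY = 1e-6

#: Canonical structure name -> parameter-table key.
STRUCTURE_PARAM_KEY = {
    "ptv1": "ptv",
    "ptv2": "ptv",
    "ptv12": "ptv",
    "ptv": "ptv",
    "lungs": "lung",
    "lung": "lung",
    "heart": "heart",
    "cord": "spinal_cord",
    "spinal_cord": "spinal_cord",
    "esophagus": "esophagus",
}


@dataclass(frozen=True)
class EUDParams:
    """Per-structure gEUD parameters."""

    structure: str
    a: float
    alpha_beta: float
    n_fractions: int = 5
    reference_fraction_dose: float = 2.0

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("volume-effect exponent a must be nonzero")
        if self.alpha_beta <= 0:
            raise ValueError("alpha/beta must be > 0 Gy")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


@dataclass(frozen=True)
class EUDResult:
    structure: str
    eud_gy: float
    params: EUDParams
    source: str  # "dvh" or "voxel"


def eqd_correct(total_dose_gy, params: EUDParams):
    """LQ conversion of a total dose in ``n_fractions`` to its 2-Gy/fx equivalent.

    Accepts scalars or arrays; identity when the fraction dose equals the
    reference fraction dose (2 Gy).
    """
    d = np.asarray(total_dose_gy, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("total dose must be >= 0 Gy")
    out = d * (params.alpha_beta + d / params.n_fractions) / (
        params.alpha_beta + params.reference_fraction_dose
    )
    return float(out) if np.isscalar(total_dose_gy) else out


def _power_mean(values: np.ndarray, weights: np.ndarray, a: float) -> float:
    if a < 0:
        values = np.maximum(values, EPS_DOSE_GY)
    return float(np.sum(weights * values**a) ** (1.0 / a))


def geud(dvh: CumulativeDVH, params: EUDParams) -> EUDResult:
    """gEUD from a cumulative DVH (differential bins at bin-centre doses)."""
    if dvh.total_volume_cc <= 0:
        raise ValueError(f"structure '{dvh.structure}' has zero volume")
    centres, vols = dvh.differential()
    keep = vols > 0
    centres, vols = centres[keep], vols[keep]
    weights = vols / vols.sum()
    eqd = eqd_correct(centres, params)
    return EUDResult(dvh.structure, _power_mean(eqd, weights, params.a), params, "dvh")


def geud_voxelwise(dose: DoseGrid, mask: ROIMask, params: EUDParams) -> EUDResult:
    """gEUD directly from member voxel doses (no binning); validation path."""
    d = structure_doses(dose, mask)
    weights = np.full(d.size, 1.0 / d.size)
    eqd = eqd_correct(d, params)
    return EUDResult(mask.name, _power_mean(eqd, weights, params.a), params, "voxel")


def percent_reduction(value_s: float, value_d: float) -> float:
    """Signed percent by which the double plan is below the single plan.

    ``100 * (S - D) / S``; positive when the double plan's value is lower.
    """
    if value_s == 0:
        raise ValueError("single-plan value is zero; percent reduction undefined")
    return 100.0 * (value_s - value_d) / value_s


def default_eud_params(
    n_fractions: int = 5,
    tumor_a_negative: bool = False,
    path=None,
) -> dict[str, EUDParams]:
    """Load the shipped (or a user) gEUD parameter table.

    ``tumor_a_negative`` flips the PTV exponent to the negative-``a`` tumor
    convention (gEUD then tracks the coldest part of the target); the default
    keeps the positive exponent of the shipped table.
    """
    if path is None:
        text = (
            resources.files("sbrteval").joinpath("data/eud_params.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    ref = float(raw.get("reference_fraction_dose", 2.0))
    table = {
        key: EUDParams(
            structure=key,
            a=float(entry["a"]),
            alpha_beta=float(entry["alpha_beta"]),
            n_fractions=n_fractions,
            reference_fraction_dose=ref,
        )
        for key, entry in raw["structures"].items()
    }
    if tumor_a_negative and "ptv" in table:
        table["ptv"] = replace(table["ptv"], a=-abs(table["ptv"].a))
    return table


def eud_params_for(
    structure: str, table: dict[str, EUDParams] | None = None, **kwargs
) -> EUDParams:
    """Resolve the parameter set for a canonical structure name.

    Refuses trachea/bronchus (and their union): no validated volume-effect
    parameters exist for them, and guessing would silently fabricate biology.
    """
    table = table if table is not None else default_eud_params(**kwargs)
    key = STRUCTURE_PARAM_KEY.get(structure)
    if key is None or key not in table:
        raise ValueError(
            f"no validated gEUD parameters for structure '{structure}'; "
            "gEUD is not computed for it"
        )
    return replace(table[key], structure=structure)
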