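"""Seeded synthetic bilateral-lung phantoms and paired plan-dose generation.

The generator emulates the study conditions of a bilateral peripheral lung
SBRT cohort: two planning target volumes, one per lung (PTV1 volume sampled
log-uniformly in 1.67-62.31 cc, PTV2 in 4.49-26.21 cc, matching the printed
clinical ranges), built as spherical gross tumor volumes expanded by a 5 mm
isotropic margin; ellipsoidal body, lungs and heart; tubular spinal cord,
trachea, bronchi and esophagus; 2.5 mm isotropic voxels.

The dose model is phenomenological, not a beam model: each target receives a
plateau of ``PD * peak`` inside the PTV that falls off as a Gaussian shell
``exp(-(r - R)^2 / (2 sigma^2))`` outside, on top of a smoothly apodized
low-dose bath over the body plus optional Gaussian noise (clipped at 0 Gy).
The two arms differ the way the two planning strategies differ in practice:

* single planning ("S"): both target kernels in one plan, broader falloff
  (``sigma_single``) and a larger bath — one optimization covering two
  distant targets spills more mid/low dose;
* double plannings ("D"): one kernel per component plan with tighter falloff
  (``sigma_double``), half the (smaller) bath each, slightly hotter plateau
  (separate optimization drives deeper dose escalation inside each target);
  the components are summed explicitly with :func:`sbrteval.grid.sum_doses`.

These defaults reproduce the clinical study's *directional* findings (lower
GI, lung V5/V20 and OAR gEUD for the double plan; slightly higher target
Dmean/HI); magnitudes are not calibrated to the real patients.

Everything is a pure function of its spec and seed: each phantom draws from
named substreams (geometry, dose, noise) so regeneration is bit-identical
even if one stage's draw count changes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .dvh import coverage
from .grid import DoseGrid, PlanDose, ROIMask, StructureSet, sum_doses

__all__ = [
    "PhantomSpec",
    "DoseModelSpec",
    "TargetSphere",
    "Phantom",
    "PatientCase",
    "generate_phantom",
    "generate_plan_dose",
    "generate_cohort",
]

PTV1_VOLUME_RANGE_CC = (1.67, 62.31)
PTV2_VOLUME_RANGE_CC = (4.49, 26.21)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic bilateral-lung phantom (mm, cc)."""

    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    dims: tuple[int, int, int] = (124, 84, 88)
    body_semiaxes: tuple[float, float, float] = (150.0, 100.0, 105.0)
    lung_center_x: float = 75.0
    lung_center_yz: tuple[float, float] = (0.0, 5.0)
    lung_semiaxes: tuple[float, float, float] = (55.0, 65.0, 85.0)
    heart_center: tuple[float, float, float] = (0.0, 20.0, -25.0)
    heart_semiaxes: tuple[float, float, float] = (35.0, 32.0, 40.0)
    cord_center_xy: tuple[float, float] = (0.0, -80.0)
    cord_radius: float = 6.0
    trachea_center_xy: tuple[float, float] = (0.0, -30.0)
    trachea_radius: float = 9.0
    carina_z: float = 20.0
    bronchus_radius: float = 7.0
    esophagus_center_xy: tuple[float, float] = (0.0, -55.0)
    esophagus_radius: float = 5.0
    ptv1_volume_cc: float | None = None  # None -> sampled from the clinical range
    ptv2_volume_cc: float | None = None
    gtv_to_ptv_margin_mm: float = 5.0
    #: minimum gap between a PTV surface and the central structures (airways,
    #: heart, cord, esophagus) — peripheral tumors only, as in the emulated
    #: cohort, keeping the steep falloff shell off the bronchial tree
    central_clearance_mm: float = 10.0
    seed: int = 0


@dataclass(frozen=True)
class DoseModelSpec:
    """Parameters of the phenomenological paired dose model (Gy, mm)."""

    prescription_dose_gy: float = 50.0
    n_fractions: int = 5
    peak_single: float = 1.42   # plateau = peak * PD; PIDL ~ 100/peak %
    peak_double: float = 1.47
    sigma_single_mm: float = 4.0
    sigma_double_mm: float = 3.0
    bath_single_gy: float = 4.0
    bath_double_gy: float = 2.8  # total over both components
    noise_sd_gy: float = 0.3
    min_coverage_pct: float = 95.0
    seed: int = 0


@dataclass(frozen=True)
class TargetSphere:
    center_mm: tuple[float, float, float]
    radius_mm: float
    requested_volume_cc: float


@dataclass(frozen=True)
class Phantom:
    structures: StructureSet
    geometry: DoseGrid  # zero-valued carrier of origin/spacing/dims/frame
    targets: tuple[TargetSphere, TargetSphere]
    spec: PhantomSpec


@dataclass(frozen=True)
class PatientCase:
    patient_id: str
    phantom: Phantom
    plan_s: PlanDose
    plan_d_components: tuple[PlanDose, PlanDose]

    @property
    def plan_d(self) -> PlanDose:
        """Superimposed double plan (explicit summation of the components)."""
        return sum_doses(*self.plan_d_components)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, stable child stream: independent of other substreams' draws."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _coords(spec: PhantomSpec):
    """Voxel-centre coordinate arrays (mm), grid centred on the origin."""
    axes = []
    for n, s in zip(spec.dims, spec.spacing):
        extent = n * s
        axes.append(-extent / 2.0 + s / 2.0 + np.arange(n) * s)
    x, y, z = axes
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _ellipsoid(x, y, z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _cylinder_z(x, y, z, center_xy, radius, z_min=None, z_max=None) -> np.ndarray:
    cx, cy = center_xy
    m = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
    m = m & np.ones_like(z, dtype=bool)
    if z_min is not None:
        m = m & (z >= z_min)
    if z_max is not None:
        m = m & (z <= z_max)
    return m


def _capsule(x, y, z, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (a bronchus-like tube)."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    len2 = float(d @ d)
    px, py, pz = x - p0[0], y - p0[1], z - p0[2]
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / len2, 0.0, 1.0)
    dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return dist2 <= radius**2


def _sphere_radius_mm(volume_cc: float) -> float:
    return 10.0 * (3.0 * volume_cc / (4.0 * math.pi)) ** (1.0 / 3.0)


def _sample_target(
    rng: np.random.Generator,
    spec: PhantomSpec,
    side: int,
    volume_range: tuple[float, float],
    fixed_volume: float | None,
    forbidden: np.ndarray,
    lung_occ: np.ndarray,
    coords,
) -> tuple[TargetSphere, np.ndarray]:
    """Sample one peripheral target: a PTV sphere fully inside its lung and
    clear of the central structures (airways, heart, cord, esophagus)."""
    if fixed_volume is not None:
        volume = float(fixed_volume)
        if not volume_range[0] <= volume <= volume_range[1]:
            raise ValueError(
                f"requested PTV volume {volume} cc outside clinical range {volume_range}"
            )
    else:
        lo, hi = volume_range
        volume = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
    radius = _sphere_radius_mm(volume)
    lung_center = np.array(
        [side * spec.lung_center_x, spec.lung_center_yz[0], spec.lung_center_yz[1]]
    )
    semis = np.asarray(spec.lung_semiaxes)
    # conservative sphere-in-ellipsoid criterion: normalized centre offset
    # bounded so the PTV (plus 2 mm slack) stays inside the lung
    f = 1.0 - (radius + 2.0) / float(semis.min())
    if f <= 0:
        raise ValueError(
            f"PTV radius {radius:.1f} mm incompatible with lung semiaxes {tuple(semis)}"
        )
    x, y, z = coords
    for _ in range(200):
        u = rng.uniform(-f, f, size=3)
        if float(np.sum(u**2)) > f**2:
            continue
        center = lung_center + u * semis
        r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        occ = r2 <= radius**2
        guard = r2 <= (radius + spec.central_clearance_mm) ** 2
        if np.any(guard & forbidden) or np.any(occ & ~lung_occ):
            continue  # too central, or pokes out of the lung
        target = TargetSphere(tuple(float(c) for c in center), radius, volume)
        return target, occ
    raise ValueError(
        f"could not place a {radius:.1f} mm PTV inside the lung clear of the "
        "central structures"
    )


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the structure set and grid geometry of one phantom."""
    rng = _substream(spec.seed, "geometry")
    x, y, z = _coords(spec)
    dims = spec.dims
    frame = f"phantom-{spec.seed}"
    geometry = DoseGrid(
        origin=(float(x[0, 0, 0]), float(y[0, 0, 0]), float(z[0, 0, 0])),
        spacing=spec.spacing,
        values=np.zeros(dims),
        frame_id=frame,
    )

    body = _ellipsoid(x, y, z, (0.0, 0.0, 0.0), spec.body_semiaxes)
    lungs_raw = {}
    for side in (+1, -1):
        lungs_raw[side] = _ellipsoid(
            x,
            y,
            z,
            (side * spec.lung_center_x, *spec.lung_center_yz),
            spec.lung_semiaxes,
        )
    heart = _ellipsoid(x, y, z, spec.heart_center, spec.heart_semiaxes) & body
    cord = _cylinder_z(x, y, z, spec.cord_center_xy, spec.cord_radius) & body
    trachea = (
        _cylinder_z(x, y, z, spec.trachea_center_xy, spec.trachea_radius, z_min=spec.carina_z)
        & body
    )
    carina = (0.0, spec.trachea_center_xy[1], spec.carina_z)
    bronchus = np.zeros(dims, dtype=bool)
    for side in (+1, -1):
        tip = (
            side * spec.lung_center_x * 0.6,
            spec.lung_center_yz[0] - 10.0,
            spec.carina_z - 5.0,
        )
        bronchus |= _capsule(x, y, z, carina, tip, spec.bronchus_radius)
    bronchus &= body
    esophagus = _cylinder_z(x, y, z, spec.esophagus_center_xy, spec.esophagus_radius) & body
    airways_and_mediastinum = heart | trachea | bronchus | esophagus | cord
    lungs = (lungs_raw[+1] | lungs_raw[-1]) & body & ~airways_and_mediastinum

    # Targets: the GTV->PTV margin is applied to the solid (sphere radius
    # R_gtv + margin) before rasterization, so the realized PTV volume tracks
    # the requested volume to within centre-sampling error.
    masks: dict[str, ROIMask] = {}
    targets_list = []
    for i, (side, vol_range, fixed) in enumerate(
        [(+1, PTV1_VOLUME_RANGE_CC, spec.ptv1_volume_cc),
         (-1, PTV2_VOLUME_RANGE_CC, spec.ptv2_volume_cc)],
        start=1,
    ):
        t, ptv_occ = _sample_target(
            rng, spec, side, vol_range, fixed,
            forbidden=airways_and_mediastinum, lung_occ=lungs_raw[side],
            coords=(x, y, z),
        )
        cx, cy, cz = t.center_mm
        gtv_radius = max(t.radius_mm - spec.gtv_to_ptv_margin_mm, 1.0)
        gtv_occ = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= gtv_radius**2
        masks[f"gtv{i}"] = ROIMask.on_grid(f"gtv{i}", gtv_occ, geometry)
        masks[f"ptv{i}"] = ROIMask.on_grid(f"ptv{i}", ptv_occ, geometry)
        targets_list.append(t)
    targets = tuple(targets_list)
    if np.any(masks["ptv1"].occupancy & masks["ptv2"].occupancy):
        raise ValueError("PTV1 and PTV2 overlap; targets must be disjoint")

    for name, occ in (
        ("lungs", lungs),
        ("heart", heart),
        ("cord", cord),
        ("trachea", trachea),
        ("bronchus", bronchus),
        ("esophagus", esophagus),
        ("body", body),
    ):
        masks[name] = ROIMask.on_grid(name, occ, geometry)
    return Phantom(StructureSet(masks), geometry, targets, spec)


def _target_kernel(
    phantom: Phantom, target: TargetSphere, peak_dose_gy: float, sigma_mm: float
) -> np.ndarray:
    x, y, z = _coords(phantom.spec)
    cx, cy, cz = target.center_mm
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    shell = np.exp(-np.square(np.maximum(r - target.radius_mm, 0.0)) / (2.0 * sigma_mm**2))
    return peak_dose_gy * shell  # == peak inside the PTV, Gaussian shell outside


def _bath_profile(phantom: Phantom) -> np.ndarray:
    """Smoothly apodized body bath: 1 at the body centre, 0 at the surface."""
    x, y, z = _coords(phantom.spec)
    ax, ay, az = phantom.spec.body_semiaxes
    rho2 = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2
    return np.clip(1.0 - rho2, 0.0, None)


def _noise(phantom: Phantom, rng: np.random.Generator, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(phantom.spec.dims)
    return rng.normal(0.0, sd, size=phantom.spec.dims)


def generate_plan_dose(phantom: Phantom, spec: DoseModelSpec, arm: str):
    """Generate the single plan ("S") or the two double-plan components ("D").

    Coverage of every PTV at the prescription dose is verified on the total
    dose; if below ``min_coverage_pct`` the plateau is inflated by 5 % and
    generation retried (bounded), then an error is raised.
    """
    if arm not in ("S", "D"):
        raise ValueError("arm must be 'S' or 'D'")
    pd_gy = spec.prescription_dose_gy
    bath = _bath_profile(phantom)
    peak = spec.peak_single if arm == "S" else spec.peak_double
    for attempt in range(4):
        rng = _substream(spec.seed, f"noise-{arm}-{attempt}")
        scale = peak * 1.05**attempt
        if arm == "S":
            values = (
                _target_kernel(phantom, phantom.targets[0], pd_gy * scale, spec.sigma_single_mm)
                + _target_kernel(phantom, phantom.targets[1], pd_gy * scale, spec.sigma_single_mm)
                + spec.bath_single_gy * bath
                + _noise(phantom, rng, spec.noise_sd_gy)
            )
            plans = PlanDose(
                phantom.geometry.with_values(np.clip(values, 0.0, None)),
                n_fractions=spec.n_fractions,
                prescription_dose_gy=pd_gy,
                arm="single",
            )
            total = plans.grid
        else:
            comps = []
            for target in phantom.targets:
                values = (
                    _target_kernel(phantom, target, pd_gy * scale, spec.sigma_double_mm)
                    + (spec.bath_double_gy / 2.0) * bath
                    + _noise(phantom, rng, spec.noise_sd_gy / math.sqrt(2.0))
                )
                comps.append(
                    PlanDose(
                        phantom.geometry.with_values(np.clip(values, 0.0, None)),
                        n_fractions=spec.n_fractions,
                        prescription_dose_gy=pd_gy,
                        arm="component",
                    )
                )
            plans = (comps[0], comps[1])
            total = sum_doses(*plans).grid
        covered = all(
            coverage(total, phantom.structures[name], pd_gy) >= spec.min_coverage_pct
            for name in ("ptv1", "ptv2")
        )
        if covered:
            return plans
    raise RuntimeError(
        f"could not reach {spec.min_coverage_pct}% PTV coverage after bounded retries"
    )


def generate_cohort(
    n: int = 10,
    master_seed: int = 0,
    phantom_spec: PhantomSpec | None = None,
    dose_spec: DoseModelSpec | None = None,
) -> list[PatientCase]:
    """Generate ``n`` independent phantoms with paired Plan S / Plan D doses.

    Per-patient child seeds derive deterministically from ``master_seed``;
    a fixed master seed regenerates the identical cohort.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base_phantom = phantom_spec or PhantomSpec()
    base_dose = dose_spec or DoseModelSpec()
    cohort = []
    for i, child in enumerate(np.random.SeedSequence(master_seed).spawn(n)):
        s_phantom, s_dose = (int(v) for v in child.generate_state(2))
        phantom = generate_phantom(replace(base_phantom, seed=s_phantom))
        dspec = replace(base_dose, seed=s_dose)
        plan_s = generate_plan_dose(phantom, dspec, "S")
        comp = generate_plan_dose(phantom, dspec, "D")
        cohort.append(PatientCase(f"p{i + 1:02d}", phantom, plan_s, comp))
    return cohort
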