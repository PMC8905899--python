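"""Synthetic multi-field IMPT phantom cases.

Stands in for clinical CT/plan data: a spherical water-equivalent "head" body
containing a spherical PTV abutted by two organ-at-risk slabs (a brainstem
slab distal to the PTV along +x and a chiasm slab lateral along +y).  Each
treatment field is a parallel broad beam from a gantry angle in the axial
plane; its depth-dose is an SOBP whose modulation covers the target, its
depth-LET curve the matching dose-averaged mix, and its lateral profile a
flat top with Gaussian penumbra.  Water-equivalent depth is the chord length
from the body surface along the beam ray.

Geometry conventions follow :mod:`biorange.grid`: axis order (x, y, z),
world mm, voxel centers at ``origin + (index + 0.5) * spacing``.  A gantry
angle of 90 degrees sends the beam along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage

from . import bragg
from .dvh import Structure
from .grid import VoxelGrid

CONSTANT_RBE = 1.1


@dataclass
class BeamField:
    """One treatment field (parallel broad beam, axial plane)."""

    gantry_angle: float        # degrees; 90 -> beam direction +x
    nominal_range: float       # R0, cm water-equivalent
    modulation: float          # m, cm
    lateral_sigma: float = 3.0  # penumbra sigma, mm
    weight: float = 1.0
    aperture_radius: float = 22.0  # flat-top radius, mm
    n_peaks: int = 12

    def __post_init__(self) -> None:
        if not (0 < self.modulation <= self.nominal_range):
            raise ValueError("modulation must satisfy 0 < m <= R0")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral sigma must be positive")
        if self.weight < 0:
            raise ValueError("field weight must be non-negative")

    @property
    def direction(self) -> np.ndarray:
        theta = math.radians(self.gantry_angle)
        return np.array([math.sin(theta), -math.cos(theta), 0.0])


@dataclass
class PlanSpec:
    """Prescription and field arrangement for one case."""

    prescribed_dose: float      # D_p, Gy(RBE), total
    n_fractions: int
    fields: list[BeamField]
    isocenter: np.ndarray       # mm
    alpha_beta_target: float = 6.0
    alpha_beta_normal: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha_beta_target <= 0 or self.alpha_beta_normal <= 0:
            raise ValueError("alpha/beta ratios must be positive")
        self.isocenter = np.asarray(self.isocenter, dtype=float)

    @property
    def fraction_dose(self) -> float:
        return self.prescribed_dose / self.n_fractions


@dataclass
class PhantomConfig:
    """Geometry and prescription of one synthetic case.

    Defaults describe a brain-like case: 1.5 mm isotropic lattice, a head-
    sized spherical body, a PTV abutting the brainstem slab 3 mm distal along
    +x, prescription 54 Gy(RBE) in 27 fractions of 2 Gy(RBE).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.5                    # mm
    body_radius: float = 66.0               # mm
    ptv_radius: float = 22.0                # mm
    ptv_offset: tuple[float, float, float] = (-10.0, 0.0, 0.0)  # mm, from body center
    ctv_margin: float = 3.0                 # mm, PTV = CTV + margin
    oar_gap: float = 3.0                    # mm between PTV surface and OAR slab
    brainstem_half_size: tuple[float, float, float] = (10.0, 11.0, 16.0)  # mm
    chiasm_half_size: tuple[float, float, float] = (8.0, 5.0, 5.0)        # mm
    prescribed_dose: float = 54.0           # Gy(RBE)
    n_fractions: int = 27
    gantry_angles: tuple[float, ...] = (75.0, 110.0, 255.0, 285.0)
    lateral_sigma: float = 3.0              # mm
    aperture_margin: float = 3.0            # mm beyond PTV radius
    distal_margin: float = 2.0              # mm of range beyond distal PTV edge
    field_taper_factor: float = 2.5         # broad lateral taper sigma / aperture
    alpha_beta_target: float = 6.0
    alpha_beta_normal: float = 2.0
    range_jitter: float = 1.0               # mm sd of per-field R0 jitter
    weight_jitter: float = 0.05             # relative sd of field weights
    noise_sd: float = 0.0                   # relative multiplicative dose noise
    group: str = "brain-like"

    @property
    def body_center(self) -> np.ndarray:
        return 0.5 * self.spacing * np.asarray(self.grid_shape, dtype=float)

    @property
    def ptv_center(self) -> np.ndarray:
        return self.body_center + np.asarray(self.ptv_offset, dtype=float)


@dataclass
class PhantomCase:
    """One synthetic patient: grids, structures, plan, and provenance."""

    config: PhantomConfig
    plan: PlanSpec
    per_field_dose: list[VoxelGrid]
    per_field_letd: list[VoxelGrid]
    hu_grid: VoxelGrid
    structures: dict[str, Structure]
    seed: int
    iso_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm
    range_scale: float = 1.0   # cumulative (1 -/+ hu_scale) range factor
    case_id: str = "case"

    @property
    def total_dose(self) -> VoxelGrid:
        total = sum(g.data for g in self.per_field_dose)
        return self.per_field_dose[0].copy_with(total)


def _voxel_center_arrays(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * config.spacing for n in config.grid_shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def _box_mask(
    centers: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: np.ndarray,
    half_size: tuple[float, float, float],
) -> np.ndarray:
    X, Y, Z = centers
    return (
        (np.abs(X - center[0]) <= half_size[0])
        & (np.abs(Y - center[1]) <= half_size[1])
        & (np.abs(Z - center[2]) <= half_size[2])
    )


def build_structures(config: PhantomConfig) -> dict[str, Structure]:
    """Body, PTV, CTV (PTV eroded by the margin) and the two OAR slabs."""
    centers = _voxel_center_arrays(config)
    X, Y, Z = centers
    c_body = config.body_center
    body = (X - c_body[0]) ** 2 + (Y - c_body[1]) ** 2 + (Z - c_body[2]) ** 2 <= config.body_radius**2
    c_ptv = config.ptv_center
    dist2 = (X - c_ptv[0]) ** 2 + (Y - c_ptv[1]) ** 2 + (Z - c_ptv[2]) ** 2
    ptv = dist2 <= config.ptv_radius**2
    # CTV: erode the PTV mask by the safety margin (distance-to-background)
    edt = scipy.ndimage.distance_transform_edt(ptv, sampling=config.spacing)
    ctv = edt >= config.ctv_margin

    bs_center = c_ptv.copy()
    bs_center[0] += config.ptv_radius + config.oar_gap + config.brainstem_half_size[0]
    brainstem = _box_mask(centers, bs_center, config.brainstem_half_size) & body

    ch_center = c_ptv.copy()
    ch_center[1] += config.ptv_radius + config.oar_gap + config.chiasm_half_size[1]
    chiasm = _box_mask(centers, ch_center, config.chiasm_half_size) & body

    structures = {
        "body": Structure("body", body, kind="body"),
        "ptv": Structure("ptv", ptv, kind="target"),
        "ctv": Structure("ctv", ctv, kind="target"),
        "brainstem": Structure("brainstem", brainstem, kind="oar", constraint_dmax=54.0),
        "chiasm": Structure("chiasm", chiasm, kind="oar", constraint_dmax=54.0),
    }
    for name, s in structures.items():
        if s.n_voxels == 0:
            raise ValueError(f"structure {name!r} falls outside the grid or body")
    if not (ptv <= body).all():
        raise ValueError("PTV extends outside the body")
    return structures


def _sobp_zgrid(r0: float) -> np.ndarray:
    return np.arange(0.0, r0 + 3.0 + 0.05, 0.05)


def _n_peaks_for(r0: float, m: float) -> int:
    """Peak count so that peak spacing stays below ~1.3 range-spread sigmas."""
    sigma = bragg.default_sigma(r0)
    return max(8, math.ceil(m / (1.3 * sigma)) + 1)


def trace_field(
    fld: BeamField,
    config: PhantomConfig,
    iso_shift: np.ndarray,
    range_scale: float,
    centers: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    body_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dose (Gy per unit weight) and LET_d (keV/um) arrays for one field."""
    if centers is None:
        centers = _voxel_center_arrays(config)
    X, Y, Z = centers
    d = fld.direction
    c_body = config.body_center
    qx, qy, qz = X - c_body[0], Y - c_body[1], Z - c_body[2]
    t = qx * d[0] + qy * d[1] + qz * d[2]
    rho2 = qx**2 + qy**2 + qz**2 - t**2
    if body_mask is None:
        body_mask = rho2 + t**2 <= config.body_radius**2
    # water-equivalent depth from body entry along the ray through each voxel
    chord = np.sqrt(np.maximum(config.body_radius**2 - np.minimum(rho2, config.body_radius**2), 0.0))
    depth_cm = np.where(body_mask, (t + chord) / 10.0, np.inf)

    r0_eff = fld.nominal_range * range_scale
    zgrid = _sobp_zgrid(r0_eff)
    dose_curve, let_curve = bragg.sobp_depth_curves(
        r0_eff, fld.modulation, fld.n_peaks, zgrid
    )
    depth_flat = depth_cm.ravel()
    dose = np.interp(depth_flat, zgrid, dose_curve, left=0.0, right=0.0).reshape(depth_cm.shape)
    letd = np.interp(depth_flat, zgrid, let_curve, left=0.0, right=0.0).reshape(depth_cm.shape)

    # lateral flat-top + Gaussian penumbra around the (possibly shifted) axis
    iso = config.ptv_center + np.asarray(iso_shift, dtype=float)
    rx, ry, rz = X - iso[0], Y - iso[1], Z - iso[2]
    along = rx * d[0] + ry * d[1] + rz * d[2]
    lat = np.sqrt(np.maximum(rx**2 + ry**2 + rz**2 - along**2, 0.0))
    excess = np.maximum(lat - fld.aperture_radius, 0.0)
    fluence = np.exp(-0.5 * (excess / fld.lateral_sigma) ** 2)
    # mild broad taper: keeps each field's maximum on-axis (inside the PTV)
    taper_sigma = config.field_taper_factor * fld.aperture_radius
    fluence = fluence * np.exp(-0.5 * (lat / taper_sigma) ** 2)

    dose = fld.weight * dose * fluence * body_mask
    letd = np.where(dose > 0, letd, 0.0)
    return dose, letd


def generate_case(
    config: PhantomConfig, seed: int, case_id: str | None = None
) -> PhantomCase:
    """Generate and normalise one synthetic case; deterministic given seed."""
    rng = np.random.default_rng(seed)
    structures = build_structures(config)
    centers = _voxel_center_arrays(config)
    body_mask = structures["body"].mask

    # per-field geometry: range reaches the distal PTV edge (plus margin),
    # modulation spans the PTV diameter (plus margins both sides)
    c_body = config.body_center
    iso = config.ptv_center
    fields: list[BeamField] = []
    # modulation spans the PTV diameter; the range margin shifts the plateau
    # distally so the well-fitted flat region sits inside the PTV on axis
    m_cm = 2.0 * config.ptv_radius / 10.0
    for angle in config.gantry_angles:
        d = np.array([math.sin(math.radians(angle)), -math.cos(math.radians(angle)), 0.0])
        t_iso = float((iso - c_body) @ d)
        rho2 = float(((iso - c_body) @ (iso - c_body)) - t_iso**2)
        depth_iso_mm = t_iso + math.sqrt(max(config.body_radius**2 - rho2, 0.0))
        r0_mm = depth_iso_mm + config.ptv_radius + config.distal_margin
        r0_mm += rng.normal(0.0, config.range_jitter)
        r0_cm = r0_mm / 10.0
        weight = max(1.0 + rng.normal(0.0, config.weight_jitter), 0.1)
        fields.append(
            BeamField(
                gantry_angle=angle,
                nominal_range=r0_cm,
                modulation=min(m_cm, r0_cm),
                lateral_sigma=config.lateral_sigma,
                weight=weight,
                aperture_radius=config.ptv_radius + config.aperture_margin,
                n_peaks=_n_peaks_for(r0_cm, min(m_cm, r0_cm)),
            )
        )

    plan = PlanSpec(
        prescribed_dose=config.prescribed_dose,
        n_fractions=config.n_fractions,
        fields=fields,
        isocenter=iso,
        alpha_beta_target=config.alpha_beta_target,
        alpha_beta_normal=config.alpha_beta_normal,
    )
    hu = VoxelGrid(np.where(body_mask, 0.0, -1000.0), spacing=config.spacing)
    case = PhantomCase(
        config=config,
        plan=plan,
        per_field_dose=[],
        per_field_letd=[],
        hu_grid=hu,
        structures=structures,
        seed=seed,
        case_id=case_id or f"case-{seed}",
    )
    _retrace(case, centers=centers, body_mask=body_mask)
    normalize_plan(case, centers=centers, body_mask=body_mask)
    if config.noise_sd > 0:
        # optional multiplicative dose noise, seeded from the case seed
        for g in case.per_field_dose:
            noisy = g.data * (1.0 + config.noise_sd * rng.standard_normal(g.shape))
            g.data = np.maximum(noisy, 0.0)
    return case


def _retrace(
    case: PhantomCase,
    centers: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    body_mask: np.ndarray | None = None,
) -> None:
    """Recompute per-field dose and LET grids from the current plan state."""
    config = case.config
    if centers is None:
        centers = _voxel_center_arrays(config)
    if body_mask is None:
        body_mask = case.structures["body"].mask
    doses, lets = [], []
    for fld in case.plan.fields:
        dose, letd = trace_field(
            fld, config, case.iso_shift, case.range_scale, centers, body_mask
        )
        doses.append(VoxelGrid(dose, spacing=config.spacing))
        lets.append(VoxelGrid(letd, spacing=config.spacing))
    case.per_field_dose = doses
    case.per_field_letd = lets


def normalize_plan(
    case: PhantomCase,
    centers: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    body_mask: np.ndarray | None = None,
) -> PhantomCase:
    """Rescale field weights so median(1.1 x D_phys | PTV) equals D_p.

    One global factor is applied to every field weight and the grids are
    retraced, so a plan already normalised (or pre-scaled by any constant) is
    reproduced exactly.
    """
    ptv = case.structures["ptv"]
    if ptv.n_voxels == 0:
        raise ValueError("PTV is empty; cannot normalise")
    total = case.total_dose.data[ptv.mask]
    med = float(np.median(CONSTANT_RBE * total))
    if med <= 0:
        raise ValueError("no dose in PTV; cannot normalise")
    factor = case.plan.prescribed_dose / med
    for fld in case.plan.fields:
        fld.weight *= factor
    _retrace(case, centers=centers, body_mask=body_mask)
    return case


def apply_scenario(case: PhantomCase, scenario) -> PhantomCase:
    """Perturbed copy of the case under a robustness scenario.

    The isocenter shift translates the beam geometry (the lateral fluence
    axes) rigidly; the HU perturbation rescales every field's water-
    equivalent range by ``(1 - hu_scale)`` (HU up -> stopping power up ->
    range down).  Dose and LET grids are recomputed; field weights (hence
    beam output) are left at their planned values.
    """
    hu = float(getattr(scenario, "hu_scale", 0.0))
    shift = np.asarray(getattr(scenario, "iso_shift", (0.0, 0.0, 0.0)), dtype=float)
    new = PhantomCase(
        config=case.config,
        plan=replace(
            case.plan,
            fields=[replace(f) for f in case.plan.fields],
            isocenter=case.plan.isocenter.copy(),
        ),
        per_field_dose=[],
        per_field_letd=[],
        hu_grid=case.hu_grid,
        structures=case.structures,
        seed=case.seed,
        iso_shift=case.iso_shift + shift,
        range_scale=case.range_scale * (1.0 - hu),
        case_id=case.case_id,
    )
    _retrace(new)
    return new


# ---------------------------------------------------------------------------
# cohort sampling: the two tumour-site groups of the study conditions
# ---------------------------------------------------------------------------

def sample_case_config(group: str, rng: np.random.Generator) -> PhantomConfig:
    """Draw one case's geometry/prescription from its group's distributions.

    brain-like: alpha/beta 6 Gy, prescriptions 36-61.2 Gy(RBE) at 1.8-2.0
    Gy(RBE)/fraction (median 54), 2-4 fields, larger targets.
    skullbase-like: alpha/beta 4 Gy, prescriptions 70-74 Gy(RBE), 2-6 fields,
    smaller targets.
    """
    if group == "brain-like":
        d_fx = float(rng.choice([1.8, 2.0]))
        n_fx = int(rng.integers(20, 31))
        d_p = min(max(d_fx * n_fx, 36.0), 61.2)
        n_fx = round(d_p / d_fx)
        ptv_radius = float(rng.uniform(17.0, 27.0))
        n_fields = int(rng.choice([2, 3, 3, 4]))
        ab_target = 6.0
    elif group == "skullbase-like":
        d_fx = 2.0
        n_fx = int(rng.integers(35, 38))
        d_p = d_fx * n_fx
        ptv_radius = float(rng.uniform(12.0, 20.0))
        n_fields = int(rng.choice([2, 3, 4, 4, 5, 6]))
        ab_target = 4.0
    else:
        raise ValueError(f"unknown group {group!r}")
    # one field aimed so its distal edge faces the brainstem slab (+x); the
    # rest alternate between the two opposing lateral windows, the usual
    # clinical arrangement of fields around the target
    angles = [float(rng.uniform(70.0, 110.0))]
    for i in range(n_fields - 1):
        lo, hi = (240.0, 300.0) if i % 2 == 0 else (60.0, 120.0)
        angles.append(float(rng.uniform(lo, hi)))
    return PhantomConfig(
        ptv_radius=ptv_radius,
        prescribed_dose=d_p,
        n_fractions=n_fx,
        gantry_angles=tuple(angles),
        alpha_beta_target=ab_target,
        group=group,
    )


def sample_cohort(
    n_brain: int, n_skullbase: int, seed: int
) -> list[tuple[str, str, PhantomConfig, int]]:
    """(case_id, group, config, case_seed) tuples for a two-group cohort."""
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_brain):
        cfg = sample_case_config("brain-like", rng)
        cohort.append((f"brain-{i + 1:02d}", "brain-like", cfg, int(rng.integers(2**31 - 1))))
    for i in range(n_skullbase):
        cfg = sample_case_config("skullbase-like", rng)
        cohort.append(
            (f"skullbase-{i + 1:02d}", "skullbase-like", cfg, int(rng.integers(2**31 - 1)))
        )
    return cohort
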