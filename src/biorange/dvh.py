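"""Cumulative dose-volume histograms, DVH indices and constraint checks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid

log = logging.getLogger(__name__)

#: Clinical maximum-dose constraints, Gy(RBE).  The brainstem is analysed as
#: a whole structure against both its core and surface limits.
DEFAULT_CONSTRAINTS: dict[str, float] = {
    "brainstem_core": 54.0,
    "brainstem_surface": 64.0,
    "chiasm": 54.0,
}

DEFAULT_BIN_WIDTH = 0.1  # Gy


@dataclass
class Structure:
    """A named structure mask on the dose lattice."""

    name: str
    mask: np.ndarray
    kind: str = "oar"  # target | oar | body
    constraint_dmax: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DVHCurve:
    dose_bins: np.ndarray            # left edges, Gy
    cum_volume_fraction: np.ndarray  # fraction of volume receiving >= edge dose

    def volume_at(self, dose: float) -> float:
        """Fraction of the structure receiving at least ``dose`` Gy."""
        idx = np.searchsorted(self.dose_bins, dose, side="right") - 1
        if idx < 0:
            return 1.0
        if idx >= len(self.cum_volume_fraction):
            return 0.0
        return float(self.cum_volume_fraction[idx])


@dataclass
class DVHIndices:
    dmax: float
    dmean: float
    d95: float
    d05: float
    dmean_over_dp_pct: float | None = None


def _structure_doses(dose: VoxelGrid, structure: Structure) -> np.ndarray:
    if structure.n_voxels == 0:
        raise ValueError(f"structure {structure.name!r} is empty")
    if structure.mask.shape != dose.shape:
        raise ValueError("structure mask is not on the dose lattice")
    return dose.data[structure.mask]


def dvh(dose: VoxelGrid, structure: Structure, bin_width: float = DEFAULT_BIN_WIDTH) -> DVHCurve:
    """Cumulative (>= dose) DVH with uniform voxel-volume weighting."""
    vals = _structure_doses(dose, structure)
    n_bins = int(np.floor(vals.max() / bin_width)) + 2
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(vals, bins=edges)
    cum = np.concatenate(([vals.size], vals.size - np.cumsum(hist)[:-1]))
    return DVHCurve(dose_bins=edges[:-1], cum_volume_fraction=cum / vals.size)


def dose_percentile(dose: VoxelGrid, structure: Structure, x: float) -> float:
    """Dx: the highest dose received by at least x% of the structure volume.

    Computed as the linearly interpolated (100 - x)th percentile of the voxel
    doses, which agrees with the exhaustive nearest-rank search within one
    voxel-dose gap.
    """
    if not (0 < x < 100):
        raise ValueError("percent coverage must lie strictly between 0 and 100")
    vals = _structure_doses(dose, structure)
    return float(np.percentile(vals, 100.0 - x))


def indices(dose: VoxelGrid, structure: Structure, prescribed_dose: float | None = None) -> DVHIndices:
    """Dmax, Dmean, D95, D05 for one structure (+ Dmean/D_p ratio in %)."""
    vals = _structure_doses(dose, structure)
    ratio = None
    if prescribed_dose is not None:
        if prescribed_dose <= 0:
            raise ValueError("prescribed dose must be positive")
        ratio = 100.0 * float(vals.mean()) / prescribed_dose
    return DVHIndices(
        dmax=float(vals.max()),
        dmean=float(vals.mean()),
        d95=dose_percentile(dose, structure, 95.0),
        d05=dose_percentile(dose, structure, 5.0),
        dmean_over_dp_pct=ratio,
    )


def v95_volume(dose: VoxelGrid, body: Structure | None, prescribed_dose: float) -> float:
    """Volume (cm^3) receiving at least 95% of the prescription.

    Evaluated over the body mask by default; pass ``body=None`` for the whole
    grid.
    """
    if prescribed_dose <= 0:
        raise ValueError("prescribed dose must be positive")
    sel = dose.data >= 0.95 * prescribed_dose
    if body is not None:
        sel = sel & body.mask
    return float(sel.sum()) * dose.voxel_volume_cm3


@dataclass
class ConstraintResult:
    structure: str
    constraint: float
    dmax: float
    exceedance: float  # Gy(RBE) above the limit, clipped at 0
    exceeded: bool


def constraint_check(
    dmax_by_structure: dict[str, float],
    constraints: dict[str, float] | None = None,
) -> list[ConstraintResult]:
    """Exceedance of Dmax limits per structure.

    ``dmax_by_structure`` maps constraint names (e.g. ``brainstem_core``,
    ``brainstem_surface`` — both evaluated on the whole brainstem Dmax) to the
    observed maximum dose.  Structures without a constraint are skipped with a
    log entry.
    """
    constraints = DEFAULT_CONSTRAINTS if constraints is None else constraints
    results = []
    for name, dmax in dmax_by_structure.items():
        limit = constraints.get(name)
        if limit is None:
            log.info("no dose constraint for structure %r; skipped", name)
            continue
        exceed = max(0.0, dmax - limit)
        results.append(
            ConstraintResult(
                structure=name,
                constraint=limit,
                dmax=dmax,
                exceedance=exceed,
                exceeded=exceed > 0,
            )
        )
    return results
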