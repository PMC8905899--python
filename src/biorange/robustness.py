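"""Clinical robustness scenarios and vRBE-vs-robustness difference metrics.

The clinical robustness protocol perturbs each plan 12 ways: CT Hounsfield
units scaled by +/-3.5% (proton range down/up) crossed with a +/-2 mm
isocenter translation along each axis.  Every scenario is recalculated under
the constant-RBE weighting, exactly as done clinically; the spread of the
resulting DVHs is then compared with the shift caused by switching the
nominal plan from cRBE to the McNamara vRBE weighting:

    CTV_diffRobust = D95_cRBE - min(D95)_robust
    CTV_diffRBE    = D95_vRBE - D95_cRBE
    OAR_diffRobust = max(D05)_robust - D05_cRBE
    OAR_diffRBE    = D05_vRBE - D05_cRBE
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import letrbe
from .dvh import DVHCurve, Structure, dose_percentile, dvh
from .grid import VoxelGrid

HU_SCALE = 0.035
ISO_SHIFT_MM = 2.0


@dataclass(frozen=True)
class RobustnessScenario:
    hu_scale: float                       # signed fraction, +/-0.035
    iso_shift: tuple[float, float, float]  # mm, one nonzero axis
    id: str = ""


@dataclass
class RobustnessBand:
    """Bin-wise min/max envelope of per-scenario DVH curves, per structure."""

    structure: str
    dose_bins: np.ndarray
    envelope_min: np.ndarray
    envelope_max: np.ndarray
    nominal: np.ndarray
    scenario_ids: list[str] = field(default_factory=list)


def make_scenarios(additive: bool = False) -> list[RobustnessScenario]:
    """The perturbation-scenario set.

    Default (cartesian) composition: {+3.5%, -3.5%} HU x {+/-2 mm in X, Y, Z}
    = 12 scenarios, the clinical protocol.  ``additive=True`` returns the
    8-scenario reading instead (2 pure HU cases + 6 pure shifts).
    """
    shifts = []
    for axis, label in enumerate("xyz"):
        for sign in (+1.0, -1.0):
            vec = [0.0, 0.0, 0.0]
            vec[axis] = sign * ISO_SHIFT_MM
            shifts.append((tuple(vec), f"{'+' if sign > 0 else '-'}{label}"))
    if additive:
        out = [
            RobustnessScenario(s * HU_SCALE, (0.0, 0.0, 0.0), f"hu{'+' if s > 0 else '-'}")
            for s in (+1.0, -1.0)
        ]
        out += [RobustnessScenario(0.0, vec, f"shift{lab}") for vec, lab in shifts]
        return out
    return [
        RobustnessScenario(s * HU_SCALE, vec, f"hu{'+' if s > 0 else '-'}_shift{lab}")
        for s in (+1.0, -1.0)
        for vec, lab in shifts
    ]


NULL_SCENARIO = RobustnessScenario(0.0, (0.0, 0.0, 0.0), "null")


def _crbe_total(case) -> VoxelGrid:
    total = case.total_dose
    return total.copy_with(letrbe.CONSTANT_RBE * total.data)


def scenario_doses(case, scenarios: list[RobustnessScenario]) -> dict[str, VoxelGrid]:
    """cRBE-weighted total dose grid per scenario (phantom recomputation)."""
    from .phantom import apply_scenario  # local import avoids cycle at import time

    out = {}
    for sc in scenarios:
        out[sc.id or repr(sc)] = _crbe_total(apply_scenario(case, sc))
    return out


def dvh_band(
    case,
    scenarios: list[RobustnessScenario],
    structures: list[Structure],
    bin_width: float = 0.1,
    scenario_dose: dict[str, VoxelGrid] | None = None,
) -> dict[str, RobustnessBand]:
    """Min/max DVH envelopes over scenarios, with the nominal cRBE curve.

    ``scenario_dose`` may supply externally computed per-scenario cRBE dose
    grids (keyed by scenario id); missing ids raise.  Otherwise the phantom
    model recomputes each scenario.
    """
    if scenario_dose is None:
        scenario_dose = scenario_doses(case, scenarios)
    else:
        missing = [sc.id for sc in scenarios if sc.id not in scenario_dose]
        if missing:
            raise ValueError(f"missing scenario dose grids for ids: {missing}")
    nominal = _crbe_total(case)
    ids = [sc.id for sc in scenarios]
    max_dose = max(g.data.max() for g in scenario_dose.values())
    max_dose = max(max_dose, nominal.data.max())
    n_bins = int(np.floor(max_dose / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    bands = {}
    for s in structures:
        curves = []
        for sid in ids:
            c = dvh(scenario_dose[sid], s, bin_width)
            padded = np.zeros(n_bins)
            padded[: len(c.cum_volume_fraction)] = c.cum_volume_fraction
            curves.append(padded)
        curves = np.array(curves)
        nom = dvh(nominal, s, bin_width)
        nom_padded = np.zeros(n_bins)
        nom_padded[: len(nom.cum_volume_fraction)] = nom.cum_volume_fraction
        bands[s.name] = RobustnessBand(
            structure=s.name,
            dose_bins=edges,
            envelope_min=curves.min(axis=0),
            envelope_max=curves.max(axis=0),
            nominal=nom_padded,
            scenario_ids=list(ids),
        )
    return bands


def diff_metrics(
    nominal_crbe: VoxelGrid,
    vrbe: VoxelGrid,
    scenario_dose: dict[str, VoxelGrid],
    ctv: Structure,
    oars: list[Structure],
) -> dict[str, float]:
    """The four robustness-vs-RBE difference scalars for one case.

    CTV metrics use D95, OAR metrics use D05 (one pair per OAR, keyed
    ``oar_diff_robust[name]`` style).  Scenario order is irrelevant.
    """
    if not scenario_dose:
        raise ValueError("no scenario dose grids supplied")
    d95_nom = dose_percentile(nominal_crbe, ctv, 95.0)
    d95_v = dose_percentile(vrbe, ctv, 95.0)
    d95_sc = [dose_percentile(g, ctv, 95.0) for g in scenario_dose.values()]
    out: dict[str, float] = {
        "ctv_diff_robust": d95_nom - min(d95_sc),
        "ctv_diff_rbe": d95_v - d95_nom,
    }
    for oar in oars:
        d05_nom = dose_percentile(nominal_crbe, oar, 5.0)
        d05_v = dose_percentile(vrbe, oar, 5.0)
        d05_sc = [dose_percentile(g, oar, 5.0) for g in scenario_dose.values()]
        out[f"oar_diff_robust_{oar.name}"] = max(d05_sc) - d05_nom
        out[f"oar_diff_rbe_{oar.name}"] = d05_v - d05_nom
    return out
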