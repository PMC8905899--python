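"""Per-case evaluation and cohort orchestration.

Ties the stages together: phantom simulation -> plan LET_d -> cRBE/vRBE
weighted dose -> DVH indices, V95, constraint checks, RBE map statistics ->
equivalent-sphere range extension -> (optionally) robustness scenarios.
Everything here is pure computation over in-memory cases; the analysis
scripts and the acceptance harness are thin callers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dvh as dvh_mod
from . import letrbe, phantom, rangeext, robustness


def evaluate_case(case: phantom.PhantomCase) -> dict:
    """All nominal-plan metrics for one case, under both RBE weightings."""
    cfg = case.config
    plan = case.plan
    total = case.total_dose
    letd = letrbe.combine_letd(case.per_field_dose, case.per_field_letd)
    ptv = case.structures["ptv"]
    body = case.structures["body"]

    crbe = letrbe.dose_rbe(total, None, None, plan.n_fractions, "cRBE")
    vrbe = letrbe.dose_rbe(
        total,
        letd,
        ptv.mask,
        plan.n_fractions,
        "vRBE-McNamara",
        alpha_beta_target=plan.alpha_beta_target,
        alpha_beta_normal=plan.alpha_beta_normal,
    )

    d_p = plan.prescribed_dose
    result: dict = {
        "case_id": case.case_id,
        "group": cfg.group,
        "prescribed_dose": d_p,
        "n_fractions": plan.n_fractions,
        "alpha_beta_target": plan.alpha_beta_target,
        "indices": {},
        "v95": {},
        "dose": {"cRBE": crbe, "vRBE": vrbe},
        "letd": letd,
    }
    analysed = ["ptv", "ctv", "brainstem", "chiasm"]
    for model, weighted in (("cRBE", crbe), ("vRBE", vrbe)):
        per_struct = {
            name: dvh_mod.indices(weighted.dose, case.structures[name], d_p)
            for name in analysed
        }
        result["indices"][model] = per_struct
        result["v95"][model] = dvh_mod.v95_volume(weighted.dose, body, d_p)
        dmax_map = {
            "brainstem_core": per_struct["brainstem"].dmax,
            "brainstem_surface": per_struct["brainstem"].dmax,
            "chiasm": per_struct["chiasm"].dmax,
        }
        result.setdefault("constraints", {})[model] = dvh_mod.constraint_check(dmax_map)

    result["range_extension"] = rangeext.biological_range_extension(
        result["v95"]["cRBE"], result["v95"]["vRBE"]
    )
    result["rbe_stats"] = letrbe.rbe_map_stats(
        vrbe.rbe,
        vrbe.dose,
        d_p,
        {name: case.structures[name].mask for name in analysed},
    )
    return result


def case_metric_rows(result: dict) -> list[dict]:
    """Tidy per-(case, model) metric rows for the cohort table."""
    rows = []
    for model in ("cRBE", "vRBE"):
        ptv_idx = result["indices"][model]["ptv"]
        row = {
            "case_id": result["case_id"],
            "group": result["group"],
            "model": model,
            "dmean_over_dp_pct": ptv_idx.dmean_over_dp_pct,
            "d95": ptv_idx.d95,
            "d05": ptv_idx.d05,
            "dmax_ptv": ptv_idx.dmax,
            "v95_cm3": result["v95"][model],
        }
        for oar in ("brainstem", "chiasm"):
            row[f"dmax_{oar}"] = result["indices"][model][oar].dmax
            row[f"d05_{oar}"] = result["indices"][model][oar].d05
        for c in result["constraints"][model]:
            row[f"exceedance_{c.structure}"] = c.exceedance
        rows.append(row)
    return rows


def run_cohort(
    n_brain: int = 10,
    n_skullbase: int = 10,
    seed: int = 1,
    keep_cases: bool = False,
) -> dict:
    """Generate and evaluate a two-group cohort.

    Returns a dict with the tidy ``metrics`` table (one row per case and
    model), the per-case ``rangeext_table`` and per-group ``rangeext_summary``,
    a ``rbe_stats`` table, and (if ``keep_cases``) the generated cases for
    downstream robustness analysis.
    """
    cohort = phantom.sample_cohort(n_brain, n_skullbase, seed)
    rows: list[dict] = []
    re_cases: list[dict] = []
    rbe_rows: list[dict] = []
    cases: list[phantom.PhantomCase] = []
    results: list[dict] = []
    for case_id, group, cfg, case_seed in cohort:
        case = phantom.generate_case(cfg, case_seed, case_id=case_id)
        res = evaluate_case(case)
        rows.extend(case_metric_rows(res))
        re_cases.append(
            {
                "case_id": case_id,
                "group": group,
                "v95_crbe": res["v95"]["cRBE"],
                "v95_vrbe": res["v95"]["vRBE"],
            }
        )
        for struct, s in res["rbe_stats"].items():
            rbe_rows.append({"case_id": case_id, "group": group, "structure": struct, **s})
        if keep_cases:
            cases.append(case)
            results.append(res)
    re_table, re_summary = rangeext.cohort_range_extension(re_cases)
    out = {
        "metrics": pd.DataFrame(rows),
        "rangeext_table": re_table,
        "rangeext_summary": re_summary,
        "rbe_stats": pd.DataFrame(rbe_rows),
    }
    if keep_cases:
        out["cases"] = cases
        out["results"] = results
    return out


def case_robustness(
    case: phantom.PhantomCase,
    result: dict | None = None,
    additive: bool = False,
) -> dict:
    """Scenario set, cRBE scenario doses and the four diff metrics for a case."""
    if result is None:
        result = evaluate_case(case)
    scenarios = robustness.make_scenarios(additive=additive)
    scen_dose = robustness.scenario_doses(case, scenarios)
    metrics = robustness.diff_metrics(
        result["dose"]["cRBE"].dose,
        result["dose"]["vRBE"].dose,
        scen_dose,
        ctv=case.structures["ctv"],
        oars=[case.structures["brainstem"], case.structures["chiasm"]],
    )
    return {
        "case_id": case.case_id,
        "group": case.config.group,
        "scenarios": scenarios,
        "scenario_dose": scen_dose,
        "diff_metrics": metrics,
    }
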