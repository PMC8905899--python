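"""Case persistence (NIfTI grids + JSON manifest) and the end-to-end runner.

A case directory holds one ``.nii.gz`` per grid (per-field dose and LET_d,
HU, one uint8 mask per structure) and ``case.json`` with the plan,
provenance and file manifest.  The NIfTI affine is diagonal (LPS, no oblique
grids) with the voxel-center origin convention of :mod:`biorange.grid`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import pipeline, stats
from .dvh import Structure
from .grid import VoxelGrid
from .phantom import BeamField, PhantomCase, PhantomConfig, PlanSpec


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag([grid.spacing] * 3 + [1.0])
    aff[:3, 3] = grid.origin + 0.5 * grid.spacing
    return aff


def _save_grid(grid: VoxelGrid, path: Path, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=dtype), _affine(grid))
    nib.save(img, str(path))


def _load_grid(path: Path) -> VoxelGrid:
    img = nib.load(str(path))
    aff = img.affine
    spacing = float(aff[0, 0])
    origin = aff[:3, 3] - 0.5 * spacing
    return VoxelGrid(np.asarray(img.dataobj, dtype=float), spacing=spacing, origin=origin)


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Persist a case; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "case_id": case.case_id,
        "seed": case.seed,
        "iso_shift_mm": list(np.asarray(case.iso_shift, dtype=float)),
        "range_scale": case.range_scale,
        "spacing_mm": case.config.spacing,
        "grid_shape": list(case.config.grid_shape),
        "config": dataclasses.asdict(case.config),
        "plan": {
            "prescribed_dose": case.plan.prescribed_dose,
            "n_fractions": case.plan.n_fractions,
            "isocenter_mm": list(case.plan.isocenter),
            "alpha_beta_target": case.plan.alpha_beta_target,
            "alpha_beta_normal": case.plan.alpha_beta_normal,
            "fields": [dataclasses.asdict(f) for f in case.plan.fields],
        },
        "files": {"hu": "hu.nii.gz", "dose": [], "letd": [], "masks": {}},
    }
    _save_grid(case.hu_grid, out / "hu.nii.gz", np.float32)
    for i, (d, l) in enumerate(zip(case.per_field_dose, case.per_field_letd)):
        dname, lname = f"dose_f{i}.nii.gz", f"letd_f{i}.nii.gz"
        _save_grid(d, out / dname, np.float32)
        _save_grid(l, out / lname, np.float32)
        manifest["files"]["dose"].append(dname)
        manifest["files"]["letd"].append(lname)
    for name, s in case.structures.items():
        mname = f"mask_{name}.nii.gz"
        grid = VoxelGrid(s.mask.astype(np.uint8), spacing=case.config.spacing)
        _save_grid(grid, out / mname, np.uint8)
        manifest["files"]["masks"][name] = {
            "file": mname,
            "kind": s.kind,
            "constraint_dmax": s.constraint_dmax,
        }
    path = out / "case.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_case(case_dir: str | Path) -> PhantomCase:
    """Load a case directory written by :func:`write_case`.

    Validates that every referenced grid exists and shares the lattice;
    raises naming the offending file otherwise.
    """
    case_dir = Path(case_dir)
    manifest = json.loads((case_dir / "case.json").read_text())
    cfg_dict = dict(manifest["config"])
    for key in ("grid_shape", "ptv_offset", "brainstem_half_size", "chiasm_half_size",
                "gantry_angles"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    config = PhantomConfig(**cfg_dict)
    plan_d = manifest["plan"]
    plan = PlanSpec(
        prescribed_dose=plan_d["prescribed_dose"],
        n_fractions=plan_d["n_fractions"],
        fields=[BeamField(**f) for f in plan_d["fields"]],
        isocenter=np.asarray(plan_d["isocenter_mm"]),
        alpha_beta_target=plan_d["alpha_beta_target"],
        alpha_beta_normal=plan_d["alpha_beta_normal"],
    )

    def load_checked(fname: str) -> VoxelGrid:
        path = case_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing grid file {fname!r}")
        g = _load_grid(path)
        if tuple(g.shape) != tuple(manifest["grid_shape"]) or abs(
            g.spacing - manifest["spacing_mm"]
        ) > 1e-6:
            raise ValueError(f"grid file {fname!r} does not match the case lattice")
        return g

    hu = load_checked(manifest["files"]["hu"])
    doses = [load_checked(f) for f in manifest["files"]["dose"]]
    lets = [load_checked(f) for f in manifest["files"]["letd"]]
    if len(doses) != len(lets):
        raise ValueError("per-field dose/LET file counts differ")
    structures = {}
    for name, rec in manifest["files"]["masks"].items():
        g = load_checked(rec["file"])
        structures[name] = Structure(
            name, g.data > 0.5, kind=rec["kind"], constraint_dmax=rec["constraint_dmax"]
        )
    return PhantomCase(
        config=config,
        plan=plan,
        per_field_dose=doses,
        per_field_letd=lets,
        hu_grid=hu,
        structures=structures,
        seed=manifest["seed"],
        iso_shift=np.asarray(manifest["iso_shift_mm"], dtype=float),
        range_scale=manifest["range_scale"],
        case_id=manifest["case_id"],
    )


def run_pipeline(
    out_dir: str | Path,
    n_brain: int = 10,
    n_skullbase: int = 10,
    seed: int = 1,
    n_boot: int = stats.DEFAULT_N_BOOT,
    robustness_cases: int = 0,
    resume: bool = False,
) -> dict:
    """Simulate -> evaluate -> DVH/rangeext -> (robustness) -> report.

    Writes all cohort tables (CSV) and the statistical report (CSV + JSON)
    under ``out_dir``.  Deterministic given the configuration and seed; with
    ``resume=True`` stages whose output files already exist are skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out / "cohort_metrics.csv",
        "rangeext": out / "range_extension.csv",
        "report": out / "cohort_report.csv",
        "summary": out / "summary.json",
    }
    import pandas as pd

    if resume and all(p.exists() for p in paths.values()):
        return {k: (pd.read_csv(p) if p.suffix == ".csv" else json.loads(p.read_text()))
                for k, p in paths.items()}

    cohort = pipeline.run_cohort(
        n_brain, n_skullbase, seed, keep_cases=robustness_cases > 0
    )
    cohort["metrics"].to_csv(paths["metrics"], index=False)
    cohort["rangeext_table"].to_csv(paths["rangeext"], index=False)
    report = stats.cohort_report(cohort["metrics"], n_boot=n_boot, seed=seed)
    report.to_csv(paths["report"], index=False)

    robust_rows = []
    if robustness_cases > 0:
        picked = [
            c for group in ("brain-like", "skullbase-like")
            for c in [x for x in cohort["cases"] if x.config.group == group][:robustness_cases]
        ]
        res_by_id = {r["case_id"]: r for r in cohort["results"]}
        for case in picked:
            rb = pipeline.case_robustness(case, res_by_id[case.case_id])
            robust_rows.append(
                {"case_id": case.case_id, "group": case.config.group, **rb["diff_metrics"]}
            )
        pd.DataFrame(robust_rows).to_csv(out / "robustness_diff_metrics.csv", index=False)

    summary = {
        "seed": seed,
        "n_brain": n_brain,
        "n_skullbase": n_skullbase,
        "n_boot": n_boot,
        "rangeext_summary": cohort["rangeext_summary"],
        "note": "raw p-values, no multiple-testing correction",
    }
    paths["summary"].write_text(json.dumps(summary, indent=2))
    out_dict = {
        "metrics": cohort["metrics"],
        "rangeext": cohort["rangeext_table"],
        "rangeext_summary": cohort["rangeext_summary"],
        "report": report,
        "rbe_stats": cohort["rbe_stats"],
    }
    if robust_rows:
        out_dict["robustness"] = pd.DataFrame(robust_rows)
    return out_dict
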