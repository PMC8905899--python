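#!/usr/bin/env python
"""Robustness scenarios versus the vRBE effect for a cohort subset.

Recomputes the first 3 cases of each group under the 12 clinical
perturbation scenarios (+/-3.5% HU x +/-2 mm per axis, cRBE weighting),
derives the DVH uncertainty bands, and compares the robustness spread with
the cRBE->vRBE shift through the four D95/D05 difference metrics.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from biorange import phantom, pipeline, robustness

SEED = 1
PER_GROUP = 3
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = phantom.sample_cohort(10, 10, SEED)
    picked = [c for g in ("brain-like", "skullbase-like")
              for c in [x for x in cohort if x[1] == g][:PER_GROUP]]
    rows = []
    band_fig_done = False
    figdir = RESULTS / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    for case_id, group, cfg, case_seed in picked:
        case = phantom.generate_case(cfg, case_seed, case_id=case_id)
        res = pipeline.evaluate_case(case)
        rb = pipeline.case_robustness(case, res)
        rows.append({"case_id": case_id, "group": group, **rb["diff_metrics"]})
        if not band_fig_done:
            bands = robustness.dvh_band(
                case, rb["scenarios"],
                [case.structures[s] for s in ("ptv", "brainstem", "chiasm")],
                scenario_dose=rb["scenario_dose"])
            fig, ax = plt.subplots(figsize=(7, 4.5))
            colors = {"ptv": "m", "brainstem": "b", "chiasm": "g"}
            for name, band in bands.items():
                ax.fill_between(band.dose_bins, 100 * band.envelope_min,
                                100 * band.envelope_max, alpha=0.3,
                                color=colors[name])
                ax.plot(band.dose_bins, 100 * band.nominal, color=colors[name],
                        label=f"{name} (cRBE nominal)")
            ax.set_xlabel("dose [Gy(RBE)]")
            ax.set_ylabel("volume [%]")
            ax.legend()
            ax.set_title(f"robustness band, {case_id}")
            fig.tight_layout()
            fig.savefig(figdir / "dvh_robustness_band.png", dpi=120)
            print(f"band figure -> {figdir / 'dvh_robustness_band.png'}")
            band_fig_done = True

    diffs = pd.DataFrame(rows)
    diffs.to_csv(RESULTS / "robustness_diff_metrics.csv", index=False)
    print(diffs.round(2).to_string(index=False))
    print("\nGroup means (Gy(RBE)):")
    print(diffs.groupby("group")[
        ["ctv_diff_robust", "ctv_diff_rbe",
         "oar_diff_robust_brainstem", "oar_diff_rbe_brainstem"]].mean().round(2))
    means = diffs.groupby("group")[["ctv_diff_robust", "ctv_diff_rbe"]].mean()
    if (means["ctv_diff_rbe"] > means["ctv_diff_robust"]).all():
        print("\nThe cRBE->vRBE D95 shift exceeds the robustness spread of "
              "D95 in both groups: the RBE-model uncertainty is of the same "
              "order as (or larger than) setup/calibration uncertainty.")


if __name__ == "__main__":
    sys.exit(main())
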