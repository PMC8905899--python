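"""Cohort statistics: bootstrap CIs around medians, Wilcoxon tests, Pearson r.

No distributional assumption is made on the cohort metrics: confidence
intervals are percentile bootstrap (default 100,000 resamples) around the
median, paired model comparisons use the two-sided Wilcoxon signed-rank test,
and associations are summarised with Pearson's product-moment correlation.
Raw p-values are reported without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

DEFAULT_N_BOOT = 100_000


@dataclass
class StatResult:
    median: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int


def bootstrap_ci_median(
    values: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    ci: float = 95.0,
) -> StatResult:
    """Percentile-bootstrap confidence interval around the median.

    Resamples with replacement ``n_boot`` times and takes the 2.5/97.5
    percentiles (for ci=95) of the bootstrap medians.  Deterministic given
    ``seed``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    n = vals.size
    medians = np.empty(n_boot)
    chunk = max(1, int(2e7 // n))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        medians[start:stop] = np.median(vals[idx], axis=1)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(medians, [alpha, 100.0 - alpha])
    return StatResult(
        median=float(np.median(vals)),
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used for small samples without ties and the tie-corrected
    normal approximation otherwise.  Returns NaN if fewer than 5 nonzero
    differences remain (degenerate comparison).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = y - x
    nz = diffs[diffs != 0]
    if nz.size < 5:
        return float("nan")
    return float(scipy.stats.wilcoxon(nz, alternative="two-sided", zero_method="wilcox").pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN for degenerate inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(x, y).statistic)


def cohort_report(
    metrics: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    ci_metrics: tuple[str, ...] = ("dmean_over_dp_pct", "d95", "d05"),
) -> pd.DataFrame:
    """Per-group, per-model medians with bootstrap CIs and paired tests.

    ``metrics`` is a tidy per-case table with columns ``case_id``, ``group``,
    ``model`` (cRBE/vRBE) and metric columns.  Returns one row per
    (group, metric) with the two models' medians, their bootstrap CIs, and
    the paired Wilcoxon p-value between models.
    """
    rows = []
    sub_seed = np.random.default_rng(seed)
    for (group, metric) in (
        (g, m) for g in sorted(metrics["group"].unique()) for m in ci_metrics
    ):
        gtab = metrics[metrics["group"] == group].pivot_table(
            index="case_id", columns="model", values=metric
        )
        if not {"cRBE", "vRBE"} <= set(gtab.columns):
            continue
        x = gtab["cRBE"].to_numpy()
        y = gtab["vRBE"].to_numpy()
        res_c = bootstrap_ci_median(x, n_boot, int(sub_seed.integers(2**31 - 1)))
        res_v = bootstrap_ci_median(y, n_boot, int(sub_seed.integers(2**31 - 1)))
        rows.append(
            {
                "group": group,
                "metric": metric,
                "n": len(gtab),
                "median_crbe": res_c.median,
                "ci_low_crbe": res_c.ci_low,
                "ci_high_crbe": res_c.ci_high,
                "median_vrbe": res_v.median,
                "ci_low_vrbe": res_v.ci_low,
                "ci_high_vrbe": res_v.ci_high,
                "median_shift": res_v.median - res_c.median,
                "wilcoxon_p": wilcoxon_paired(x, y),
            }
        )
    return pd.DataFrame(rows)
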