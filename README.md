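# biorange

Variable-RBE proton dose analysis: how does replacing the clinical constant
RBE of 1.1 with a LET-dependent (McNamara) model change the RBE-weighted
dose a proton plan delivers?

Proton plans are prescribed assuming a flat relative biological
effectiveness of 1.1, but measured RBE rises steeply with dose-averaged LET
at the Bragg-peak distal falloff — exactly where organs at risk (brainstem,
optic chiasm) sit in brain and skull-base treatments. This package
implements, as a tested pipeline over synthetic multi-field IMPT phantom
cases:

- **dose-averaged LET scoring** per voxel,
  `LET_d = (1/rho) * sum(dE * dE/dx) / sum(dE)`, event-level and
  field-combined;
- **RBE-weighted dose** under cRBE (`1.1 * D_phys`) and the McNamara vRBE
  model, `RBE(d, LET_d, (a/b)_x)` with
  `RBE_max = p0 + p1 LET_d/(a/b)_x`,
  `RBE_min = p2 - p3 sqrt((a/b)_x) LET_d`, evaluated at the fraction dose;
- **DVH indices** (Dmax, Dmean, D95, D05, V95) and OAR constraint checks
  (brainstem core/surface 54/64, chiasm 54 Gy(RBE));
- the **biological range extension** `R_ext = R_vRBE - R_cRBE`, where
  `R = (3 V95 / 4 pi)^(1/3)` is the equivalent-sphere radius of the volume
  receiving at least 95% of the prescription — a volumetric range measure
  that is insensitive to dose inhomogeneity and field arrangement;
- the **clinical robustness protocol** (12 scenarios: +/-3.5% HU x +/-2 mm
  isocenter shifts) and the D95/D05 difference metrics comparing the
  robustness spread with the cRBE -> vRBE shift;
- **cohort statistics**: percentile-bootstrap CIs around medians, paired
  two-sided Wilcoxon tests, Pearson correlations.

The phantom simulator stands in for non-distributable patient data: it
generates two-group cohorts (brain-like, alpha/beta 6 Gy; skull-base-like,
alpha/beta 4 Gy) of spherical targets abutting OAR slabs, irradiated by
analytic SOBP fields with rising distal LET_d on a 1.5 mm lattice. See
`docs/methods.md` for the model and its limits.

## Worked example

```python
from biorange import phantom, pipeline

cfg = phantom.PhantomConfig()           # brain-like case, 54 Gy(RBE) / 27 fx
case = phantom.generate_case(cfg, seed=42)
res = pipeline.evaluate_case(case)

for model in ("cRBE", "vRBE"):
    ptv = res["indices"][model]["ptv"]
    print(model, round(ptv.dmean_over_dp_pct, 2), round(ptv.d95, 2),
          round(res["indices"][model]["brainstem"].dmax, 2),
          round(res["v95"][model], 1))
print("R_ext:", round(res["range_extension"].r_ext, 2), "cm")
```

prints

```
cRBE 99.87 52.51 49.13 70.9
vRBE 103.82 54.23 64.86 98.1
R_ext: 0.29 cm
```

Under the constant weighting the plan is on prescription (PTV mean dose
99.9% of the 54 Gy(RBE) prescription) and the brainstem respects its 54
Gy(RBE) core limit (Dmax 49.1). The variable model raises the PTV mean by
~4% and pushes the brainstem maximum to 64.9 Gy(RBE) — 10.9 Gy(RBE) above
the limit — because RBE climbs at the distal edge that faces the brainstem.
The V95 volume grows from 70.9 to 98.1 cm^3, an equivalent-sphere
biological range extension of 0.29 cm.

## Cohort analyses

The numbered drivers under `analysis/` run the full study on a seeded
20-case cohort and write tables under `results/`:

```
python analysis/01_simulate_cohort.py    # sample cases, export demo grids
python analysis/02_evaluate_cohort.py    # LET, cRBE/vRBE dose, DVH, V95
python analysis/03_cohort_statistics.py  # bootstrap CIs + Wilcoxon tests
python analysis/04_range_extension.py    # R_ext per case/group + figure
python analysis/05_robustness.py         # 12-scenario bands + diff metrics
```

On this cohort the vRBE model raises the median PTV Dmean/D_p from ~99.9%
to 103.3% (brain-like) and 108.4% (skull-base-like) — the low-alpha/beta
group gains more, every case's range extension is positive (group means
0.38 and 0.35 cm), and the cRBE -> vRBE D95 shift exceeds the D95 spread of
the 12 robustness scenarios in both groups.

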