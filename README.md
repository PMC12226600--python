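# cortasym

Quantifying hemispheric cortical asymmetry for dementia differential
diagnosis and subtyping.

Frontotemporal dementia (FTD) typically atrophies the cortex more
asymmetrically than Alzheimer's disease (AD), and the semantic variant of
primary progressive aphasia (svPPA) is the most asymmetric FTD phenotype.
`cortasym` turns that radiological impression into a single number per
scan — the **Cortical Asymmetry Index (CAI)** — and provides the cohort
analyses a memory-clinic study needs around it: age-adjusted group
comparisons, longitudinal mixed models, within-disease subtyping by
hierarchical clustering, and associations with fluid biomarkers (NfL,
GFAP) and cognition (MMSE). Because clinical MRI and biomarker data of
this kind cannot be shared, the package ships a calibrated synthetic
cohort generator so every stage of the pipeline can be validated against
planted ground truth.

## The index

For one subject, let the 34 Desikan-Killiany regional mean cortical
thickness values of the left and right hemispheres be turned into density
estimates `p` and `q` (Gaussian KDE with Silverman bandwidth by default)
evaluated on a shared 128-point grid spanning the pooled, 10%-padded
thickness range. With `m = (p + q)/2` and natural logarithms,

```
KL(p‖q) = Σᵢ pᵢ ln(pᵢ/qᵢ)
JS(p, q) = ½ KL(p‖m) + ½ KL(q‖m)
CAI      = √JS(p, q)
```

Deliberately, the grid-evaluated density vectors are **not** renormalised
to unit sum before the divergence is taken (`DensitySettings(normalise=False)`,
the default), so the index scales with grid resolution; the grid
construction is therefore fixed and recorded with every result. Raw
thickness values are used with no subject-level normalisation — the index
is computed within subject, across hemispheres. CAI is unitless and
non-negative; higher values mean a more asymmetric brain.

## Worked example

```python
from cortasym import (
    default_calibrated_config, simulate_cohort, compute_cohort_cai,
    build_cohort_table, group_comparison, cluster_by_cai,
)

records, biomarkers, truth = simulate_cohort(default_calibrated_config(seed=1))
table = build_cohort_table(records, compute_cohort_cai(records), biomarkers)
base = table[table.visit == 1]

print(base.groupby("group")["cai"].mean().round(2).to_dict())
print(group_comparison(base, "cai", "group", ("age_at_mri",)).summary())
print(cluster_by_cai(base, "FTD").summary())
```

prints (seed 1):

```
{'AD': 0.4, 'CTR': 0.16, 'FTD': 0.61}
Group comparison: cai ~ C(group) + age_at_mri
Omnibus F(group) = 191.135, p = 2.35e-62
...
CAI clustering [FTD]: k = 2 (mean silhouette)
  cluster 1: n = 17, mean CAI = 1.143
  cluster 2: n = 83, mean CAI = 0.496
```

Controls sit near 0.16, AD near 0.40, FTD near 0.61: both dementias are
more asymmetric than controls and FTD more than AD (the omnibus ANCOVA,
adjusted for age, is overwhelmingly significant). Within FTD the
silhouette criterion selects two subgroups; cluster 1 is the
high-asymmetry subgroup, enriched for svPPA and for higher NfL.

The same stages are available from the shell:

```bash
cortasym simulate --seed 1 --out-dir cohort/
cortasym cai cohort/thickness_wide.tsv --out cai.csv
cortasym analyze cohort/thickness_wide.tsv --biomarkers cohort/biomarkers.csv --out-dir results/
cortasym cluster cohort/thickness_wide.tsv --biomarkers cohort/biomarkers.csv --out-dir results/
cortasym run --seed 1 --out-dir full_run/   # everything, deterministically
```

Thickness tables are accepted in the FreeSurfer `aparcstats2table` wide
convention (`lh_<region>_thickness` / `rh_<region>` columns plus
`subject_id, visit, group, phenotype, sex, age_at_mri, age_of_onset`) or
in a long CSV (`subject, visit, hemi, region, thickness` + covariates);
biomarkers travel in a per-subject CSV with columns `csf_nfl, csf_1433,
csf_ykl40, plasma_ttau, plasma_ptau, plasma_nfl, plasma_gfap,
plasma_uchl1, mmse` (empty cells = missing).

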