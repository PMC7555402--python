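# cesm-radiomics

First-order radiomic analysis of contrast-enhanced spectral mammography
(CESM) lesions: feature extraction from paired low-energy (LE) and
recombined (RC) views, feature–histology association testing, and linear
discriminant classification of histological and molecular outcomes — with
a fully synthetic cohort generator so that every stage is testable without
patient data.

## The problem

CESM produces two aligned views of a breast lesion: a low-energy image
equivalent to a digital mammogram, and a recombined subtraction image that
highlights contrast uptake (tumor neo-angiogenesis). Radiomics asks
whether simple gray-level statistics of the lesion ROI carry information
about the tumor's biology — estrogen and progesterone receptor expression
(ER%, PR%), the Ki67 proliferation index, HER2 status, histological grade,
and the triple-negative subtype.

The pipeline computes, per lesion, seven first-order statistics on each
view (14 features total):

| feature | definition |
| --- | --- |
| Mean | arithmetic mean μ of ROI gray levels |
| VC | variation coefficient σ/μ |
| Max-Min | gray-level range |
| Skewness | m₃/σ³ (population central moments) |
| Entropy | −Σ pᵢ log₂ pᵢ over a 256-bin histogram of the ROI's [min, max] |
| RelativeSmoothness | 1 − 1/(1+σₙ²), σₙ the σ of intensities rescaled by the representable range |
| Kurtosis | m₄/σ⁴ (non-excess) |

Each feature is tested against the five outcomes (Pearson correlation for
ER/PR/Ki67; two-sided Mann–Whitney for HER2 and for grade G3 vs G1/G2),
with Bonferroni adjustment over the 14 tests per outcome. Six binary
tasks — ER±(1% cutoff), PR±(20%), Ki67±(20%), high vs low grade, HER2±,
triple-negative vs not — are classified with pooled-covariance Gaussian
LDA, δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + ln π_k, evaluated by leave-one-out
cross-validation and summarized by the ROC area of the pooled LOO scores.

Because no public CESM cohort with per-lesion histology exists at this
scale, the package ships a statistical phantom generator: ~68 lesions with
realistic label marginals and in-ROI textures whose first-order statistics
carry *configurable, calibrated* associations with the labels. That turns
every downstream claim into a testable parameter-recovery statement.

## Worked example

```python
from cesm_radiomics import (CohortConfig, generate_cohort, extract_cohort_features,
                            features_to_frame, build_association_table, run_all_tasks,
                            task_summary_frame)

cfg = CohortConfig(
    n_lesions=68, seed=7,
    effect_map=(("ki67_pct", "RC_VC", 0.5), ("her2", "LE_RelativeSmoothness", 1.2)),
)
records, pairs = generate_cohort(cfg)
features = features_to_frame(extract_cohort_features(pairs))

table = build_association_table(features, records)
row = table[(table.outcome == "Ki67") & (table.feature == "RC_VC")].iloc[0]
print(f"Ki67 vs RC_VC: r = {row.statistic:.2f}, raw p = {row.p_raw:.2g}, "
      f"Bonferroni p = {row.p_adjusted:.2g} (family of {row.family_size})")
print(task_summary_frame(run_all_tasks(features, records)).to_string(index=False))
```

prints

```
Ki67 vs RC_VC: r = 0.40, raw p = 0.0007, Bonferroni p = 0.0098 (family of 14)
 task  pos  neg  auc_pct  feasible
   ER   58   10    47.59      True
   PR   34   34    42.47      True
 Ki67   44   24    53.03      True
Grade   25   43    26.98      True
   TN    6   62    49.46      True
 HER2   17   51    76.93      True
```

The planted Ki67↔RC_VC correlation of 0.5 is attenuated to r = 0.40 in a
single n = 68 sample but survives Bonferroni; the planted HER2 texture
shift lifts that task's LOO AUC to 77% while the four tasks without
planted signal scatter around chance (LOO AUCs often dip below 50% on null
data — a known small-sample artifact of leave-one-out).

More narrative scripts live in `examples/` (cohort generation, feature
extraction, association table, classification, full pipeline), and
`cesm-radiomics run --synthetic --n 68 --seed 1 --out run1` drives the
whole pipeline from the shell with per-stage subcommands
(`generate`, `extract`, `associate`, `classify`, `report`).

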