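# pdstriatum

Multi-modality (T1-MR + dopamine-transporter PET) striatal analysis for
Parkinson's-disease classification, exercisable end to end on synthetic 3D
brain phantoms.

In early Parkinson's disease, presynaptic dopamine-transporter (DAT)
binding falls in the striatum — earliest and most strongly in the posterior
putamen — while structural anatomy is largely preserved. PET tracers of the
DAT show this loss, but PET alone localizes the striatal anatomical regions
(SARs: caudate nucleus, putamen, pallidum, bilateral) poorly. The pipeline
implemented here therefore combines the two modalities: a deeply supervised
residual 3D U-Net segments the SARs on the subject's MR; a rigid MR→PET
registration propagates those labels (plus a parieto-occipital reference
region) onto the PET; region statistics are normalized to
striatal-to-occipital ratios,

    SOR = (striatum − occipital) / occipital,

yielding 90 features per subject (14 regions × 6 statistics = 84 SOR
features + 6 SAR volumes); Welch t-tests at α = 0.01 select features, a
linear SVM classifies PD vs NL under leave-n-out cross-validation, and a
random forest ranks feature importance. A single-modality comparison arm
replaces the subject MR with a pre-labeled PET template aligned by
pre-rigid + affine registration.

The segmentation network trains with the composite loss

    L = w_D · E_i[(−ln Dice_i)^γ] + w_C · E_x[−ln p_l(x)],

(defaults w_D = 0.8, w_C = 0.2, γ = 0.3), where Dice_i is the soft Dice of
label i and p_l(x) the predicted probability of the true label — the
exponentiated Dice term keeps the small striatal structures from being
swamped by background. Deep supervision applies the same loss at every
decoder resolution.

Clinical MR/PET cohorts of this kind are not freely redistributable, so the
package ships a first-class phantom generator: paired MR/PET volumes with
gold-standard labels, group-dependent uptake (PD reduction strongest in the
posterior putamen), additive noise, per-subject anatomical jitter, and a
known rigid MR↔PET misalignment. Every stage of the pipeline — losses,
registration recovery, feature schema, selection calibration, leakage-free
cross-validation — is tested against these phantoms with analytically known
ground truth. See `docs/methods.md` for the full model description and for
what phantom-scale results do and do not demonstrate.

Audience: researchers building or evaluating multimodal neuroimaging
classification pipelines who need a compact, fully inspectable, CPU-scale
reference implementation with honest oracles.

## Worked example

```python
from pdstriatum import (PhantomConfig, generate_cohort, PipelineConfig,
                        cohort_features, leave_n_out_cv, select_features,
                        rf_importance)

cohort = generate_cohort(PhantomConfig(), n_pd=12, n_nl=8, seed=7)
table, failures = cohort_features(cohort, PipelineConfig(arm="manual_labels", seed=7))

selected, pvals = select_features(table, alpha=0.01)
res = leave_n_out_cv(table, n=1, seed=7)
imp, agg = rf_importance(table, seed=7)

print(f"subjects: {len(table)}, features: {len(table.feature_names)}")
print(f"selected features: {len(selected)} (volumes: "
      f"{sum(n.endswith('_volume') for n in selected)})")
print(f"leave-one-out accuracy: {res.acc_mean:.3f}  "
      f"wrong predictions: {res.wrong_mean:.1f}")
print("aggregate importance per statistic kind:")
print(agg.round(4).to_string())
```

prints

```
subjects: 20, features: 90
selected features: 48 (volumes: 0)
leave-one-out accuracy: 1.000  wrong predictions: 0.0
aggregate importance per statistic kind:
mean      0.130
median    0.210
q3        0.298
q1        0.082
max       0.278
min       0.002
volume    0.000
```

Reading: on a separable phantom cohort the 90-feature schema is produced
for every subject; about half the SOR features separate the groups at
α = 0.01 while none of the six volume features does (the generator draws
volumes from a group-independent distribution); leave-one-out
classification is perfect; and the forest assigns essentially all
importance to the intensity statistics — with the minimum last (edge
voxels dominate the regional minimum, so it carries the least group
signal) and volume negligible.

The same stages are available from the shell:

```bash
pdstriatum simulate --n-pd 12 --n-nl 8 --seed 7 --out cohort/
pdstriatum run --manifest cohort/manifest.csv --arm manual_labels --n 1,2 \
    --seed 7 --out report/
```

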