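# regionage

Region-wise multimodal brain-age modeling: per-region Gaussian-process
age prediction with bias correction, brain-age-gap computation, and group
inference — with a ground-truth synthetic cohort generator so the whole
pipeline is testable without access to clinical imaging data.

## The problem

"Brain age" is an age estimate predicted from neuroimaging features by a
model trained on healthy subjects. The *brain-age gap* — corrected
predicted age minus chronological age — indexes apparent accelerated
aging, and in disorders such as schizophrenia it varies across brain
regions and modalities. A region-wise analysis needs, per atlas region
and modality (gray-matter intensity, voxel-wise average functional
connectivity, fractional anisotropy):

1. **Key-voxel selection** — a stability selector on the healthy training
   cohort: draw half the subjects, rank voxels by |Pearson r| with age,
   keep the top half; intersect over 100 such draws to get one round's
   key set; repeat for 100 rounds and keep voxels selected in more than
   10 rounds.
2. **Age model** — Gaussian-process regression (squared-exponential +
   white-noise kernel) on the key voxels with five-fold cross-validation.
3. **Bias correction** — fit `brain age ≈ α·chronological age + β` on the
   out-of-fold predictions, then

       corrected brain age = brain age + [chronological age − (α·chronological age + β)]
       brain age gap       = corrected brain age − chronological age

   with model performance reported as MAE and Pearson r between corrected
   and chronological age.
4. **Inference** — per-region ANCOVA of the gap on group with
   chronological age, sex, MMSE and education as covariates; partial η²
   effect sizes; Benjamini–Hochberg FDR across regions; and, within the
   patient group, standardized regressions of the gap on clinical
   variables (PANSS subscales, illness duration, onset age, nicotine,
   BMI; antipsychotic dose separately) controlling for age and sex.

With the default 90 GM + 90 FC + 48 FA atlases a full run trains exactly
228 region models. Since cohorts of this kind are confidential, the
`synthetic` module generates study-shaped cohorts — 230 healthy training
subjects aged 20–84, held-out control and patient groups, voxel maps with
a calibrated age signal, and region-specific injected "accelerated
aging" offsets — with machine-readable ground truth for validation.

## Worked example

```python
from regionage import (PipelineConfig, SyntheticConfig, ModalitySpec,
                       SelectionParams, run_full)

cfg = PipelineConfig(
    synthetic=SyntheticConfig(
        n_hc_train=120, n_hc_test=40, n_scz=40,
        atlas_spec={"GM": ModalitySpec(n_regions=8, n_voxels=120,
                                       baseline=10.0, slope_sign=-1)},
        effect_spec={"GM": {1: 5.0, 2: 5.0}},   # +5 y injected in regions 1, 2
    ),
    selection=SelectionParams(n_inner=50, n_outer=30, count_threshold=3),
    seed=42,
)
bundle = run_full(cfg)

perf = bundle.performance
print(f"trained {bundle.n_models} region models "
      f"(mean CV MAE {perf['cv_mae'].mean():.2f} y, mean CV r {perf['cv_r'].mean():.3f})")
grp = bundle.group_results
for _, row in grp.sort_values("partial_eta_sq", ascending=False).head(3).iterrows():
    print(f"GM region {row['region_id']:>2.0f}: gap HC {row['hc_mean_gap']:+.2f} y, "
          f"SCZ {row['scz_mean_gap']:+.2f} y, partial eta^2 {row['partial_eta_sq']:.3f}, "
          f"adjusted p {row['p_adjusted']:.2g}")
```

prints

```
trained 8 region models (mean CV MAE 4.17 y, mean CV r 0.960)
GM region  2: gap HC -0.07 y, SCZ +5.63 y, partial eta^2 0.236, adjusted p 7.1e-05
GM region  1: gap HC -0.48 y, SCZ +4.76 y, partial eta^2 0.146, adjusted p 0.0026
GM region  3: gap HC -0.18 y, SCZ -0.49 y, partial eta^2 0.023, adjusted p 0.39
```

The two regions carrying the injected +5-year effect are recovered with
patient gaps near +5 years and survive FDR correction; untouched regions
show near-zero gaps in both groups. The models themselves track age with
an MAE of ~4 years on this small cohort (~3 years at the full default
scale of 200 voxels/region and n = 230).

## Command line

Every stage is also a subcommand exchanging plain files, so stages can be
re-run in isolation:

```sh
regionage simulate        --config cfg.yaml --out cohort/        # NIfTI + TSV + truth JSON
regionage build-maps      --cohort cohort/ --out maps/
regionage select-features --maps maps/ --meta cohort/subjects.tsv --config cfg.yaml --out masks.json
regionage train           --maps maps/ --meta cohort/subjects.tsv --masks masks.json --config cfg.yaml --out models/
regionage predict         --maps maps/ --meta cohort/subjects.tsv --models models/ --out estimates.tsv
regionage compare         --estimates estimates.tsv --meta cohort/subjects.tsv --config cfg.yaml --out stats/
regionage run-all         --config cfg.yaml --seed 0 --out run/  # everything, in memory
```

One master seed governs all randomness; two same-seed runs produce
byte-identical outputs.

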