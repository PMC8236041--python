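# relimap

Test–retest reliability analysis for longitudinal task-fMRI contrast maps.

Task-fMRI measures are increasingly proposed as biomarkers — for example to
predict treatment outcome from neural cue-reactivity — but a measure can
only predict anything if it is reliable across repeated scans. `relimap`
implements the complementary reliability measures used for longitudinal
multi-session designs (N subjects × K sessions × C task conditions), working
from per-subject first-level contrast or statistic maps in NIfTI format:

- **Thresholded-activation overlap.** Each subject's t-map is binarized at a
  voxel-wise threshold (default one-sided p < 0.001); between two sessions
  the super-threshold voxel sets A, B are compared by
  Jaccard = |A∩B|/|A∪B| and Dice = 2|A∩B|/(|A|+|B|), summarised per session
  pair × contrast, and tested with a two-way repeated-measures ANOVA
  (factors: contrast, session pair) with paired post-hoc comparisons.
- **Voxel-wise ICC(3,1).** The consistency intraclass correlation from the
  two-way mixed model, ICC = (BMS − EMS)/(BMS + (k−1)·EMS), which for k = 2
  sessions equals (σ²_between − σ²_within)/(σ²_between + σ²_within). Maps
  can be thresholded (e.g. ICC > 0.75, good-to-excellent by the Fleiss
  benchmarks) and summarised per atlas region.
- **Similarity and re-identification ("fingerprinting").** The subject ×
  subject matrix of spatial correlations between two sessions' maps; a
  subject is re-identified when their within-subject similarity (diagonal)
  strictly exceeds every between-subject similarity in their row. Includes
  the Welch t-test of within- vs between-subject similarity and ECDF curves.
- **Cross-condition correlation and difference-score attenuation.** Spatial
  Spearman correlations between condition maps (e.g. food vs neutral)
  quantify shared variance, and a closed form predicts the reliability of a
  difference contrast X − Y from the constituent reliabilities and their
  cross-correlation — subtraction removes shared true variance while
  measurement errors add.
- **Rating-scale reliability.** The same consistency ICC applied to
  in-scanner visual-analogue craving contrasts (mean food − mean neutral
  rating per session), plus a one-way repeated-measures ANOVA of the
  session time course.
- **Variance-component phantoms.** A synthetic-data generator draws
  multi-subject, multi-session, multi-condition map stacks from
  Y = μ + b_subject + ε_session with known per-voxel σ²_between and
  σ²_within (hence known true ICC), a controllable sharing coefficient
  between condition signals, and synthetic craving ratings — so every
  analysis stage is testable by parameter recovery. See
  [docs/methods.md](docs/methods.md) for the model and its limits.

## Worked example

Generate a two-condition phantom in which the food and neutral conditions
share 60 % of their stable signal variance, derive the difference contrast
by subtraction, and measure how its reliability compares:

```python
import numpy as np
from relimap import (PhantomSpec, generate_condition_stack, overlap_table,
                     overlap_summary, voxelwise_icc, similarity_matrix,
                     reidentification, condition_correlation_summary)

spec = PhantomSpec(shape=(12, 12, 12), n_subjects=20,
                   sigma2_between=0.5, sigma2_within=0.5, seed=42)
stack, truth = generate_condition_stack(
    spec, ("food", "neutral"), sharing=0.6,
    differences={"food_minus_neutral": ("food", "neutral")},
)

table = overlap_table(stack, ["food", "neutral", "food_minus_neutral"],
                      [("T0", "T1")], t_threshold=1.0)
print(overlap_summary(table)[["contrast", "mean_dice", "sd_dice"]]
      .round(3).to_string(index=False))

for c in ("food", "food_minus_neutral"):
    m = voxelwise_icc(stack, c, ["T0", "T1", "T2"])
    print(f"mean voxel-wise ICC[{c}]: {np.nanmean(m.values):.3f}")

fp = reidentification(similarity_matrix(stack, "food_minus_neutral", "T0", "T1"))
print(f"re-identification: {fp.rate:.0f}% (mean within r = {fp.mean_within:.2f})")

rho = condition_correlation_summary(stack, ["food"], "neutral")
print(f"food-neutral mean rho = {rho['mean_rho'].iloc[0]:.2f} "
      f"(expected {truth.expected_rho_spearman:.2f})")
```

Output:

```
          contrast  mean_dice  sd_dice
              food      0.623    0.016
           neutral      0.628    0.018
food_minus_neutral      0.497    0.022
mean voxel-wise ICC[food]: 0.479
mean voxel-wise ICC[food_minus_neutral]: 0.271
re-identification: 100% (mean within r = 0.54)
food-neutral mean rho = 0.43 (expected 0.43)
```

The difference contrast is markedly less reliable than either constituent
condition (Dice 0.50 vs 0.62/0.63; mean ICC 0.27 vs 0.48) even though it was
built from the very same data — the attenuation that
`relimap.difference_reliability` predicts in closed form: with test–retest
r = 0.75 for each constituent and cross-condition r = 0.45, the difference
score's reliability drops to (0.75 − 0.45)/(1 − 0.45) ≈ 0.55 at the map
level. The recovered cross-condition Spearman rho (0.43) matches the
generator's analytic expectation.

## Command line

Every stage is also exposed as a `relimap` subcommand over on-disk studies
(NIfTI volumes + a manifest TSV with columns subject, session, condition,
path):

```bash
relimap simulate --seed 3 --out-dir sim/          # phantom study bundle
relimap overlap    --manifest sim/manifest.tsv --mask sim/mask.nii.gz \
                   --df 440 --p 0.001 --contrasts food_minus_neutral --out ov.tsv
relimap icc        --manifest sim/manifest.tsv --mask sim/mask.nii.gz \
                   --contrast food_minus_neutral --out-dir icc/
relimap similarity --manifest sim/manifest.tsv --mask sim/mask.nii.gz \
                   --contrast food_minus_neutral --pairs T0:T1,T1:T2 --out-dir sim_out/
relimap ratings    --ratings sim/ratings.tsv --out ratings.json
relimap run        --config study.yaml --out-dir results/   # full workflow + report.json
```

`relimap run` executes all configured stages and writes a versioned
`report.json` carrying every summary statistic together with the thresholds,
session pairs, and exclusion counts that produced it.

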