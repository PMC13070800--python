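# idolseg

Patient-adaptive 3D liver-tumor segmentation and RECIST response evaluation
for treated hepatocellular carcinoma (HCC).

After chemoradiotherapy, response is read off follow-up CT by RECIST 1.1:
the change in the target lesion's longest axial diameter D classifies the
case (PR if ΔD ≤ −30%, PD if ΔD ≥ +20% and ≥ 5 mm, CR if the lesion
disappears, SD otherwise).  Getting D automatically requires segmenting a
*treated* tumor — necrotic, scarred, on a cirrhotic background — where a
model trained across patients often fails on a new patient's follow-up
scan.

`idolseg` implements a two-stage answer:

1. **Generalized model** — a 3D, single-channel fully convolutional
   DenseNet (encoder blocks of 2/3/4/5 dense layers + 7-layer bottleneck,
   growth rate 12) trained on {CT, contour} pairs from both time points
   with a combined cross-entropy + dual cross-entropy + soft-Dice loss,
   Adam at batch size 1 under a polynomial learning-rate decay
   lr(t) = 10⁻³·(1 − t/T)⁰·⁹.
2. **Personalized model** — the generalized weights *intentionally
   overfitted* to one patient's prior pair {CT_pre, Tumor_pre}, repeated
   and perturbed (affine + brightness + noise) for a fixed 350 epochs; the
   final checkpoint segments that patient's CT_post.

Predicted masks feed mask-to-RECIST geometry (longest in-plane diameter of
the largest connected component per axial slice), response classification,
and agreement statistics: Dice similarity DSC = 2|A∩B|/(|A|+|B|),
2×2 PR/SD concordance with sensitivity/specificity/balanced-accuracy AUC,
exact McNemar, paired t / Wilcoxon / Spearman.

Since no clinical images are published, the package ships (a) a synthetic
phantom generator producing paired pre/post portal-venous-like liver CT
with exact ground-truth masks, configurable shrinkage and a peritumoral
edema ring excluded from the truth (the documented over-segmentation trap),
and (b) fixture tables transcribing the published per-case validation
results, from which every reproducible summary statistic is recomputed.

The network and its training run on a small numpy autodiff engine included
in the package; no GPU or deep-learning framework is required.

## Worked example

```python
from idolseg import (PhantomConfig, generate_case, fit_generalized,
                     TrainConfig, NetConfig, IdolConfig, adapt, segment_post,
                     dice, measure_case, predict, binarize)
from idolseg.phantom import generate_cohort
from idolseg.reproduce import DESK_NET, run_desk_experiment

# a 9-patient synthetic cohort: 6 train / 3 validation
report = run_desk_experiment(seed=0)
for row in report["per_case"]:
    print(row["case_id"], round(row["dsc_fcd_post"], 3), round(row["dsc_idol_post"], 3))
print("means:", {k: round(v, 3) for k, v in report["means"].items()})
```

prints (seed 0):

```
val00 0.616 0.764
val01 0.677 0.826
val02 0.791 0.687
means: {'dsc_fcd_pre': 0.824, 'dsc_fcd_post': 0.695, 'dsc_idol_post': 0.759,
        'pred_post_volume_cc': 6.037, 'true_post_volume_cc': 3.548}
```

Read: on held-out phantom patients the generalized model's post-treatment
Dice drops to 0.695 (treated tumors look different), while the
patient-adapted model reaches 0.759 — the same direction as the published
clinical comparison (0.53 → 0.63) — and the adapted model's masks are
larger than the truth (6.04 vs 3.55 cc), reproducing the known tendency to
over-segment into peritumoral inflammatory change.

Reproducing the published tables needs no training at all:

```python
from idolseg.reproduce import recompute_summaries
rep = recompute_summaries()
print(rep["mean_dsc_idol_post"])   # {'value': 0.6342..., 'published': 0.63, 'match': True}
print(rep["auc"])                  # {'value': 0.875,  'published': 0.875, 'match': True}
```

A command-line interface mirrors the stages (`idolseg phantom generate`,
`idolseg train fit`, `idolseg idol adapt|segment`, `idolseg metrics dice`,
`idolseg recist measure|concordance`, `idolseg reproduce tables|experiment`);
volumes and masks are NIfTI-1 (`.nii`/`.nii.gz`), masks stored as uint8.

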