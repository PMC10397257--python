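# endodx

Patient-level diagnosis from endoscopic video frame scores.

Distinguishing sinonasal **inverted papilloma (IP)** — a benign tumor
with real recurrence and malignancy risk — from **chronic
rhinosinusitis with nasal polyps (CRSwNP)** is hard in outpatient nasal
endoscopy, and definitive diagnosis requires pathology. A
computer-aided approach classifies every frame of an endoscopic video
and then turns the *ordered sequence* of frame scores into a single
patient-level call. `endodx` implements that pipeline as a testable,
seedable library for methods work: the cross-validation and ensembling
protocol, the two original temporal aggregation rules, the evaluation
metrics, and a synthetic cohort generator so everything runs without
clinical video.

## The method

A frame classifier emits a score $s_t \in [0,1]$ (higher = more
IP-like) for each frame $t$ of a patient's video, in video order.

**Grouped cross-validation.** Patients are split into $K$ groups,
stratified by class and balanced in patients and images (greedy
longest-first packing); each model trains on $K-1$ groups and scores
only the held-out group, so no patient's frames ever straddle the
train/test boundary. Training is repeated $R$ times
($K{\times}R$ models; $8 \times 25 = 200$ at clinical scale), and
**leave-one-repeat-out ensembles** average the $R-1$ remaining score
streams frame by frame ($24$-of-$25$ at clinical scale), damping
run-to-run training fluctuation.

**Patient-unit aggregation.** Lesion evidence in video is temporally
contiguous, which two statistics exploit:

- *continuity analysis*: $C = \max$ length of a run of consecutive
  frames with $s_t \ge \tau$; call IP when $C \ge L$;
- *five-second scoring*: with window $W = \mathrm{round}(5\,\mathrm{s}
  \times \mathrm{fps})$ frames ($W = 599$ at 119.88 fps),
  $M = \max_i \frac{1}{W}\sum_{t=i}^{i+W-1} s_t$; call IP when
  $M \ge \theta$.

Metrics are sensitivity, specificity, their average **SS-Avg**
(balanced accuracy — the headline figure for a 21-vs-32 imbalanced
cohort), ROC curves with trapezoidal AUC, median-case ROC across
repeats, and fluctuation (sd across repeats). A clinician-comparison
module summarizes per-rater correct-diagnosis rates by experience band
(<5, 5–10, >10 years) for overlay on the ROC plane.

Because no clinical videos are distributable, the `synthetic` module
generates seeded surrogate cohorts: lesion visibility follows a
two-state Markov chain (mean dwell, stationary visible fraction),
frame logits are `+separation/2` on lesion-visible frames of positive
patients and `-separation/2` for negatives, with AR(1) logit noise —
and, optionally, procedural frame *images* whose lesion frames carry a
papillary texture so the full training path can run.

## Worked example

Classifier-free mode: generate a noisy synthetic cohort and aggregate
its score streams directly.

```python
import endodx as e

cfg = e.SyntheticCohortConfig(n_pos=10, n_neg=10, frames_per_patient=600,
                              separation=1.5, master_seed=0)
streams, labels = e.generate_score_streams(cfg)

frame_scores = [v for s in streams for v in s.scores]
frame_labels = [labels[s.patient_id] for s in streams for _ in s.scores]
print(f"frame-level  AUC={e.roc(frame_scores, frame_labels).auc:.3f}")

stats = {s.patient_id: e.max_window_mean(s, 5.0) for s in streams}
t = e.select_threshold(stats, labels)
cm = e.confusion({p: e.patient_decision(v, t) for p, v in stats.items()}, labels)
print(f"5-s scoring  AUC={e.roc(stats, labels).auc:.3f}  theta={t:.3f}  "
      f"sens={cm.sensitivity:.0%}  spec={cm.specificity:.0%}  SS-Avg={cm.ss_avg:.1%}")
```

prints

```
frame-level  AUC=0.646
5-s scoring  AUC=0.990  theta=0.469  sens=100%  spec=90%  SS-Avg=95.0%
```

Frame-by-frame prediction is weak (the lesion is visible in only a
quarter of a positive patient's frames, and frames are noisy), but the
5-second window statistic concentrates the contiguous evidence and
nearly separates the classes — the central claim the patient-unit
methods rest on.

The same pipeline, end to end with a trained frame classifier, from
the shell:

```sh
endodx run --preset desk --seed 1 --out runs/demo     # simulate→train→evaluate
endodx raters --raters raters.csv --manifest runs/demo/cohort/manifest.csv \
    --out raters.json                                 # clinician comparison
```

`runs/demo/report.json` holds the full report (frame-level and
patient-level sensitivity/specificity/SS-Avg for single models and
ensembles, fluctuation, median-case AUCs) with the config hash and
seed embedded; `simulate`, `partition`, `train`, `aggregate` and
`evaluate` expose the individual stages.

## Layout

| module | contents |
| --- | --- |
| `endodx.synthetic` | seeded cohort generator: score streams + frame images |
| `endodx.cohort` | manifest I/O, balanced grouped partition, leakage check |
| `endodx.frame_prep` | lazy augmentation pools, epoch sampling, transforms |
| `endodx.committee` | K×R training orchestration, classifier contract, stream I/O |
| `endodx.aggregate` | ensembles, continuity and 5-s statistics, thresholds |
| `endodx.evaluate` | confusion/ROC/fluctuation metrics, clinician comparison |
| `endodx.cli` | run configs, end-to-end pipeline, `endodx` subcommands |

See `docs/methods.md` for the modeling choices, parameter meanings and
known limitations.
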