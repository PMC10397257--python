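# Methods

This note documents the models, defaults and design decisions behind
`endodx`, in the spirit of a methods appendix: what is simulated, what
is computed, and what passing tests do and do not establish.

## Problem setting

One patient contributes one endoscopic video; a frame classifier
yields a score stream $s_1,\dots,s_n \in [0,1]$ in video order (higher
= more IP-like), and the diagnostic question is patient-level:
IP versus CRSwNP. The clinical reference protocol is 21 IP + 32 CRSwNP
patients, ~143k frames at 119.88 fps, 8 patient groups, 25 repeated
trainings (200 models), 24-of-25 ensembles. The package reproduces the
*protocol* faithfully at configurable scale; it does not attempt to
reproduce clinical weights or clinical accuracy, which depend on
unavailable video.

## Synthetic cohort model

The generator produces the minimal structure the aggregation methods
assume — contiguous positive evidence — and nothing more.

**Score streams.** For a positive patient, lesion visibility
$v_t \in \{0,1\}$ follows a two-state Markov chain with mean visible
dwell $d$ frames (geometric exit, $p_\text{exit} = 1/d$) and
stationary visible fraction $f$
($p_\text{enter} = f p_\text{exit}/(1-f)$); the chain starts at its
stationary law, so no burn-in is needed. The frame logit is
$\mu_t = +\sigma/2$ when $v_t = 1$ and $0$ otherwise; negative
patients sit at $\mu_t = -\sigma/2$ throughout ($\sigma$ =
`separation`). Noise is AR(1) *on the logit scale* —
$e_t = \rho e_{t-1} + \varepsilon_t$, $\varepsilon_t \sim N(0,
\texttt{noise\_sd}^2)$, initialized at the stationary marginal — and
the score is $s_t = \text{logistic}(\mu_t + e_t)$. Squashing after
adding noise keeps scores in $[0,1]$ without clipping artifacts;
thresholding a noise-free stream recovers the visibility chain
exactly, which the tests use as a run-length oracle.

**Frame images.** Each frame is a small procedural RGB image: a
pink-mucosa base color, a low-frequency shading field that itself
evolves as AR(1) across frames (temporal coherence), per-pixel sensor
noise scaled by `noise_sd`, and — on lesion-visible frames of positive
patients — a high-frequency "papillary bump" texture whose amplitude
is proportional to `separation` (0.04 of dynamic range per unit). An
optional distractor texture for negative patients (pale, coarser
bumps) is off by default, since no prevalence of IP-like regions in
CRSwNP is established. No claim is made that the texture resembles
real IP morphology; it is a learnable, parameterized stand-in for
"class-specific fine texture", echoing the raspberry-like appearance
clinicians describe. Bleeding, forceps, specular highlights and
photometric drift of real endoscopy are deliberately absent, so a
classifier's success here shows the *protocol* works, not that the
feature set would survive clinical video.

**Stock benchmark defaults** (used throughout the tests and the
acceptance script): 20+20 patients × 200 frames, `separation=3`,
`noise_sd=1`, `ar1_rho=0.8`, lesion dwell 30 frames, visible fraction
0.25, 64-px frames, 119.88 fps. These sizes keep a full K=4 × R=10
trained run at a few CPU-minutes while leaving the frame-level problem
genuinely hard (frame AUC well below patient AUC), which is the regime
the patient-unit methods are for. Determinism: every patient's stream
and images derive from `(master_seed, patient_index)` via independent
seed sequences, so cohorts are bit-reproducible and unchanged by
adding patients elsewhere in the cohort.

## Partition

Groups are built per class: patients sorted by frame count descending
(ties shuffled by seed), each assigned to the group with the fewest
patients of that class, ties broken by the smaller running image
total, then by seeded group order. This greedy longest-first packing
guarantees per-class group sizes differ by ≤ 1 — reproducing the
reference structure (IP 2,2,2,3,3,3,3,3; CRSwNP 4×8) — and a bounded
image-total spread, which a brute-force test verifies on small
instances. The published protocol states only "random, as uniform as
possible"; the exact clinical patient-to-group mapping is not
recoverable and not a goal. The 7:1 learning:evaluation ratio is
interpreted as 7 groups train / 1 group evaluate per fold. A class
with fewer patients than groups degrades gracefully: a warning, and
folds lacking the class report NaN (not zero) for its rates.

## Augmentation and training protocol

The clinical protocol augments ~143k frames to 6 million images and
draws 120,000 per epoch for 50 epochs. Materializing such a pool is
pointless, so the pool is *lazy*: descriptor $i$ (source frame +
fully-instantiated transform parameters) is a pure function of
`(seed, i)`, making a 6-million-entry pool free to construct and
byte-reproducible. Source frames are drawn uniformly over all frames
of all training patients — deliberately not per-patient balanced,
matching the stated protocol — and epochs sample uniformly without
replacement (with-replacement behind a flag; the protocol does not
specify). The transform families (H/V flip, rotation ±20°, crop
80–100%, brightness/saturation ±20%) are standard endoscopy-safe
choices; the protocol does not list its transforms, so these are
configurable defaults, not claims of fidelity.

## Classifier backend

The committee is coupled to learning machinery only through a
two-method contract: `fit(samples, labels, seed)` and
`score(samples) -> [0,1]`. The default backend is a deliberately small
deterministic model — 12 hand-crafted texture features (channel
means/sds, high-pass energies at two scales, gradient and Laplacian
energy) standardized and fed to logistic regression. The package's
subject is the committee/aggregation protocol, and this backend makes
a full K×R committee trainable in minutes on one CPU while still
being a genuine learner on the synthetic texture signal. Run-to-run
variability across repeats enters through per-job seeds
(SHA-256 of `(master_seed, repeat, fold)`), which drive pool
construction and epoch sampling — mirroring the training-to-training
fluctuation that motivates ensembling. Frames inherit their patient's
label during training (weak labeling): lesion-invisible frames of
positive patients are noisy positives, exactly as in frame-labeled
clinical training. An `oracle` backend that replays the generator's
latent scores verifies the orchestration is an identity map around
the backend. Heavier backends (e.g. a compact CNN such as
MobileNet-V2, the clinical reference at 224×224 input) can be plugged
in through the same contract; none is bundled.

## Aggregation

Both patient statistics are computed exactly (run-length by boundary
differences; window by one sliding-sum pass) and are property-tested
against exhaustive enumeration. The window statistic is reported as
the window *mean* (sum/W): identical patient ordering to the maximum
window sum at fixed W, but frame-rate-invariant and thresholdable on
$[0,1]$. $W = \mathrm{round}(\texttt{window\_seconds} \times
\mathrm{fps})$, clipped to the stream length — 599 frames for 5 s at
119.88 fps. Ensembles average scores frame-wise (probability
averaging; majority vote behind a flag — the combination rule is not
published). All boundary ties count positive, uniformly: frame
positive iff $s \ge \tau$, patient positive iff statistic ≥ cutoff.

No numeric values for $\tau$, $L$ or $\theta$ are published, and the
clinical operating points are therefore not exactly recoverable.
Defaults: $\tau = 0.5$; $L$ and $\theta$ are selected *per evaluation
fold* by maximizing SS-Avg over the patients of the other folds only
(smallest maximizer on ties, favoring sensitivity), so an evaluation
fold never tunes its own cutoff. Threshold-free comparisons use the
ROC/AUC over the patient statistics.

## Evaluation

SS-Avg = (sensitivity + specificity)/2 is the headline metric; with a
21/32 class split a reported "accuracy" of 0.843 equals the mean of
the published sensitivity (80.95%) and specificity (87.63%) and is
treated as balanced accuracy throughout. ROC curves use the rule
"statistic ≥ t" with tied values collapsed to one operating point,
endpoints (0,0) and (1,1), trapezoidal AUC (equal to the tie-corrected
Mann–Whitney $U/(n_+ n_-)$, which the tests assert); the median-case
curve is the actual curve with (lower-)median AUC, never an
interpolation. Fluctuation summaries use the sample (n−1) standard
deviation. Clinician tables report each rater's raw correct-diagnosis
rate (the clinical comparison metric) *and* a sensitivity/specificity
pair for ROC overlay — the published band definitions overlap ("<5"
and "4–10"), resolved here as <5 / 5–10 / >10 years.

## Numerical and degenerate-input choices

Scores are validated to $[0,1]$ at every boundary (stream
construction, CSV ingest with line-numbered errors, backend output
clipped). Empty streams, single-class ROC inputs, sub-2 ensembles and
mismatched patient sets raise immediately rather than propagating
NaNs; genuinely undefined rates (a class absent from a fold) are NaN
and flagged, never zeroed. Score-stream CSV reading is chunked, so
million-row files validate with a bounded working set.

## What the tests show — and don't

Passing the suite establishes: the protocol is leakage-free by
construction and by check; the aggregation statistics equal their
brute-force definitions; ensembles reduce SS-Avg fluctuation on the
stock benchmark; temporal aggregation beats frame-level prediction
when lesions are temporally clustered (visible fraction 0.25); and the
pipeline recovers chance at zero separation and perfection in the
noise-free fully-visible limit. None of this validates performance on
clinical endoscopy: the synthetic texture is far easier and cleaner
than real mucosa, the default backend is far smaller than a clinical
CNN, and desk-scale cohorts are an order of magnitude smaller than
even the (already small) clinical study.
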