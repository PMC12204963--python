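# Methods

`ctphase` identifies the contrast phase — early arterial (EAP), late
arterial (LAP), portal venous (PVP) or delayed (DP) — of each volume in a
1–3 phase abdominal CT examination, from image content alone (no
acquisition metadata).  This note documents the model, the synthetic data
it is developed against, the numerical choices, and what the desk-scale
experiments do and do not show.

## The classification model

**Shared-parameter extraction.**  Every phase volume of one examination
passes in parallel through the *same* 3D residual feature extractor (one
parameter set for all branches).  Sharing makes the network agnostic to
which slot a phase arrives in, and is what makes permutation
equivariance possible.

**Cross-phase attention fusion.**  After the mid-level stage (stage 2 of
4 at full scale), each phase's feature map is flattened to an
N positions × C channels matrix F and mixed with every other phase
present:

    f_att(A, B) = A · softmax(−AᵀB)
    F′_p = F_p + Σ_{q≠p} f_att(F_p, F_q)

The C × C affinity AᵀB is a channel Gram matrix over spatial positions;
the softmax is row-wise (each row sums to 1) so f_att re-weights A's
channels.  The *negated* affinity up-weights channels of A that are most
dissimilar to B — accentuating inter-phase differences, which is the
discriminative signal for phase identity.  The published formula gives no
operand shapes; the channel-Gram reading adopted here is the one
shape-consistent interpretation that keeps F′ the same shape as F under
the stated additive fusion.  An optional 1/√N affinity scaling
(`scale_affinity`) exists for numerical headroom but is off by default,
matching the bare formula.  With a single phase the sum is empty and the
network reduces to a plain forward pass; missing phases simply drop out
of the sum.

**Heads and strategies.**  Fused features continue through the remaining
stages to a global average pool and a softmax head.  Strategy A
(one-step) uses a 4-class head directly.  Strategy B (two-step cascade)
first classifies AP / PVP / DP with a 3-class model; a separate 2-class
EAP-vs-LAP model is activated *only* for phases whose first-step argmax
is AP, and runs on those phases alone.  The cascade's 4-vector is
assembled by the product rule p(EAP) = p(AP)·p(EAP|AP) etc.; for non-AP
phases the residual AP mass is parked in the EAP slot with split (1, 0)
purely to keep a unit-sum vector (a renormalising convention is
selectable; labels are unaffected either way because such a phase's
argmax is not AP).  The two step-2 models are trained independently —
whether the original development re-used step-1 weights is unstated, and
independent training is the cleaner default.

**Phase-order calibration.**  One examination holds at most one
acquisition per step-1 class, acquired in the order AP < PVP < DP.
`calibrate_order` brute-forces all assignments of distinct step-1 classes
to the exam's phases (≤ 3! = 6), maximising the product of predicted
probabilities; when the acquisition order is known, assignments violating
it are excluded.  Calibration is an exam-level prior: it defaults on for
exam-level prediction and off for phase-wise metrics.  Relative order is
the rank of each phase under canonical timing EAP < LAP < PVP < DP.
Ties everywhere break to the earliest class in canonical order.

## Training

Adam with focal loss (γ = 2 by default; the loss reference gives no γ,
and γ = 0 recovers cross-entropy), staircase learning rate (divide by
`lr_decay_factor` = 10 every `lr_decay_every` = 100 epochs), best
validation epoch kept (earliest on ties).  One examination is one sample:
its 1–3 phases are forwarded jointly through the fusion network.
Augmentations mirror acquisition variability: random flips applied
identically to all phases of an exam (flipping per-phase would destroy
the co-registration the attention relies on), random phase-subset
simulation of missing phases, and random input order.  The validation
split (fraction 0.2) is stratified by phase-set composition and seeded.

Two presets exist.  The full-scale recipe — 192³ inputs, 18-layer
extractor (4 stages, 64–512 channels), 1000 epochs at base LR 1e-5 — is
configured but not exercised here.  The desk preset used throughout the
tests is a miniature of the same architecture: 32³ (or 24³) inputs, 3
stages of 8/16/32 channels with attention after stage 2, tens of epochs
at base LR 1e-3 (scaled up because the miniature's loss landscape is far
better conditioned than the full-size one).  Batch size 4 examinations;
He-normal weight initialisation, zero biases (both unstated in the
original recipe).

The numerical backend is a small float64 reverse-mode autodiff engine
over numpy (`ctphase.nn`) with im2col 3D convolutions.  It is fully
deterministic for a fixed seed, which the determinism contracts in the
test suite rely on.

## Synthetic phantoms

The phantom is an ellipsoidal liver containing tubular portal and
hepatic veins, with an arterial blood-pool column through the volume.
Unenhanced baselines are parenchyma 55 HU, blood pool 45 HU, background
30 HU.  Each phase volume is baseline + per-structure enhancement deltas
+ per-voxel Gaussian noise (SD 5 HU); a per-exam jitter (SD 3 HU) on each
mean delta emulates inter-patient variation.  Default deltas (HU):

| structure     | EAP | LAP | PVP | DP |
|---------------|-----|-----|-----|----|
| artery        | 250 | 220 | 90  | 60 |
| portal vein   | 5   | 45  | 110 | 70 |
| hepatic vein  | 0   | 5   | 95  | 60 |
| parenchyma    | 2   | 25  | 55  | 35 |

These encode the annotation criteria: EAP = strong artery only; LAP adds
moderate portal/parenchymal enhancement with the hepatic vein still
unenhanced; PVP = strong portal vein, hepatic vein and parenchyma; DP =
everything less enhanced than PVP.  The rule-based labeler
(`rule_label`) operationalises the qualitative criteria with numeric
cut-offs (artery strong ≥ 150, portal moderate ∈ [25, 80), portal strong
≥ 80, hepatic vein unenhanced < 20 / strong ≥ 80, parenchyma strong
≥ 40; all configurable, since the criteria themselves are qualitative).
The PVP/DP decision prefers a same-exam PVP reference when available and
falls back to the absolute cut-offs.  Default deltas keep ≥ 5σ margins
to every binding cut-off so the generate → measure → label round trip
is the identity for any seed at the default noise level.

Edge-case generators place exams near the decision boundaries seen in
clinically misidentified examinations: an EAP with ~12 HU portal
enhancement (slight arterial-phase portal "flash"), an LAP just above
the moderate cut-off, and a nearly flat PVP/DP pair (portal difference
~34 HU, hepatic vein ~9 HU).

What the phantom does *not* emulate: real anatomy, lesions, respiratory
motion or inter-phase misregistration, scanner/manufacturer effects,
beam hardening.  Passing tests therefore demonstrate that the
architecture, cascade and statistics behave as specified on separable,
co-registered data — they do not certify clinical accuracy, and the
published clinical accuracies are checked only at the level of the
metric formulas applied to the published confusion counts.

## Desk-scale experiments

Two seeded experiments anchor the learning claims.  (1) A 3-class
miniature trained for 30 epochs on 60 phantom exams (32³) reaches ≥ 90%
held-out step-1 accuracy (in practice 100%).  (2) On an "EAP/LAP-hard"
cohort whose arterial appearances are identical except for the portal
vein delta (~12 vs ~30 HU, pulled toward the moderate cut-off), the
cascade's phase-wise accuracy is at least the one-step model's,
aggregated over 5 seeds (24³, 48 training exams, 20 epochs per model).

The mechanism behind (2) at desk scale is worth stating plainly: the
portal-only cue sits below what the miniature extractor reliably
detects, so *both* strategies hover near chance on EAP vs LAP.  The
cascade still wins because its 3-class first step stays essentially
perfect, while the 4-class model — forced to carve the hard arterial
split and the easy splits with one decision — degrades on PVP/DP as
well.  That is the decomposition argument in miniature: fewer
simultaneous distinctions, better performance on each.

## Numerical conventions

* Window normalisation maps [WL − WW/2, WL + WW/2] linearly onto [0, 1]
  and clamps outside (WL 50 / WW 600 by default; whether the original
  preprocessing clamps or rescales is unstated — clamping is assumed).
* Resampling is trilinear (order-1 spline, no overshoot);
  nearest-neighbour is appropriate for masks.
* The reported "AUC" of an argmax classifier is balanced accuracy,
  (sensitivity + specificity)/2 — the exact area under the one-vertex
  ROC of a hard classifier.  This reproduces all 12 published AUC values
  to 3 decimals.  A score-based Mann–Whitney ROC AUC is available when
  probability outputs exist.
* Table rounding is decimal half-up (96.875 → 96.9), 1 decimal for
  percents and 3 for AUC; Python's builtin banker's rounding does not
  reproduce the printed cells.
* 95% CIs use Wilson by default (Clopper–Pearson selectable).  The
  published brackets match neither method exactly (their procedure is
  unstated), so CI values are reported but not regression-tested.
* Zero-denominator metrics are undefined (`None`), never 0.
* Focal loss clamps p_t at 1e-7; the autodiff path clamps inside the
  logarithm (log(p+ε)), the closed-form path outside (max(p, ε)) — they
  agree to O(ε/p_t).

## Known limitations

* The full 192³ / 1000-epoch configuration is provided but unexercised;
  all empirical statements here are desk-scale.
* The miniature extractor cannot detect portal-only arterial differences
  near the moderate cut-off (see above); at full scale and cohort size
  this is exactly the regime the published misidentification analysis
  describes.
* The published AUC-difference p-values between strategies are not
  reproduced (their computation method is unstated); `compare_strategies`
  deliberately emits none.
* Phantoms are co-registered by construction; the method's sensitivity
  to misregistration is out of scope.
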