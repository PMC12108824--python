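# Methods

## Signal model of the synthetic sessions

Each humidity channel follows first-order relaxation toward a
posture-dependent contact level,

    h_k(t_i) = L_k(p_i) + (h_k(t_{i-1}) − L_k(p_i)) · exp(−Δt/τ),

with τ = 120 s by default. The contact profile L_k(p) is a Gaussian bell
(width 1.5 sensor pitches) between a dry baseline of 35 %RH and a contact
plateau of 85 %RH, centred one pitch in from the left end (left posture),
at the array centre (supine), or one pitch in from the right end (right).
On a 7-sensor array this loads roughly three adjacent sensors per posture
and gives the two end sensors the largest left-vs-right contrast with
opposite signs — the qualitative structure real pillows show. Independent
Gaussian noise (default sd 0.5 %RH, i.e. well inside the DHT22's ±2 %RH
band) is added and the result clipped to [0, 100].

τ = 120 s was chosen once as a moisture equilibration time that produces
gradual-but-clear level shifts over a few minutes; it is configurable. The
sessions default to 4 h at 10 s sampling. Temperature channels drift
monotonically at 0.4 °C/h with 0.05 °C noise and are deliberately ignored
by detection; ambient channels are slow AR(1) fluctuations around room
conditions (24 °C, 45 %RH) and exist to exercise I/O. Schedules hold each
posture for at least 10 min; transition times are drawn by a minimum-gap +
Dirichlet-leftover construction snapped to the sampling grid, which
generates any feasible transition count directly.

**What the generator does not emulate:** physiological sweating dynamics
and sleep-stage coupling, apnea/snoring, partial head contact, sensor
drift and dropout, pillow-material memory effects, and inter-subject
variability in contact levels. Passing tests therefore demonstrate that
the *algorithms* recover known structure under realistic noise, not that
the method achieves any particular accuracy on real sleepers.

## Flux statistic

Two aggregations of per-sensor change are provided. The windowed std-sum
flux computes, per trailing 1-min window (≥ 6 samples at 10 s), each
sensor's population standard deviation (divisor N, as a within-window
dispersion, not an estimator) and sums across sensors; the sliding variant
(1-sample stride) is the default detection input, with a tiled
(disjoint-subinterval) variant retained. The squared-change sum
Σ_k (h_k(t) − h_k(t−1))² prevents simultaneous rises and falls from
cancelling. Both are min-max normalized by default so thresholds (0.43 on
the squared-change sum; 0.16 on the flux rolling average) and segmentation
penalties live on a comparable scale across subjects and sensor subsets.
Partial windows at the series start use the available samples, keeping the
flux defined from the first sample.

The nominal smoothing window of 10 s equals the transmission period, i.e.
a single sample; the smoother therefore takes its window in seconds as
explicit configuration rather than hard-coding a no-op.

## Change-point detection

The flux is near zero while posture is held and elevated in a burst while
the head moves, so detection is penalized segmentation with the L2
(segment-mean) cost C(y_{a..b}) = Σ (y_i − ȳ)². PELT implements the exact
optimal-partition recursion with pruning; we use the conservative rule
(drop candidate s only when F(s) + C(s,t) > F(t) + β), which preserves
exactness for this concatenation-subadditive cost — agreement with an
unpruned O(n²) DP is asserted over hundreds of random series in the test
suite. The minimum segment length is 2 samples (20 s), preventing
singleton noise segments. Binary Segmentation accepts greedy bisections
while the cost reduction exceeds the penalty; BOCPD runs the standard
run-length posterior (Normal observations, Normal-Inverse-Gamma prior,
constant hazard 1/200, weakly informative defaults μ₀ = series mean,
κ₀ = 1, α₀ = 1, β₀ = series variance) and declares a change where the MAP
run length resets. BOCPD is known to be sensitive to these priors; they
are exposed as parameters.

**From boundaries to posture changes.** A movement burst has an entry and
an exit boundary in any segmentation. Only rising edges — boundaries where
the segment mean increases by at least `min_rise` (default 0.1 on the
normalized flux) — are reported as posture changes, with events closer
than a 60 s refractory gap merged (first kept). A trailing flux window
first reacts one sample after the physical transition, so event times are
corrected by one sample (`lag_correction_samples = 1`). A half-window
correction of (w−1)/2 samples was considered and rejected: empirically the
L2-optimal rising edge sits at the burst onset (the first window touching
the transition), not at mid-rise, and over-correcting by 2.5 samples moves
detections outside the ±10 s matching tolerance; with the 1-sample
correction, noise-free transitions are recovered to within one sampling
period.

The penalty is grid-searched per subject/session (0.05–0.5, step 0.01)
maximizing F1 against ground truth, ties broken toward the larger penalty
(the sparser model). Evaluation matches detections to true transitions
one-to-one, closest pairs first, within ±10 s; with both sets empty,
precision = recall = F1 = 1 by convention.

## Sensor-subset search

"Same segments as the full array" is operationalized strictly: a subset
matches when its posture-change count equals the 7-sensor reference count
*and* every reference change is matched one-to-one within the tolerance.
The reference penalty is reused across subsets so that differences reflect
sensors rather than tuning; `regrid=True` re-searches per subset. Superset
monotonicity is *not* assumed (adding a noisy sensor can change the
normalized flux); determinism of the search is asserted instead.

## Curve-image classification

Windows of 10 min are rendered as humidity-curve images: the selected
channels min-max normalized **jointly** over the window (per-channel
normalization would erase the level ordering that encodes posture), drawn
as fixed-color polylines on white at 2× resolution, downsampled to
224×224×3. Labels come from the majority posture within the window; exact
ties go to the later posture.

The classifier is the compact CNN conv(32, 3×3) → maxpool 2×2 →
conv(64, 3×3) → maxpool 2×2 → flatten → dense(128, ReLU) → softmax(3),
implemented directly on numpy (im2col convolutions; He initialization;
float32 throughout; bit-reproducible given the seed). Training uses a
stratified 80/20 split, SGD with learning rate 0.01 and momentum 0.9,
batch size 32, at most 30 epochs with early stopping on validation loss
(patience 6, best weights restored; training also ends once the monitored
loss reaches 0.02, i.e. has converged).
The patience is deliberately generous: on some seeds the validation loss
dips, rises for several epochs while the minority classes reorganize, and
only then descends to convergence — a short patience window freezes such
runs at the transient dip. Class weighting uses inverse-frequency weights
w_c = N/(n_classes·N_c) against the supine-dominated 438/66/24 mix.

Numerical choices that matter: the class-weighted loss is a weighted
*mean* over each batch (normalized by the batch's weight sum), and
gradients are clipped to global norm 1.0. Without these, a batch rich in
weight-7.3 minority samples can take a step large enough to kill the dense
ReLU layer early in training, after which only the output bias learns
(validation loss pinned at ln 3). Images enter the network scaled to
[0, 1] and resized to the classifier's `input_size`, default 96×96 — a
scaled-down training resolution chosen to keep a full three-seed benchmark
on a single CPU at desk scale; rendering stays at 224×224 and the
resolution is configurable.

The binary change/no-change report orders validation windows by time
within each session and flags a change whenever consecutive predicted
labels differ, compared against the same rule applied to true labels. This
is an interpretation — the binary matrix construction is not otherwise
procedural — and is documented as such. The classifier sits behind a
plain scikit-learn estimator interface, so alternative backends (e.g.
pretrained transformer encoders) can be swapped in as an extension.

## Benchmark problem sizes

The standard change-point benchmark uses 20 sessions of 4 h (1440 samples)
with 6–20 transitions each; the classifier benchmark uses 528 windows
(438/66/24) per seed over three seeds. These sizes keep the full suite at
desk scale while leaving dozens of transitions and hundreds of validation
windows to average over.

## Known limitations

- All accuracy figures are on synthetic data; the generator's idealized
  contact model makes classes more separable than real recordings.
- Detection is offline (full-session normalization and grid search);
  no streaming variant is provided.
- The penalty grid search requires ground truth and is therefore a
  calibration procedure, not a deployable estimator.
- BOCPD results depend visibly on prior settings; defaults are weakly
  informative, not tuned.
- With head motion absent (e.g. limb-only movement), nothing is detectable
  by construction.
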