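# Methods

## The advising model

Both advised classifiers post-process a standard kernel SVM; the
quadratic program itself is delegated to libsvm (via scikit-learn's
`SVC`/`NuSVC`) and the package's own contract is the reconstruction
check: decision values recomputed from the stored support vectors,
signed dual coefficients `α_i y_i`, and bias must match the solver's
output to 1e−6 (enforced at training time, and to 1e−9 through the JSON
round trip).

The advising layer assumes that a training point the fitted machine gets
wrong marks a region where the decision surface is locally untrustworthy,
and that the *true* label of that point is better evidence there than the
SVM's sign.  Its reach is limited by the neighborhood length
`NL(x_i)` — the kernel-induced distance from the misclassified point to
the nearest correctly classified point of a different label — so a lone
flipped label deep inside a foreign cluster gets a small radius, while
a point in a genuinely contested region gets a larger one.  The layer is
non-iterative by design: it never retrains or re-advises.

Distances are always the kernel-induced metric
`d(u,v) = (k(u,u)+k(v,v)−2k(u,v))^{1/2}`, with the radicand clamped at 0
before the root to absorb floating-point negatives (vectorized BLAS paths
can land a hair below zero for near-identical points).

### The advised-weight aggregation

The printed form of the advised weight is typographically corrupted in
its source; this package defines

```
AW(x_k) = mean over {i ∈ MD : d(x_k, x_i) ≤ NL(x_i)} of (1 − d/NL) ,
```

zero when MD is empty or no neighborhood qualifies.  The mean form is
bounded in [0,1] by construction, reduces exactly to the two zero
branches, and matches the stated intent (a score of how deep the test
point sits inside misclassified neighborhoods).  The choice is recorded
in the serialized model as `normalization: "mean"`.

### The decision rule and its edge cases

Per test point: if `AW < |h| / max_batch |h|` the SVM label stands;
otherwise the point takes the true label of the nearest qualifying MD
point (ties to the smallest MD training index).  Consequences of reading
the rule exactly as printed:

* equality routes to the relabeling branch (the SVM branch is a strict
  `<`);
* scaling is per test batch; a single-point prediction scales by its own
  `|h|`, making the scaled value 1 — batch prediction is the intended
  mode;
* if the relabeling branch is selected but no MD neighborhood contains
  the point (both sides zero), the base label stands;
* MD points with no correctly classified, differently labeled neighbor
  have no contrast to measure against; they are flagged and excluded
  from advising rather than given an arbitrary finite radius.

### Label-space advising

LSA-SVM measures neighborhoods between numeric label encodings:
signed ±1 for two classes, one-hot for more (integer codes available).
The label distance is plain Euclidean by default; the kernelized form
with a label-space RBF is behind a configuration switch, since both
appear in the method's description without a stated choice.  Two
interpretation decisions, both recorded here because the method's
description leaves them open:

* the advised weight needs the test point's label, which is unknown at
  prediction time; the base SVM's predicted label is used — it is the
  only label available before advising, and the rule's fallback branch
  presumes the base prediction exists;
* the relabeling target is the qualifying MD point nearest in *feature*
  space, because with few classes the label metric is too coarse to rank
  candidates (for two classes every label distance is 0 or 2).

The two-class case is therefore degenerate: `NL ≡ 2`, every MD point
qualifies, and LAW collapses to the fraction of MD sharing the predicted
label.  On noisy two-class data with many low-confidence points this can
*lower* accuracy (low-`|h|` points inherit noisy MD labels); the package
reproduces this faithfully rather than patching it, and the degeneracy is
asserted exactly in the tests.  It also means the label-space variant's
advantage is computational (label vectors of length ≤ L versus d feature
dimensions per comparison), not geometric, in the binary case.

Multiclass problems are reduced one-vs-one with majority vote (ties to
the earliest class in sorted class order).  The advising rule needs a
scalar confidence per point; the vote winner's smallest pairwise `|h|`
over its machines is used — the weakest link of the winning class —
which reduces exactly to `|h|` for two classes.

## Signal pipeline

Conditioning defaults are the conventional sEMG choices: 4th-order
Butterworth band-pass 25–550 Hz and an IIR notch at 50 Hz with quality
factor 30, both applied forward-backward (zero phase, so annotations stay
aligned); polyphase resampling to 1000 Hz (1080 Hz or any other target is
a parameter — the band edges and orders are configurable too, since only
the bands are inherent to the method).  Windows are specified in samples
(50/15 at 1000 Hz ≙ 50 ms / 15 ms); each window takes the majority label
of its per-sample annotations, ties toward the earlier label in sorted
class order, and rest-labeled windows are dropped.  The majority rule and
rest-dropping are this package's own conventions — continuous recordings
need *some* window-labeling rule and none is standard.

Time-domain features use the classical definitions; ZC counts sample
pairs with product ≤ 0 (a sampled zero at a crossing counts once) and an
amplitude gap above threshold, SSC counts interior slope-sign changes
with at least one adjacent difference above threshold.  Thresholds
default to 1% of the window's own RMS — an adaptive noise gate — and can
be pinned explicitly.  The integer feature-set codes (11, 13, 14) map to
{MAV,WL,ZC}, {MAV,RMS,WL,ZC}, {MAV,RMS,WL,ZC,SSC}; the mapping is
provisional configuration (the codes' original key is not published).
Optional per-feature z-scoring is fitted on training folds only.

## Evaluation

Folds are stratified with a caller-supplied seed; the sizing rule is
3-fold for n > 1000, 5-fold otherwise.  The benchmark reuses identical
folds across all six classifiers (c/ν × plain/SA/LSA), so comparisons are
paired.  Sensitivity/specificity are one-vs-rest, macro-averaged unless a
positive class is declared.  Training time is reported but never asserted
— it is hardware-bound.  The `(C, γ)` grid search covers the 20 powers of
two from 2⁻⁹ to 2¹⁰ on each axis (400 combinations); ν-SVM reuses the γ
grid with ν ∈ {0.05, …, 0.5}, and single fits default to ν = 0.1, since
no principled mapping from penalty-style values to ν exists.  Grid ties
break toward smaller C (or ν), then smaller γ.

## Synthetic data

`make_blobs` draws spherical Gaussian clusters (default centers 6 apart
on the first axis) and flips exactly `round(noise·n)` labels, recording
ground truth — a stand-in for small tabular benchmarks.

`make_planted_fixture` is engineered so the advising layer provably
corrects the base SVM: clusters at ±2 (spread 0.45, 40 points each),
three +1-labeled points planted near x ≈ −0.9 on the −1 side, and a
deliberately smooth machine (RBF γ = 0.2, C = 1) that cannot carve
islands around them — so they are genuinely misclassified.  Three test
points sit essentially on top of them with true label +1: the base SVM
is wrong there with small `|h|` relative to the batch, while the advised
weight is near 1.  The generator *verifies* all of this by running the
base SVM and the advised rule, retrying with a fresh sub-seed (up to 10)
if a draw fails, so tests never silently exercise the wrong branch.

`make_semg` emulates the recording protocol: 4 channels at 2000 Hz, per
movement class one trial of 3 s activity and 5 s rest, repeated; activity
is class-specific per-channel envelope gains (each class drives a
different dominant channel) modulating white Gaussian noise, with
~100 ms raised-cosine ramps, plus a 50 Hz line sinusoid (amplitude 0.3)
and baseline noise (σ = 0.05).  This is an amplitude model: it exercises
every filtering, windowing and feature stage and yields a cleanly
separable 4-class problem at the default signal-to-noise ratio, but it
has no motor-unit physiology, no crosstalk, no electrode-shift or fatigue
nonstationarity.  Tests passing on it show the pipeline and the advising
mechanics are correct — not that clinical-grade accuracy transfers to
real patients.

## Problem sizes and numerics

The shipped analyses use one repetition of the 4-class protocol
(64 s of signal, ~800 windows of 20 features) with 3-fold CV, blob
fixtures of 40–200 points, and 10 draws of the planted fixture — sizes
chosen so every experiment reruns from scratch in seconds while leaving
each effect (advising corrections, reduction to the base SVM, the
degeneracies) comfortably visible.  Model serialization stores floats at
full repr precision, so reload reproduces decision values bit-for-bit;
cross-path kernel computations (batched vs pairwise) agree only to ~1e−14
because of BLAS ordering, which is why exactness claims in tests are at
1e−9 rather than bitwise.
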