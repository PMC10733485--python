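# Methods

## Problem and model

Two-class motor-imagery EEG decoding rests on event-related
desynchronization (ERD): imagining a movement suppresses the amplitude
of mu (7–13 Hz) and beta (13–30 Hz) rhythms over sensorimotor cortex.
Which channels, which narrow band, and which latency window carry the
contrast varies across subjects, so a decoder that fixes any of the
three loses accuracy. This package implements a joint optimizer over
all three domains.

The unit feature extractor is the common spatial pattern (CSP). For
class covariance matrices C₁, C₂ it solves the generalized eigenproblem

    C₁ w = λ (C₁ + C₂) w,

keeping the m eigenvectors with the largest and the m smallest λ
(m = 1 by default, so 2 filters). The per-trial feature is
f_p = log(var((Wᵀ X)_p)). Per-trial covariances are trace-normalized
before class averaging, removing global amplitude nuisance, and the
class means are shrunk by a fraction α toward (trace/M)·I
(default α = 0.05) so the eigenproblem stays well conditioned when the
window is short relative to the channel count.

The analysis grids are: 17 overlapping sub-bands of 4 Hz width every
2 Hz covering 4–40 Hz; 2 s time windows every 0.5 s (5 windows in a 4 s
epoch, 4 in a 3.5 s epoch); and nested channel modes — the top-16,
top-32 and all channels ranked by the Fisher discriminant criterion
(FDC) of segment log-power, where each channel's score is the maximum
over overlapping 1 s segments of (m₁−m₂)²/(var₁+var₂). One *view* is a
(channel mode, time window) pair whose feature matrix stacks the 2m CSP
features of all k sub-bands (N × 2mk, band-major).

Feature selection couples the views through an L2,1-penalized
least-squares problem on the shared ±1 label vector y:

    U* = argmin_U ½ Σ_v ‖V_v u_v − y‖² + λ‖U‖₂,₁ ,

where ‖U‖₂,₁ sums the L2 norms of the rows of U (features × views).
The row-wise penalty zeroes whole feature rows, selecting CSP features
jointly across views. λ is parameterized as a fraction of λ_max, the
smallest penalty whose solution is exactly zero, making the grid
{0, 0.1, …, 1} scale-free with a guaranteed all-zero endpoint at 1.

The *sparsification step* then refines the selection per view: restrict
U to its non-zero rows (Q), sort each row's views by |weight| (R), and
keep only each row's Ns strongest views, with candidate sets nested in
Ns by construction. Zero-weight entries inside a surviving row are
never selected. The final features feed an RBF-kernel SVM (C = 1,
kernel width by the variance-scaled heuristic) on z-scored columns.

## Hyperparameters and protocol

λ ∈ {0, 0.1, …, 1} and Ns ∈ {1, …, S·T} are chosen by stratified 5-fold
cross-validation *inside* the training folds. λ = 1 always yields zero
features and is excluded; a λ whose solution is all-zero in any inner
fold is likewise excluded. Accuracy ties resolve to the largest λ
(sparser support at equal accuracy) and then the smallest Ns. Because
the support boundary shifts slightly with the training-set size, the
inner-CV λ can occasionally zero every row when re-solved on the full
training set; fitting then steps down to the next smaller grid λ.

The FDC ranking, CSP bank, feature standardization, solver,
sparsification and SVM are all refit from the training folds of each
outer split — the outer test fold touches no fitted component. Channel
ranking inside the inner loop is likewise recomputed from the inner
training folds.

Evaluation is stratified outer 5-fold accuracy (fraction correct;
classes are balanced by design of the generator). All folds derive from
one master seed, and the comparison decoders reuse the same outer folds
for paired comparison.

## Numerical choices

* Filtering: 5th-order Butterworth, applied forward–backward
  (zero-phase; effective order 10). The pipeline is offline, and
  zero-phase filtering keeps the time grid aligned with cue-locked
  latencies. Sub-band filters run on the full epoch before window
  slicing to keep filter edge artifacts out of the 2 s windows.
* Windows use half-open, 0-based sample indexing
  [round(start·fs), round(end·fs)).
* Variance is the biased (1/T) estimator with the mean removed;
  FDC within-class variances use ddof = 1.
* Eigenvector signs are fixed so each filter's largest-magnitude entry
  is positive (reproducible across linear-algebra backends). FDC ties
  break toward the lower channel index.
* The solver is FISTA with step 1/L (L = largest per-view Gram
  eigenvalue), a function-value restart that guarantees a monotone
  objective trace, relative-change tolerance 1e-6 and at most 1000
  iterations. Rows with norm ≤ 1e-8 × max row norm count as zero.
* Per-trial covariances per (band, window) are computed once per
  dataset and reused across folds; CSP fitting averages them and the
  log-variance features are quadratic forms in them, algebraically
  identical to filtering and projecting raw signals per fold.

## The synthetic generator

`SyntheticSpec` plants a known ERD effect: per channel an independent
1/f background (exponent 1), a shared common-mode 1/f component
(removed exactly by CAR), and on the active channels a band-limited
oscillation made by band-pass filtering white noise (realistic
within-band variance, unlike a pure sinusoid). Class-2 trials multiply
the oscillation amplitude by `attenuation` inside the ERD window, with
100 ms raised-cosine ramps at the edges to avoid filter-ringing
confounds. Defaults: 100 trials/class, 20 channels at 100 Hz for 4 s,
active channels C3/C4, band 10–14 Hz, window 0.5–2.5 s, attenuation
0.5, background σ = 1, common mode σ = 0.5, oscillation σ = 2 (a
prominent mu rhythm, a few times the in-band background power, so the
planted 1/attenuation² power contrast dominates in-band variance).
Channel names come from a fixed 10–20 list ordered so the default
active indices are C3 and C4 and the anchor-channel baseline resolves.

Because the planted effect is a one-sided amplitude suppression, the
discriminative signal concentrates in the *maximum*-variance CSP
feature of the matching band; the minimum-variance twin carries no
independent information, and under the largest-λ tie rule the selected
support is deliberately minimal. Recovery is therefore assessed at the
band level (the support contains a feature row of the planted band).

What the generator does not emulate: volume conduction (active sources
appear on single channels), ocular/muscular artifacts, trial-to-trial
nonstationarity, or multi-band effects. Passing recovery tests shows
the estimator chain recovers planted second-order structure under these
idealized conditions, not that real-data accuracies are reproduced.

The tiny `checkerboard_case` fixture (20 trials, 6 channels, 2 s, one
active channel, whole-epoch attenuation 0.3, no common mode,
oscillation σ = 1.5 against background σ = 1) is sized so its
by-construction properties hold: with a shared common-mode component
CSP legitimately spreads weight across channels to cancel it, and with
a negligible in-band background the trace normalization washes out a
single dominant channel — both are avoided by design.

## Comparison decoders

All baselines share preprocessing, the CSP implementation, the SVM and
the outer folds. FBCSP ranks features by a plug-in mutual-information
estimate (equal-frequency 8-bin histogram — deterministic and adequate
for ranking) and keeps the top-4 bands by the mean MI of each band's
features. SFBCSP selects band features by an L1 least-squares fit whose
penalty fraction γ ∈ {0, 0.01, …, 1} (of the all-zero bound) is tuned
by inner CV, ties toward larger γ. DFBCSP ranks bands by the Fisher
ratio of the anchor channel's whole-epoch log band-power (whole-epoch
rather than segmented, as the simpler convention). MSO is the
multi-view model restricted to the single 0.5–2.5 s window with every
non-zero row kept — the pipeline without the time-level sparsification.

## Benchmark sizes

The shipped verification suite uses the generator's default conditions
with the channel modes scaled to the 20-channel montage (8/16/all).
Monte-Carlo sizes: 100 seeds for channel- and band-recovery rates, 20
seeds for accuracy medians and method ordering, 3 permutation and 2
no-effect control runs; the reproduction script uses 10 seeds for the
accuracy medians. These sizes give stable medians and rate estimates
with 5% resolution at the 100-seed level.

## Known limitations

* Two classes only; multi-class CSP extensions are out of scope.
* Offline (zero-phase) filtering; causal decoding is not supported.
* The BCI-competition recordings the protocol was designed around are
  not bundled; the HDF5/NPZ container is the supported input.
* SVM hyperparameters are fixed defaults (config-overridable), not
  tuned per subject.
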