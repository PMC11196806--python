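# Methods

This note documents the models, numerical choices and limitations behind
`eegperm`, in the order data flows through the pipeline.

## Synthetic recordings

Each channel is a sum over the six analysis bands of band-limited Gaussian
oscillations plus a white noise floor. For band *b* with shared-source gain
*g_b*, channel *c* receives

    x_bc = [ g_b · a_c · s_b + (1 − g_b) · p_bc ] / sqrt(g_b² + (1 − g_b)²)

where `s_b` is one band-wide common source, `p_bc` a channel-private
source, and `a_c ∈ {−1, +1}` a per-channel projection sign drawn once per
band. All sources are unit-variance white noise passed through the same
Kaiser band-pass design used by the preprocessing stage (consistency over a
second filter implementation), normalized analytically by the kernel
energy ‖h‖₂, so no per-call calibration loop is needed. Components are
scaled by √(w_b) so the expected relative power matches the configured
`band_weights` after normalization to their sum; the recovery tests verify
this empirically to ±0.05.

The projection signs `a_c` are the one deliberate departure from the
plainest mixing scheme: with a spatially uniform projection the common
source appears identically in every channel and the common-average
reference subtracts it *exactly*, leaving zero shared-source coherence for
the downstream stages to detect. Real cortical sources reach the electrodes
with spatially varying topographies; unit-magnitude random signs are the
smallest model of that fact which leaves both the pairwise coherence
magnitude and the power calibration untouched.

With equal gains on two channels the magnitude-squared coherence is
g⁴/(g² + (1−g)²)², e.g. ≈0.02 at the default g = 0.3 and ≈0.48 at
g = 0.6 — so the default post-intervention gain increase of +0.3 in the
treated group produces a coherence change of roughly +0.3 after subtracting
the Welch bias floor.

Defaults encode the study geometry: 62 channels (10-10 subset, AFz reserved
as ground), 2048 Hz, 120 s, 13 subjects per group. The resting band-weight
profile (delta 0.25, theta 0.20, alpha1 0.15, alpha2 0.10, beta1 0.15,
beta2 0.10) is a typical eyes-open resting distribution with a mild
low-frequency dominance as seen in mild cognitive impairment. The treated
group's post-session effect defaults to delta and theta power ×0.7, beta2
×1.3 and coherence gain +0.3 — the *directions* are the phenomenon of
interest; the magnitudes are simulation settings chosen to be clearly
detectable at n = 13, not estimates of any clinical effect size.
Subject-to-subject variation is log-normal multiplicative jitter
(σ = 0.1) on band weights, shared between a subject's sessions so that
paired contrasts cancel it, as trait-like power differences do in real
data.

What the generator does **not** emulate: 1/f spectral background beyond the
band weights, realistic blink/EMG morphology (artifacts are stylized
spikes, steps and bursts), volume-conduction mixing, and nonstationarity
within a session. Passing tests therefore demonstrate the *statistical
machinery* — calibration, power, directionality — on signals with the
study's spectral and coherence structure, not robustness to every
physiological nuisance in clinical EEG.

`null_power_maps` provides the exchangeable null for calibration runs at
the level the cluster test actually consumes (subject × channel power
maps, spatially correlated with a squared-exponential kernel, pre and post
i.i.d.); generating 200 full signal-level studies would test the same null
hypothesis at ~1000× the cost.

## Preprocessing

The band-pass is a linear-phase Kaiser FIR (β = 5.653 ↔ 60 dB, 1 Hz
transition, 0.5–40 Hz). The tap count comes from the Kaiser
order-estimation relation, rounded to an odd (type-I) count, then nudged
upward in steps of two until the realized kernel's DC leakage |Σh| meets
the design attenuation — a band-pass kernel is a difference of two
low-pass designs and its DC residual oscillates with the exact length. At
2048 Hz the estimate is 7426 taps (order 7425). The kernel is applied by
centred FFT convolution on reflect-padded data (exact group-delay
compensation for a symmetric kernel), then the signal is decimated to
512 Hz (anti-aliasing already guaranteed by the 40 Hz cutoff against the
256 Hz Nyquist) and re-referenced to the common average. Filtering precedes
decimation; rejection runs after conditioning — the criteria are
amplitude-based, so this ordering is second-order.

Epoch rejection evaluates four per-channel criteria (100 µV absolute;
150 µV peak-to-peak, 200 ms window/100 ms step; 100 µV half-window-mean
step statistic, 200 ms window/50 ms step; 50 µV consecutive-sample jump).
The "step function" statistic is the absolute difference between the means
of the two halves of the window, the standard detector for the quasi-step
deflections of saccades and blinks. Sliding windows always include the
final fully-contained window so epoch tails are never unexamined. Any
criterion on any channel rejects the whole epoch; no channel interpolation
is attempted.

## Spectra and band power

Per-epoch spectra are one-sided Hann-taper periodograms scaled as
densities (their integral equals the tapered signal's mean power). Band
edges are half-open (low ≤ f < high): the printed band edges touch at 4,
8, 11, 14 and 25 Hz and a shared bin must be counted once; assigning it
upward is the convention here. Relative power normalizes by total power
over 0.5–40 Hz (the conditioned pass-band), not by the six-band sum, so
the six values sum to slightly below 1 (the 35–40 Hz remainder). Epochs
must span ≥2 s so the grid resolves the 0.5 Hz delta edge.

Pre/post difference features pair the k-th kept pre epoch with the k-th
kept post epoch and truncate to the shorter list; no within-session
ordering information is used beyond the index. For the cluster test, epoch
band powers are averaged per subject — the permutation unit is the
subject, and per-epoch resolution would only add within-subject noise.

## Cluster-based permutation test

The cluster-forming statistic is the dependent-samples t on d = post − pre
(sample sd, n−1). The adjacency graph links electrodes within 1.3× the
median nearest-neighbour distance on the unit head sphere, which on this
62-channel template yields a single connected component with mean degree
≈4. Clusters are connected components of same-sign suprathreshold
channels; the cluster statistic is the signed mass (sum of t), with
cluster size available as an alternative. The default cluster-forming
threshold is the two-sided parametric t critical value at α with n−1 df —
conventional, and configurable since no principled default exists.

The null randomizes the sign of each subject's difference vector (the
exchangeable transformation for a paired design) and records the maximal
|mass| over channels and both signs; observed clusters receive
+1-corrected Monte-Carlo tail p-values, so p ≥ 1/(n_perm+1) and the
procedure controls the family-wise error non-asymptotically. Inference is
two-sided via the max-|mass| null, matching a study design where both
power decreases and increases are of interest. Sign flips change the mean
of d but not its per-channel sum of squares, so all permutation t-maps
reduce to one matrix product — this is what makes 200-study calibration
runs affordable.

The exact variant enumerates all 2ⁿ sign assignments (refusing n > 12) and
reports plain tail fractions; the identity assignment is always in the
orbit, so p ≥ 2⁻ⁿ without correction. A float-tolerant comparison counts
the identity's tie with each observed mass (the two are computed through
different code paths). The Monte-Carlo p converges to this exact p and the
test suite checks agreement to ±0.01 at 50 000 permutations, plus
agreement of clusters, masses and p-values with MNE-Python's independent
implementation of the same procedure.

Degenerate channels (zero-variance differences) get t = 0 when the mean
difference is also zero and ±∞ otherwise, with a warning either way.

## Coherence

A single Welch segment makes MSC identically 1, so each 5 s epoch is
subdivided into 1 s Hann segments with 50% overlap (9 averaging segments);
the code refuses fewer than two segments with an explanation. The
all-channel cross-spectral matrix is computed in one vectorized pass
(segment FFTs once, outer products) and is tested bin-for-bin against
scipy's per-pair estimator. K averaging segments leave a bias floor of
about 1/K on independent signals — with 9 segments per 5 s epoch that
floor is ≈0.11, which is why coherence *changes* rather than raw values
are the quantity compared between groups. Region-pair coherence averages
MSC over all cross-region channel pairs and over band bins (unweighted).
Pairs of regions in opposite hemispheres are inter-hemispheric; pairs
involving the shared occipital region are counted with the
intra-hemispheric set, as region pairs like right-temporal–occipital
conventionally are.

The headline comparison is the unpaired rank-sum test on per-subject mean
pre→post changes between groups; a paired signed-rank variant for
within-group pre-vs-post contrasts is also provided. The exact rank-sum
null is used when the pooled sample is ≤25 without ties, the tie-corrected
normal approximation otherwise. Raw p-values are reported with
Benjamini–Hochberg adjusted values alongside, since 21 region pairs × 6
bands is a sizeable family.

## Classification

Splits are at the subject level: all epochs of a subject stay on one side
of the 70/30 split. This is the single most consequential design decision
in the pipeline — epochs of one subject are strongly correlated, and an
epoch-level split lets the classifier recognize *subjects* rather than
intervention effects; the suite demonstrates the inflation directly on
identity-only features (epoch-level mode exists precisely for that
comparison). Features are standardized with training-set statistics only.
The classifier is an RBF-kernel soft-margin SVM with C = 1 and the
inverse-feature-count kernel width — deliberately default-valued, since no
hyperparameter search is part of the protocol. Twenty random splits are
averaged; the per-run spread is reported. Per-channel maps repeat the full
protocol with one channel's feature at a time.

A group-size note: the sign-flip null has 2ⁿ atoms, so a global effect
cannot reach p < 0.05 with fewer than 7 subjects per group (2/2⁶ > 0.05);
simulation-based tests therefore use n ≥ 8.

## Problem sizes in the checks

The test-suite and acceptance-script simulations run at reduced scale
chosen for statistical clarity per unit compute: 256–512 Hz sampling,
15–40 s recordings, 4–8 subjects per group for signal-level studies, and
subject-level power maps for the 200-study calibration of the cluster
test. The counting checks (24 epochs per 2-minute recording, 312 feature
rows per 13-subject group) run at the full recording geometry, where they
are exact integer arithmetic.

## Known limitations

* EDF support targets continuous 16-bit single-session files (1 s records);
  BDF/BrainVision/FIF dialects are out of scope.
* The montage is a fixed 62-name 10-10 subset with template coordinates;
  studies with other caps must supply matching labels (coordinate-less
  channels are excluded from spatial analyses).
* Clustering is over channels within one band; joint channel × frequency
  clustering and threshold-free cluster enhancement are not implemented.
* No ICA or other component-based artifact removal: the pipeline expects
  pre-cleaned input and relies on threshold rejection.
* The independent-samples (group × time interaction) cluster test is a
  documented extension point, not implemented.
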