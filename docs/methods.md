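# Methods

This note records the models, defaults and numerical choices behind
`eegmodes`, and what the synthetic validation does and does not show.

## Signal model of the synthetic generator

The generator emulates the geometry of a clinical pre-seizure/seizure EEG
study: `n_subjects` (default 16) subjects, ten bipolar temporal/frontal
channels (Fp1–F7, F7–T1, T1–T3, T3–T5, Fp1–F3 left; Fp2–F8, F8–T2, T2–T4,
T4–T6, Fp2–F4 right), 100 Hz sampling, one-minute epochs, one pre-seizure
and one seizure epoch per subject. Each channel of each epoch is an
independent classification segment, so the default scale yields
16 × 10 × 2 = 320 segments with balanced labels.

Per channel the signal is

* background: 1/f-shaped Gaussian noise (spectral exponent 1.0), standard
  deviation 20 (microvolt-like arbitrary units) — a crude stand-in for
  broadband EEG background;
* alpha rhythm: a 10 Hz sinusoid of amplitude 6 with random phase;
* seizure activity (seizure class only): a 4 Hz sinusoid of amplitude
  `effect_size × 8` plus a half-amplitude 8 Hz harmonic, random phase.

`effect_size` (default 3) is the single class-separation dial; at 0 the
two classes are drawn from identical distributions, and the 3–5 Hz band
power gap grows linearly with it. A per-channel lognormal gain
(σ = 0.1) introduces amplitude heterogeneity. Randomness flows from one
master seed through `SeedSequence([seed, subject, epoch])` with one child
stream per channel, so any epoch can be regenerated bit-identically in
isolation.

What the generator does **not** model: volume conduction or any spatial
correlation between channels, artifacts (EMG, eye blinks, electrode pops),
nonstationarity within an epoch, seizure evolution, or inter-subject
variability beyond independent noise draws. Passing tests on this data
show the pipeline's mechanics and its analytic guarantees hold, and that
spectrally separated classes are recovered; they say nothing about
accuracy on clinical recordings.

Fractional Gaussian noise (`generate_fgn`) is synthesized exactly by
Davies–Harte circulant embedding of the fGn autocovariance
γ(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2; it is the ground-truth
long-memory process for validating the Hurst estimator (lag-1
autocorrelation 2^{2H−1} − 1 is checked against sample estimates).

## EMD and EEMD

Envelopes are natural cubic splines through the maxima/minima, with the
two extrema nearest each edge mirrored across the boundary before
fitting — the least end-swing-prone of the simple boundary rules.
Plateaus count as a single extremum at their midpoint.

Sifting of one IMF stops when the Cauchy criterion
SD = Σ(h_prev − h)²/Σh_prev² falls below `sd_threshold` (default 0.2)
**and** the iterate satisfies the IMF oscillation condition
(|#extrema − #zero-crossings| ≤ 1), capped at `max_sift_iterations`
(default 10). The SD test alone stops too early on broadband signals,
leaving first IMFs that badly violate the oscillation condition; adding
the condition to the stop rule brings the satisfaction rate on random
signals above 95% without raising the iteration cap. Mode extraction ends
when the residue has fewer than two maxima or minima (monotone residues
included) or at `max_imfs` (default 16, the largest mode count the method
is expected to produce on minute-long EEG). EMD is additive by
construction — the residue is defined as the input minus all extracted
IMFs — so reconstruction is exact to floating point.

EEMD adds Gaussian white noise of σ = `noise_fraction`·σₓ (default 0.2)
to each of `ensemble_size` (default 100) copies, decomposes each with EMD,
pads member IMF lists with zero series to the maximum count, and averages
index-wise. These are the canonical EEMD settings. Two residue notions
coexist: the reported `residue` is x − Σ(averaged IMFs) (so the IMFSet
remains additive), while `ensemble_residue` is the ensemble mean of the
member residues. The identity Σ IMFs + ensemble_residue = x + (mean added
noise) makes ‖x − (Σ IMFs + ensemble_residue)‖ the right quantity for the
noise-cancellation check: it decays like 1/√ensemble and is measured to
drop roughly threefold from ensemble 10 to 100.

The DWT baseline is a 3-level db4 transform in periodized mode, which is
exactly orthonormal: perfect reconstruction and coefficient-energy
conservation hold to 1e−8 and are tested. Features are computed on the
coefficient vectors of A3, D1–D3, not on reconstructed band signals.

## IMF selection

Four metrics are computed per IMF: energy Σ|IMF[n]|² (descending),
Pearson correlation with the original signal (descending), the spectral
log-ratio distance Σₖ ln(S_x(ω_k)/S_IMF(ω_k)) over the full DFT grid
(ascending), and the two-sided one-sample t-test p-value of the zero-mean
hypothesis (descending — IMFs are nominally zero-mean, so a high p-value
marks a well-behaved mode; the rejection flag h = (p < 0.05) is recorded
alongside). The log-ratio form of the spectral distance is kept as the
method's definition even though it is not the probability-normalized
Kullback–Leibler divergence; a symmetric KLD variant is available behind
`symmetric_kld=True` for comparison. Both spectra are floored at 1e−12 ×
the larger spectral peak before the ratio, which leaves identical inputs
at exactly zero and makes the distance invariant under common scaling.

Ranking is stable with ties broken toward the lower IMF index; undefined
scores (zero-variance components: correlation NaN, p-value sentinel 0)
rank last. Each segment contributes four rows — metric order energy,
correlation, psd_distance, p_value — padded with sentinel 0 to
`max_imfs` columns. Consensus counts first-column (first-priority)
occurrences over all rows jointly for both classes and returns the k = 3
most frequent indices, ties toward the lower index. A Borda-style
all-column consensus was considered and rejected: the first-priority
histogram is the method's defining step and the extra columns mostly
encode noise ordering among negligible modes.

## Features

Time-domain moments use divisor N (population form), so kurtosis of a
Gaussian is 3, not 0. All spectral sums run over the full two-sided DFT
grid k = 0..N−1 with ω_k = 2πk/N in radians/sample; consequences — a pure
real tone has spectral entropy exactly 1 bit, and total power equals
time-domain energy (Parseval) — are accepted and tested. Undefined
features (zero-variance series) yield NaN sentinels and the affected rows
are dropped from feature tables with a logged count.

The Hurst estimator is plain rescaled-range analysis: ~10 logarithmically
spaced window sizes m ∈ [8, N/2]; per non-overlapping window, R = range of
the cumulative deviations from the window mean and S = the window standard
deviation (divisor m); HE is the least-squares slope of ln(mean R/S)
versus ln(m). No small-sample (Anis–Lloyd) correction is applied; the
uncorrected estimator carries the well-known mild upward bias on
uncorrelated series (measured ≈ 0.54 at n = 6000 versus the asymptotic
0.5), which is the package's reference behaviour.

Higuchi's fractal dimension uses the standard curve-length construction
with normalization (N−1)/(⌊(N−m)/k⌋·k²) and k_max = 30, the saturation
point for minute-long 100 Hz segments; the dimension is the slope of
ln L(k) versus ln(1/k). Recovery is validated on three closed-form cases:
smooth line → 1, Brownian path → 1.5, white noise → 2.

## Classification

Stratified, shuffled, seeded k-fold (default 5) with no validation split.
Stratification is a deliberate strengthening of plain random folds: at
320 samples it guarantees both classes in every training split. Features
are z-scored per fold with statistics from the training folds only — SVM
and KNN are scale-sensitive and the feature bank spans orders of
magnitude. Classifiers: RBF-kernel soft-margin SVM (kernel configurable),
5-nearest-neighbour with Euclidean distance, Gaussian naive Bayes, and
logistic regression fitted by maximum likelihood with decision at
P₁ ≥ 0.5. Seizure is the positive class. Mean metrics are arithmetic
means of per-fold metrics (the cross-validation accuracy convention);
zero-denominator metrics in a fold are NaN sentinels excluded from the
mean. The hemisphere summary averages per-channel mean accuracies over
the fixed left/right channel sets; in the pipeline the per-channel models
are fit on the first feature group with the first configured classifier,
with fold count clamped to the per-class sample count when channels have
few segments.

## Problem sizes used in validation

The structural checks run the full default scale (320 segments of 6000
samples, EMD throughout, a 1280 × 16 ranking matrix). EEMD convergence is
demonstrated on 512-sample signals with ensembles of 10 versus 100 over
ten seeds, and estimator-recovery checks use 20 seeds at n = 2000–6000 —
scales at which the Monte-Carlo means are stable to well within the
asserted tolerances.

## Known limitations

* EMD has no uniqueness theory; the IMFs depend on the envelope and stop
  conventions above, and other conventions yield slightly different mode
  splits (the additivity and oscillation guarantees still hold).
* The oscillation-property rate on broadband noise is just above the 95%
  bar at a 10-iteration sifting cap; raising the cap raises the rate at
  proportional cost.
* The EEMD averaged IMFs are not themselves exact IMFs (averaging breaks
  the extrema/zero-crossing property slightly); this is inherent to EEMD.
* Classification numbers on the synthetic data reflect the generator's
  construction and transfer to no clinical claim.
* EDF reading ingests signals and sampling rates but class labels must be
  supplied externally (EDF carries no seizure annotation usable here).
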