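# Methods

This note documents the models, conventions and design choices behind
`adhdaid`, in the order the pipeline runs them.

## Pre-processing

Recordings are band-pass filtered with a Butterworth IIR filter of total
order 6 (three second-order sections; pass band 0.5–60 Hz) and notch
filtered at 50 Hz with an order-2 IIR notch. "Total order" is the design
convention here: asking scipy for a band-pass of order N yields a 2N-order
filter, so the default is designed with N = 3. The notch's quality factor
is not implied by its order; the default Q = 35 gives a ≈1.4 Hz −3 dB
trough, the usual power-line setting, and is configurable. Filters are
applied causally in a single pass by default (matching common practice in
the MATLAB-style environments this pipeline emulates); zero-phase
forward–backward application is available via `FilterSpec(zero_phase=True)`.
Whether the original protocol filtered causally or zero-phase is unknown;
both are provided and the choice is recorded in the config hash.

Segmentation is non-overlapping with no padding: windows of round(4·fs)
samples, trailing remainder discarded, label inherited from the recording.
All windows and band edges are defined in seconds/Hz, so rates other than
128 Hz work unchanged. Input is assumed to be microvolts and is never
rescaled — every feature is either scale-covariant or standardised before
classification.

## Variational mode decomposition

VMD minimises the summed bandwidths of K analytic modes subject to soft
reconstruction, solved by the standard frequency-domain ADMM: each mode's
spectrum is a Wiener-type update û_k = (f̂ − Σ_{i≠k}û_i + λ̂/2) /
(1 + α(ω−ω_k)²) and each centre frequency the power-weighted spectral mean
of its mode. Defaults: K = 9, α = 2000, τ = 0 (multipliers off — robust
when the signal is noisy, at the cost of exact reconstruction), relative
convergence tolerance 1e-7, iteration cap 500, centre frequencies
initialised uniformly over [0, fs/2). The signal is mirror-extended to
twice its length before the FFT and cropped after, suppressing edge
ringing. Only the non-negative half-spectrum is iterated (with multipliers
off it is the only nonzero part), and batches of signals share one ADMM
loop for speed; convergence is tracked per signal and a converged signal
is frozen, so results are independent of how signals are batched. The
residual is defined as input minus mode sum, making the decomposition
identity exact by construction. VMD is applied per 4-s segment (not per
recording), consistent with decomposing after segmentation.

The inner loop is JIT-compiled with numba when available; a pure-numpy
path with identical semantics is the fallback.

## Discrete wavelet transform

Level-1 decomposition with the Symlets-5 mother wavelet via PyWavelets.
The boundary mode is periodization, which makes A₁/D₁ exactly half-length
and energy conservation exact for orthogonal wavelets — the property the
tests pin. The denoised view is the A₁ coefficient sequence itself (no
reconstruction); downstream band powers on this representation use the
effective sampling rate fs/2.

## Empirical wavelet transform

Band edges come from the magnitude spectrum of the segment: local maxima
are detected, the nine largest kept (fewer if fewer exist), and edges
placed at midpoints between consecutive retained peaks — the most common
segmentation rule for this transform; the "horizon" rule is otherwise
underdetermined. The filter bank is Meyer-type: smooth cosine-squared
crossovers of half-width γ·ω around each edge, with γ chosen just below
the largest value for which transitions do not overlap. The band responses
are built to sum to one at every frequency, so the modes reconstruct the
input to machine precision (partition of unity). If no interior spectral
peak exists (flat or empty spectrum), the transform falls back to a
level-one DWT filter bank (approximation/detail reconstructions) and flags
it. The denoised view is the sum of all modes except the highest band,
paralleling the VMD residual exclusion; which output the original
protocol fed to feature extraction is not documented, but the total
feature count (33 × 4 × 19 = 2508) forces one vector per channel per
method, and dropping the top band is the natural noise-removal reading.

## Feature bank (33 scalars)

Moments are population (biased); kurtosis is non-excess (Gaussian → 3).
Shannon and log-energy entropies follow the wavelet-entropy convention on
the unit-L2-norm sample sequence with ε = 1e-12 guarding zeros; Rényi and
Tsallis entropies use order 2 on a 64-bin amplitude histogram (orders and
the probability model are conventions of this implementation, exposed as
arguments). The autoregressive model is order 4 — chosen so the 30
extractors yield exactly 33 scalars and the 19-channel matrix has the
printed 2508 columns — estimated by Yule–Walker with biased
autocovariances (solve_toeplitz; numerically identical to statsmodels'
`yule_walker(method="mle")`, which the tests cross-check). Band powers
integrate a Welch PSD (Hamming window of 2·min(128, L/4) samples, 50%
overlap) over the five canonical bands; powers are absolute, the γ band is
clipped below Nyquist, and the α/β ratio divides by max(β, ε). Degenerate
zero-variance inputs map to defined zeros (and the log-variation feature
to its ε floor) so downstream selection never sees NaN or ±inf.

## Site search and feature selection

The six-site partition of the 19-channel montage is fixed (pre-frontal
Fp1/Fp2; frontal Fz/F3/F4/F7/F8; central Cz/C3/C4; parietal Pz/P3/P4;
temporal T3/T4/T5/T6; occipital O1/O2). Sites are ranked by the
cross-validated accuracy of a reference classifier — default
quadratic-kernel SVM, the choice consistent with the published ranking —
and fused cumulatively; ties break by the canonical site order so traces
are reproducible.

ANOVA scoring is the one-way F statistic (infinite F from perfect
separators is capped at a large sentinel so rankings stay finite). χ²
scoring min–max scales each column to [0, 1] first because EEG features
can be negative. Kruskal–Wallis is the H statistic with midrank tie
correction, vectorised across columns and verified against
scipy.stats.kruskal. Top-k selection breaks score ties by ascending column
index. Selection is fitted inside each training fold by default
("fold-honest"); `paper_mode` ranks once on all data to mimic protocols
where the filter statistics see the full dataset — useful for comparison,
known to be optimistic.

## Classification and evaluation

SVMs use sklearn's SVC with box constraint C = 1: polynomial kernels of
degree 3 ("cubic") and 2 ("quadratic") with coef0 = 1, and an RBF kernel
with scale √P (γ = 1/P) — the "medium" preset the name refers to. kNN is
k = 3, Euclidean, unweighted. The network is two hidden layers of 10 ReLU
units, logistic output, cross-entropy loss, Adam, iteration cap 1000,
seeded. Features are z-scored with statistics fitted on the training fold.
Cross-validation is stratified 10-fold at segment level (subject-level
splitting is deliberately out of scope here; the generator's exchangeable
segments make segment-level CV honest on synthetic data). Metrics are
computed from the confusion matrix pooled across folds; ROC/AUC from the
pooled decision scores, with ADHD as the positive class throughout.

## Synthetic generator

Each channel is 1/f^γ background noise (γ = 1, σ = 10 µV) plus one
narrowband stochastic oscillation per canonical band — band-pass-filtered
white noise normalised to the band amplitude (δ 8, θ 6, α 8, β 4, γ 1.5 µV)
under a slow (0.05–0.25 Hz) ±30% envelope. The class effect multiplies θ
power by (1+δ) and β power by (1−δ) on the fronto-central channels by
default; δ, the bands and the sites are configurable, and the template is
a simulation convenience, not a neurophysiological claim. Oscillations
are deliberately stochastic rather than fixed-frequency sinusoids: a
fixed tone would fingerprint each record, and segment-level CV would then
re-identify records instead of classes, so the δ = 0 null would sit above
chance without any pipeline defect. With exchangeable segments, the null
stays at chance unless something leaks — which is exactly what the null
test is for.

What the generator does **not** emulate: eye/muscle artifacts,
event-related potentials, inter-subject variability beyond independent
noise draws, volume-conduction correlations between channels, and the
visual-attention task structure of real recordings. Passing tests
therefore demonstrate that the pipeline recovers planted band-power
structure and does not leak — not that the published clinical accuracies
transfer.

## Problem sizes and numerics

The end-to-end recovery tests run the generator's default study
(20 records/class × 60 s → 600 segments, 2508 features); the null study
uses 10/class × 32 s and the ten site-recovery replicates 5/class × 24 s,
sizes chosen so the chance bands and win counts are still conclusive. The
binomial 95% band used for null checks is 0.5 ± 1.96/(2√n) at each test's
own n. VMD dominates runtime (~0.1 s per 19-channel segment batch);
feature extraction is ~1.3 ms per vector.

Known limitations: EWT boundary placement uses peak midpoints only (the
lowest-minimum variant is not implemented); wavelet levels > 1 and wavelet
packets are out of scope; no artifact rejection, re-referencing or
resampling; subject-level cross-validation is available via the harness's
``groups`` argument (all segments of a subject share a test fold) but is
not the default protocol and is not exercised by the synthetic study.
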