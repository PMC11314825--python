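# Methods

## Scope and model

The package classifies fixed 10-s single-lead ECG windows into two classes
(pre-AF = 1, non-AF = 0). The signal path is: min–max normalization →
wavelet denoising → time-delay embedding → thresholded recurrence plot →
either (a) scalar recurrence quantification (RQA) for statistical group
comparison, or (b) a pooled recurrence-density image fed to a residual CNN.
All stages are deterministic given their inputs; every stochastic component
(signal synthesis, weight initialisation, batch shuffling, splitting) is
driven by an explicit integer seed.

## Wavelet denoising

* **Transform.** Orthonormal Daubechies DWT, default `db5` (filters derived
  at run time by spectral factorisation of the Daubechies half-band
  polynomial; correctness is asserted through the defining identities:
  Σh = √2, unit energy, orthogonality to even shifts, p vanishing moments).
  Boundaries use *periodized* extension rather than symmetric padding: the
  single-level analysis map is then an orthogonal matrix for every even
  input length, so multi-level reconstruction is exact to machine rounding
  by construction, and energy comparisons between coefficient vectors and
  signals coincide. Odd intermediate lengths are padded by repeating the
  last sample, with the pad tracked and removed on reconstruction.
* **Depth.** N = ⌈log₂(fs/f_L)⌉ with f_L = 0.5 Hz (the bottom of the
  diagnostic ECG band): 10 levels at 500 Hz, 8 at 128 Hz, clamped to
  ⌊log₂ n⌋ for short signals.
* **Threshold.** δ = median(|d₁|)/0.6745 from the finest detail band (the
  MAD estimator; the absolute value is essential, a signed median of
  symmetric noise is ≈ 0). T = δ√(2 ln n) with n the segment length —
  the universal threshold's sample count, not the level count (with the
  level count, √(2 ln 10) ≈ 2.1 would barely shrink anything). Soft
  thresholding w ↦ sgn(w)·max(|w|−T, 0) is applied to every detail band;
  thresholding all bands rather than a subset is configurable via
  `threshold_scale` and `level`.
* **Baseline removal.** The drift band is [0, f_L). Zeroing only the
  deepest approximation A_N is insufficient: at 500 Hz/level 10 the band of
  A_10 ends at 0.24 Hz, and a 0.25 Hz drift mostly lives in D_10. The
  implementation therefore zeroes A_N *plus every detail band lying wholly
  below f_L* (exactly D_10 in the default geometry). Measured on a clean
  beat train + 0.2 mV, 0.25 Hz drift, the sub-0.5 Hz residual is ≈ 4.5 % of
  the injected drift power, independent of drift phase.
* **Order.** Normalization precedes denoising (the pipeline's flowchart
  order); both operate per segment, so min/max are per-segment statistics.

## Recurrence analysis

* **Embedding.** u(i) = (x(i), x(i+τ), …, x(i+(m−1)τ)), defaults
  m = 3, τ = 3; M = N − (m−1)τ points (a 5000-sample window yields
  M = 4994).
* **Threshold.** ε = 0.10 × max pairwise Euclidean distance. The Heaviside
  step is taken strictly (Θ(0) = 0): recurrence requires distance < ε, so
  the pair realising the maximum distance is never recurrent even at
  fraction 1. Because ε scales with the data, the matrix is bit-invariant
  under x ↦ a·x + b (a ≠ 0); a constant trajectory has no scale and raises
  a degenerate-signal error.
* **Line of identity.** Included by default in all diagonal statistics,
  matching the defining sums over all (i, j); `theiler=1` excludes it
  (standard RQA practice) for users who prefer the conventional reading.
* **Statistics.** With p(l)/p(v) the histograms of maximal diagonal/vertical
  run lengths: REC = ΣR/M²; DET and LAM are the fractions of recurrence
  points lying on diagonal (resp. vertical) lines of length ≥ lmin (= 2)
  (resp. ≥ vmin = 2); ENTR = −Σ p̂(l) ln p̂(l) over the normalised
  distribution of diagonal lengths ≥ lmin (reported positive); TT and Lmean
  are the mean vertical/diagonal line lengths over qualifying lines; Lmax
  is the longest diagonal, reported both raw and divided by M (TT and Lmean
  are also exported /M, since lengths in matrix units are scale-bound).
* **Boundary correction.** The corner diagonals of an M×M matrix have
  length < lmin, so no "line" can exist there by definition; counting their
  recurrence points as non-deterministic is a boundary artifact (it caps
  DET at (M²−2)/M² even for a perfectly periodic signal). DET and LAM
  therefore count a maximal run as a line when its length reaches lmin
  **or** it spans its entire truncated diagonal/column. A fully recurrent
  plot then has DET = LAM = 1 exactly. Histograms, ENTR, Lmean, and Lmax
  are not affected.
* **Degenerate plots.** If no qualifying line exists, the affected
  statistics are reported as 0 and flagged; REC is always defined.
* **Images.** RP images are block-mean density images: rows/columns are cut
  into S (default 224, benchmark 64) nearly equal contiguous bins and each
  pixel is the mean recurrence in its block — exactly mean-preserving when
  S divides M. Matrices no larger than S are zero-padded unscaled. To bound
  M, signals may be decimated by plain striding before embedding (the
  pipeline default decimates 5000 → 500); the min–max/denoise steps come
  first, so aliasing of broad-band noise is limited but not eliminated.

## Classifier

Stem 3×3 conv (stride 2, 16 channels) + BN + ReLU; three residual blocks
16→16 (2×2 kernels, stride 1), 16→32 and 32→64 (3×3 kernels, stride 2),
each block conv-BN-ReLU-conv-BN with an additive skip (1×1 projection +
BN when shape changes) and a final ReLU; global average pooling; FC
64→32→ReLU→2. The 2×2 kernels use asymmetric (0,1) padding. The `raw1d`
variant applies the same topology with height-1 kernels to the denoised
series. The classification head is initialised near zero so an untrained
model predicts ≈ 0.5. The default configuration has ~33 k parameters
(≪ the 11 MB sanity bound asserted in the tests).

Training: softmax cross-entropy, Adam (default lr 1e−5; the synthetic
benchmark uses the scaled-down protocol lr 1e−3, ≤ 20 epochs), mini-batches
of 32, early stopping on validation loss with configurable patience and
restoration of the best-epoch weights. Cross-validation uses stratified,
record-disjoint folds (`StratifiedGroupKFold`), so segments of one record
never straddle folds — the same constraint the record-level train/val/test
split enforces via largest-remainder apportionment (ties resolved toward
the training partition).

## Synthetic data

Each beat is a sum of five Gaussians (P, Q, R, S, T) with amplitudes
0.15/−0.10/1.0/−0.15/0.30 mV, offsets −200/−35/0/+35/+250 ms and widths
25/10/12/10/55 ms — a deliberately simple McSharry-style morphology.
R-peak times accumulate lognormal RR intervals with a specified mean heart
rate and coefficient of variation. The stated world:

* non-AF-like: 75 bpm, RR CV = 0.05, full P wave;
* pre-AF-like: 75 bpm, RR CV = 0.30, P amplitude × 0.3.

Equal mean rates are deliberate, so class differences come from rhythm
irregularity and P-wave attenuation alone (the qualitative AF signature),
not from trivial rate differences. Noise defaults: 0.2 mV drift at
0.25 Hz, 0.05 mV powerline at 50 Hz, 0.05 mV high-passed (> 45 Hz) white
muscle noise, each with seed-determined phase. On this world the RQA
ordering matches what is reported for real pre-AF ECG — recurrence rate,
entropy and trapping time all larger in the pre-AF class (trapping time
≈ 8.5 vs ≈ 6.5 at the README scale, Welch p < 1e−4) — which is a property
of the generator *by construction*, not evidence about real ECG. A green
classification benchmark therefore establishes that the pipeline extracts
and learns genuine RP structure, not that it predicts clinical AF: real
pre-AF morphology, inter-patient variability, electrode artifacts, and
ectopy are all outside the generator.

## Numerical choices and edge rules

* Constant segments min–max-normalize to all zeros.
* Resampling is polyphase with anti-aliasing; output length is forced to
  round(n·fs′/fs) (trim or edge-pad of at most one sample); equal rates
  return the input unchanged, bitwise.
* Windowing drops the trailing remainder; a signal shorter than one window
  yields no segments (not an error).
* Metric ratios with zero denominators are reported as 0 and flagged
  (`EvalMetrics.undefined`); AUC uses average ranks so ties count ½; the
  group-comparison p-value for two zero-variance groups is defined as 1
  (identical) or 0 (different).
* All WFDB decoding assumes a single interleaved .dat per record, formats
  16 or 212, physical units via (adc − baseline)/gain.

## Known limitations

* The generator is not clinically faithful; no claim about real AF
  prediction performance is made or tested.
* The architecture's channel widths, stem, and FC sizes are this package's
  own defaults; published descriptions of comparable models leave them
  unspecified.
* Decimation before embedding is plain striding, not a decimating filter.
* The CNN is pure numpy: fine at the tested scales (seconds per epoch on
  64×64 images), but not meant for full-database training.
* WFDB annotation files, multi-segment records, and hospital XML exports
  are unsupported.
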