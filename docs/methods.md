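# Methods

## Session model and epoching

The OFC session is modelled as habituation (default 300 s) immediately
followed by conditioning (default 240 s) with a shock cycle of
`shock_period` = 12 s containing a `shock_duration` = 2 s shock at the start
of each cycle. The first shock is placed at conditioning onset; the
alternative (first shock after one full inter-shock interval) yields the
same number of cycles and is available via `first_shock_at`.

Conditioning analysis windows are the inter-shock intervals trimmed by a
`guard` = 1 s at both ends: cycle *k* contributes
`[k·12 + 3, (k+1)·12 − 1)` s relative to conditioning start, giving 20
windows of 12 − 2 − 2·1 = 8 s. Habituation is tiled with 10-s windows; the
number of habituation windows is not prescribed anywhere, so the whole
phase is tiled by default (30 windows — maximal data) with an option to
restrict to a fixed count. Quarters are formed by shock-cycle index
(5 cycles = 60 s each), not by wall-clock time, so no window straddles a
quarter boundary; a cycle count not divisible by 4 puts the remainder in
the last quarter with a logged warning.

All intervals are half-open `[start, end)` seconds from recording start and
are discretized with `floor(t·fs)` at both edges.

## Filtering order and artifact containment

Shock artifacts are orders of magnitude larger than the LFP. A zero-phase
IIR filter applied to the *continuous* trace would smear artifact energy
through the 1-s guard at roughly 10⁻³ relative amplitude, defeating the
purpose of the guard. The pipeline therefore slices the guard-trimmed
epochs from the raw signal first and band-filters each epoch independently
(4th-order Butterworth, forward–backward via `sosfiltfilt`, so no phase
lag distorts the cross-correlation). With this order the guarantee is
exact: samples inside shock windows never reach the filter, and injected
artifacts change no matrix entry at all (bit-for-bit), which the test suite
asserts. The standalone `bandpass` still operates on arbitrary continuous
signals. Per-epoch zero-phase filtering has edge transients confined to a
few tens of milliseconds at each epoch end (filter order ≪ epoch length);
they are identical across conditions and do not bias comparisons.

## Connectivity

"Cross-correlation coefficient" is implemented as the zero-lag Pearson
correlation of the theta-filtered epoch pair (default). Because the term
is ambiguous in the field, a lag-maximized mode (signed maximum of the
normalized cross-correlation within ±100 ms) is also provided; the mode is
recorded in every output's metadata. Per-epoch coefficient matrices are
averaged arithmetically across epochs (a Fisher-z mean is available by
flag; for the coefficient magnitudes involved here the two differ by
< 0.02). Group matrices are element-wise means across subjects, with the
per-subject pair values exported for external statistics.

Matrix dissimilarity is the Euclidean norm of the difference over the
strict upper triangle — each unordered pair counted once, diagonal
excluded. Counting both symmetric halves would scale every distance by √2
and change nothing else; the once-per-pair convention keeps the
single-pair case interpretable (a δ change in one pair gives distance δ).

## Spectral power

Welch estimation with 2-s Hann segments and 50 % overlap (0.5 Hz
resolution), segment periodograms averaged across all epochs of a phase.
Min–max normalization is applied per channel and per phase across the
1–55 Hz bins; habituation and conditioning are normalized independently,
so a phase comparison compares two unit-interval spectra (joint
normalization is a caller option by passing concatenated bins). The band
table preserves the 13–14 Hz gap between alpha and beta as defined rather
than silently bridging it. Band values are means of normalized bins with
`low ≤ f < high`; note that a mean divides by band width in bins, so a
narrowband peak produces a larger *mean* in a narrow band than the same
peak would in a wide band — symmetric comparisons across bands of unequal
width should use the summed normalized power, as the tests do.

## Synthetic data

The generator's purpose is ground truth, not biophysics. Coupled pairs
share a band-limited Gaussian source `s` mixed as `x_k = c·s + noise_k`;
backgrounds are independent pink noise (PSD ∝ 1/f, exponent configurable).
Two calibration choices make the model analytically checkable:

* `noise_sd` is the noise standard deviation **within the analysis (theta)
  band**, not broadband — the pink-noise trace is rescaled so its
  theta-filtered SD equals `noise_sd`.
* the source is normalized so that its *refiltered* variance is 1, because
  the analysis stage band-filters every epoch again; without this the
  second pass attenuates source and noise unequally (transition-band
  losses) and biases the correlation a few percent low.

With both conventions the expected theta correlation of a coupled pair is
exactly `ρ = c²/(c² + σ²)` — at gain 1 the reference curve `1/(1+σ²)` —
which the acceptance suite verifies at σ ∈ {0, 1, 2} over 100 seeds.

Phase-specific gains emulate condition contrasts: the default
transgenic-like (`Tg`) cohort spec has AI_L–BLA_R gain 0.3 in habituation
and gains (0.5, 0.65, 0.8, 0.95) across the four conditioning quarters, so
the planted network change both exceeds habituation and grows over the
session; the wild-type-like control has flat 0.3 gains everywhere. The
recordings have no stated empirical SNR to copy, so `noise_sd = 1` (theta
SNR determined entirely by the gains above) is the package's convention.
Freezing bouts are placed to cover 45–75 % (Tg) or 5–30 % (Wt) of
conditioning; plaque burden follows a monotone link to freezing
(0.25 %-points burden per %-point freezing) with per-region noise scaled so
the AI link is the tightest of the four regions. Shock artifacts are
Hann-windowed deflections strictly inside the shock windows.

What the generator does **not** emulate: volume conduction, nonstationary
1/f slope, spike contamination, movement artifacts outside shock windows,
or any biophysical oscillator dynamics. Passing tests therefore show the
*analysis chain* is correct and well-calibrated, not that it is robust to
every pathology of real recordings.

Plaque images are two-level (background 20, foreground 200, optional
Gaussian noise) with disk-shaped blobs unioned inside the region mask and
the final blob trimmed to land on the exact target pixel count, so the
truth-mask burden equals the target to rounding precision.

## Behavior

Freezing bouts are maximal immobility runs with duration strictly greater
than 1 s; a run of exactly 1.0 s is not a bout (the boundary is
configurable via `min_bout`). Bout duration is `run_length/fs`, so scoring
is invariant to the trace sampling rate up to one sample at each boundary.
The >2-SD exclusion uses the mean and sample SD (ddof = 1) computed once
over all values including the candidate — a single pass, no iterative
re-screening, which is the simplest defensible reading. Continuous
activity traces are binarized at a user-supplied threshold; no threshold is
inferred.

## Statistics

Spearman's r_s is Pearson on midranks. Its two-sided p is exact by full
permutation enumeration for n ≤ 8 (the observed ordering counts, so
p ≥ 1/n!) and a t-approximation above. Steiger's test uses the pooled-r̄
Z1* variant (Fisher z-transforms of both coefficients, covariance term with
r̄ = (r12+r13)/2, normal reference); Williams' T2 is available by flag
since sources vary in which "Steiger's Z" they mean. Applying the Fisher
machinery to rank correlations is conventional, not exact; the type-I
calibration test (trivariate-normal null, n = 30, 10,000 replicates,
rejection rate in [0.04, 0.06] at α = 0.05) covers the product-moment
case. Invalid correlation triples (not completable to a positive
semi-definite matrix) are rejected rather than silently processed.

## Problem sizes and runtime choices

Recovery simulations run 100 seeds with one subject per cohort per seed at
the full default recording size (8 channels, 540 s, 1600 Hz); cohort-size
averaging is a separate, cheaper property (group matrices are plain means)
and is exercised at reduced fs in the unit tests. The analysis drivers use
the full cohort sizes (10 Tg-like, 7 Wt-like). The Steiger calibration
vectorizes all 10,000 replicate correlation matrices in one einsum pass.

## File formats

Recordings: HDF5 (lossless float64 round trip) and CSV with a JSON sidecar
(written with `%.17g` and read with round-trip float parsing, so the CSV
path is also exact). EDF import/export is not provided. Protocols, band
tables and run configurations round-trip through YAML; every pipeline
output directory carries the SHA-256 config hash and seed, and rerunning
the same configuration reproduces every file byte for byte.

## Known limitations

* Zero-lag Pearson discards lead/lag structure; the lagged-max mode
  reports magnitude-dominant lag but not directionality.
* Four-point trajectory correlations have n = 4; their p-values are
  reported but carry little power, as the worked example shows.
* The dissimilarity of two *estimated* matrices has a positive noise floor
  (≈ 0.29 under the default Wt conditions with 5-epoch quarter matrices);
  trajectories should be compared against a matched control, not against
  zero.
* Otsu thresholding assumes a bimodal in-region intensity histogram; very
  sparse or very dense plaque fields may need the fixed-threshold mode.
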