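# Methods

This note documents the models and procedures implemented in `neurocomm`,
the synthetic data they are validated on, the parameter choices that
matter, and the limits of what the validation shows.

## Preprocessing

Spikes are counted in half-open 50 ms bins anchored at the analysis span
start; units averaging below 0.1 spikes/s are excluded. Counts are
z-scored per unit, with moments computed over run-period bins (a mask
argument); zero-variance units are zeroed and flagged rather than dropped,
preserving column alignment. LFP filtering uses zero-phase (forward–
backward) Butterworth bandpasses, order 4 per pass, in the canonical bands
delta 0.5–4 Hz, theta 6–12 Hz, ripple 150–250 Hz. Band "power" for
state detection is the magnitude of the analytic signal smoothed with a
100 ms boxcar — a concrete estimator chosen because it is monotone in
instantaneous band amplitude and robust at these band widths.

## State windows

High-state windows of fixed 300 ms duration open at upward crossings of
the 85th percentile of a scalar state series (band envelope, coherence, or
running speed); low-state windows open at downward crossings of the 15th
percentile. Percentiles of the empirical distribution are used rather than
fractions of the maximum: the threshold is then insensitive to isolated
extreme values. Windows start *at* the crossing sample; crossings inside
an open window are ignored. Windows overlapping a window of any other
state set are deleted from both sets (no state is privileged), and the
surviving sets are subsampled to the global minimum count, stratified over
ten equal time segments with a spillover rule so retained windows stay as
uniform over the recording as the data allow. Equalization is global
across all state sets, the stricter of the plausible readings.

## Mean-matched partitions

Comparing CA1→CA1 with CA1→PFC dimensionality requires target populations
matched in size and rate distribution. Firing rates of both regions are
binned into 20 equal-width bins spanning the pooled min–max range (the
top boundary closes the last bin); from each bin, the minimum count across
regions is drawn without replacement from each region. The matched CA1
subset serves as the CA1→CA1 target, disjoint from the remaining CA1
sources; the same source set serves both target conditions within a
repetition. Partitioning repeats 50 times by default and is held fixed
across window conditions.

## Reduced-rank regression

`B_OLS = (XᵀX)⁻¹XᵀY`, computed by a linear solve unless cond(XᵀX) exceeds
1e10, in which case a Moore–Penrose pseudoinverse keeps the estimate
defined. Rank-m predictors project the OLS predictions onto their top-m
principal directions: `B_RRR(m) = B_OLS V₁:ₘV₁:ₘᵀ` with `V` the right
singular vectors of the *training predictions* `X·B_OLS` (prediction-space
PCA; the alternative, PCA of the coefficient matrix itself, does not
optimize predictive rank reduction). Cross-validation uses five folds
formed over whole windows, never splitting a window's bins between train
and test, so within-window autocorrelation cannot leak. Held-out
`R² = 1 − SSE/SST` pools all target units, with SST around the training
mean. The optimal dimension is the smallest m whose mean R²(m) lies within
one standard error (across folds) of the full-rank mean. Training-set
R²(m) is provably nondecreasing in m; the test suite verifies the
implementation against a brute-force SVD-of-predictions oracle at every
rank.

## CCA and the shared/local decomposition

Canonical weights come from the SVD of the whitened cross-covariance, with
a trace-scaled ridge (1e-8 × mean diagonal) on each within-region
covariance for numerical safety. Five-fold cross-validation reports
held-out canonical correlations (weights from the training split,
correlation on the test split) to separate real shared channels from
overfit ones; reported weights come from a final full-data fit. CCA signs
are fixed by convention: each training correlation is made non-negative,
then each pair is flipped so the largest-magnitude CA1 weight is positive.
Aligned activity `(U+V)/√2` and local activity `(U−V)/√2` form an exact
per-component isometry. Variates are computed per session ("a stable,
session-wide subspace") over run-period bins.

Trajectory repeatability bins each trial's aligned activity into 100
linearized-position bins (missing bins linearly interpolated) and compares
trials by cosine similarity, categorized *pure match* (same trajectory
label), *same type* (same direction class), and *different type*.

## Coherence and WPLI

Multitaper coherence uses 1 s sliding windows, time–bandwidth 3, 5 DPSS
tapers — about 2 Hz of resolution over theta, implemented directly on
`scipy.signal.windows.dpss` tapers so the window/taper conventions are
identical for the coherence and WPLI estimators. WPLI is computed from
single-taper (Hann) cross-spectra on 1 s windows within the requested
band; windows with identically zero imaginary cross-spectra are reported
missing rather than zero-filled. The debiased-squared estimator is
available behind a flag but not default. Normalization for cross-animal
comparison: z-scoring within frequency band per animal, or min–max
scaling to [0, 1] per frequency per animal over the animal's full dataset.
Epoch trends use 1,000 balanced bootstrap draws in which every animal
contributes an equal number of samples, percentile 95% CIs, a Mann–Kendall
trend test on the epoch means, and a one-way ANOVA across epochs.

## Behavioral decoding

Features are the top-10 aligned then top-10 local components. Binary
behaviors (correct/error, outbound/inbound, left/right) use Bernoulli
regression; continuous behaviors (velocity, acceleration, linearized
position, IdPhi) use a Student-t regression with ν = 4 fixed — heavy
enough tails to shrug off outliers while keeping the likelihood smooth.
All fits are deterministic penalized maximum likelihood via iteratively
reweighted least squares (ridge 1e-6 for Bernoulli, 1e-8 otherwise);
coefficient intervals come from the asymptotic inverse Fisher information.
MCMC sampling is intentionally out of scope: the point estimates are what
the downstream contrasts consume, and determinism makes every result
reproducible bit for bit. 50,000 random bins train each model (70% when
fewer exist); metrics are held-out R² (continuous) or F1 (binary). IdPhi
for recorded position data is the windowed integral of |dφ/dt| of movement
heading over 1 s; the generator plants IdPhi directly, so the estimator
only matters for external data.

The mixed behavior × theta comparison fits, per data split
(animal × epoch × continuous behavior), the model family
{R~B, R~θ, R~B+θ, R~B*θ, R~B+θ with per-group intercepts} by OLS and
reports R² and AIC. Grouped intercepts are fixed effects (`C(group)`),
not random effects — adequate for intercept shifts at these group counts,
and free of convergence failures.

## Manifold geometry

Per session, spiking is averaged per behavioral state — direction
(outbound/inbound) × turn (left/right) × linearized-distance bin (100 by
default; 25 in desk-scale runs) — and neurons are concatenated across
sessions into a state × neuron pseudopopulation. Unoccupied states are
filled by linear interpolation along the distance axis within trajectory
type, keeping rows aligned across animals. Each neuron's state profile is
z-scored (rate-scale invariance across animals) before CCA between the
CA1 and PFC blocks; embedding coordinates are the top-3 aligned
components. The ring contrast compares Euclidean distances between states
sharing a distance bin: within a manifold (same direction, different
turn) vs between manifolds (different direction), by rank-sum test. The
contrast is invariant to rotation/translation of the embedding and to
column permutations within region blocks (tested).

## The synthetic generator

The generator emulates one recording day: eight 15-min run epochs (scaled
down in tests), W-track behavior at 30 samples/s cycling the four
trajectory types with a raised-cosine traversal of linearized position, a
per-epoch accuracy ramp (0.6 → 0.95), and IdPhi bumps in the choice zone
of 20% of outbound trials. LFP at 1.5 kHz is an amplitude-modulated theta
carrier (amplitude high during movement — these bouts define the
theta-state gate), ripple bursts (100 ms, 0.1/s) during stillness, a delta
component and 1/f noise; the PFC theta carrier lags CA1 by a configurable
phase.

Spike counts are Poisson with log-rates
`base + L·[g(gate)·z_shared ; z_private] + W·behavior`, where the shared
latents (AR(1), coefficient 0.8 per 50 ms — smooth but stationary) load on
both regions through row-normalized loading matrices, private latents on
one region, and behavior couples through the shared loading vectors. A
variance-matched offset keeps each unit's mean rate at its base rate
(log-uniform 5–20 Hz — a regime where 50 ms bins carry enough spikes for
single-bin decoding, spanning pyramidal-to-interneuron rates). The gate
gain is 2.0 in theta-high bins and 0.5 in theta-low bins.

Two scale choices deserve explanation:

- `shared_strength = 0.3` (per-unit log-rate SD from shared latents at
  gain 1). Larger values push the exponential nonlinearity into a regime
  where products of latents act as extra cross-region dimensions and the
  measured rank exceeds the planted one; at 0.3 the planted rank-3
  structure is recovered as m̂ ∈ {2, 3, 4} across seeds.
- `coupled_latent_z_scale = 0.25`: behavior-coupled shared channels carry
  an attenuated intrinsic latent in the default ("shared") mode, so the
  intrinsic fluctuations do not mask the behavioral signal in decoding.
  The negative control ("local" mode) plants the behavior signal with
  equal magnitude and opposite sign in the two regions — exactly on the
  unreciprocated (U−V) axis — and there the full intrinsic latent is kept:
  it anchors the sign of the canonical pair. This anchoring is a real
  constraint of the construction: if the anti-symmetric signal outweighed
  the reciprocated latent on its channel, CCA would legitimately flip the
  pair's sign and relabel the planted signal as aligned. A
  region-independent "private" planting was rejected because a behavior
  signal present in both regions is itself cross-region correlated and
  would be absorbed into the shared subspace, defeating the control.

The gating benchmark (high- vs low-theta-state R²) plants pure gated
communication with behavior coupling disabled: the ungated behavior
couplings of the default session contribute equally to both states and
dilute the contrast that benchmark is designed to isolate. The rank
recovery, decoding and manifold benchmarks all run with the default
couplings.

What the generator does **not** emulate: place-field structure beyond the
planted behavior couplings, conductance-level dynamics, spike waveforms or
sorting artifacts, non-Poisson count dispersion, sleep/rest states, and
cross-frequency coupling. Passing recovery benchmarks therefore shows the
estimators are correct and well-calibrated on data satisfying their
assumptions — not that real recordings satisfy those assumptions.

## Numerical choices and degenerate inputs

Quantile-degenerate state series (constant input) yield empty window sets
with a warning rather than an error. Empty spike sets bin to zero-column
matrices. Mann–Kendall uses exact enumeration (Mahonian recursion on the
S-distribution) for n ≤ 10 without ties, and the tie-corrected normal
approximation with continuity correction otherwise. The permutation test
reports the add-one estimator `(1 + #extreme)/(1 + n_perm)`. Balanced
bootstrap draws take the minimum group size from every group so no animal
dominates. All randomness flows from explicit seeds; the generator derives
per-component substreams from one session seed.

## Problem sizes in the shipped benchmarks

Rank recovery and the gating contrast use 20 seeds × 20,000 bins
(two ~17 min epochs, 30/20 units); CCA recovery 50,000 samples; decoding
and manifold benchmarks two 450 s epochs. These sizes put Monte-Carlo
noise comfortably below each criterion's margin while keeping a full
validation run around half a minute on one CPU.

## Serialization

Sessions round-trip through a plain directory: per-unit spike-time text
files, raw float32 LFP with a JSON sidecar (sample rate, region), behavior
CSV, and a JSON config echo. NWB import/export is not implemented;
ingestion of recorded datasets is limited to this directory layout.
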