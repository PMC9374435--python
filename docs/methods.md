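# Methods

This package re-implements, as a tested pipeline, a directed
functional-connectivity analysis of hippocampo-cortical interactions during
a verbal working-memory task: multitaper spectral power, phase-locking
values (PLV), nonparametric spectral Granger causality (GC), permutation
inference, and a simplified LCMV beamforming stage, exercised end to end on
a synthetic generator with known directed coupling.

## Data model and epoch clock

Trials are epoched arrays (trials x channels x samples, microvolts) with
t = 0 at probe onset.  The canonical windows are fixation [-6, -5) s
(baseline), encoding [-5, -3) s (stimulus presentation), maintenance
[-3, 0) s, and the maintenance *analysis* window [-2, 0) s — the last two
seconds of the delay, used because encoding-related processing can extend
past the stimulus offset.  All windows are half-open so adjacent windows
never share a sample.

Preprocessing follows the recording conventions of the emulated setup:
hippocampal LFP and cortical ECoG are re-referenced against *distinct*
depth contacts (a shared reference injects a common signal and fabricates
coupling; the configuration is rejected), scalp EEG against averaged
mastoids.  Resampling uses a linear-phase Kaiser FIR (cutoff 0.8 x the new
Nyquist, 70 dB stopband) with delay compensation and reflect padding, i.e.
zero phase — phase preservation matters because PLV and GC are phase-based.
Artifact rejection, for which no published criterion exists, uses two
configurable thresholds: peak amplitude (default 500 uV) and peak robust
z-score (default 6, against the per-channel median/MAD pooled over trials
so a spiking trial cannot inflate its own baseline).  These defaults are
not claimed to match the original study's (unpublished) criterion.

## Spectral estimation

All estimators consume per-trial, per-taper Fourier coefficients with
unit-energy tapers, so `|X(f)|^2 / fs` is a two-sided density.  Two taper
families are provided: DPSS (time-bandwidth (K+1)/2 for K tapers) and
"hann" = the sine-taper family, whose first member applies exactly a Hann
window in power; a multi-taper "Hann" estimate is realized as the first K
sine tapers (there is no canonical orthogonal family of literal Hann
windows).

The time-frequency PSD uses frequency-adaptive windows of 10 cycles at
each frequency, DPSS smoothing of half-bandwidth 0.2 x f (time-bandwidth
2.0 at the defaults, admitting 3 tapers), a 0.1 s time step, and the
frequency range [4, 100] Hz.  Windows whose half-length exceeds the
distance to a trial edge are shifted inward, keeping the nominal centre;
this is what lets the 1-s fixation baseline exist for the low-frequency
rows.  Baseline correction is (P(t, f) - P_fix(f)) / P_fix(f), so "+1.0"
means a 100 % power increase.

## Phase-locking value

PLV_{i,j}(f) = |(1/N) sum_n X_i X_j* / (|X_i||X_j|)| over N trials.
Cross-terms are averaged across tapers within a trial *before* the
across-trial modulus, keeping N equal to the trial count.  The PLV
configuration is 2 DPSS tapers over [4, 100] Hz at 1 Hz resolution.  Under
independence E[PLV] ~ sqrt(pi)/2 * N^(-1/2) (Rayleigh resultant), which is
why N is stored with every spectrum; windows of different lengths (1 s
fixation vs 2 s maintenance) share N but not spectral resolution, and the
bias difference between them is noted, not corrected.

## Nonparametric spectral Granger causality

The chain is: (1) trial- and taper-averaged cross-spectral density S(f) on
the full [0, Nyquist] grid (signals resampled to 40 Hz so that the
reported [4, 20] Hz band is well inside Nyquist; 2 sine tapers; zero
padding to 20 s giving 0.05 Hz spacing); (2) Wilson's minimum-phase
factorization S = H Sigma H*; (3) Geweke's spectrum

    GC_{y->x}(f) = ln( S_xx / (S_xx - (Sigma_yy - Sigma_xy^2/Sigma_xx) |H_xy|^2) ),

evaluated from the factorization's own reconstruction, which makes the
intrinsic power structurally non-negative; negative values can arise only
from floating-point noise, are clipped to zero and counted, and a clipped
fraction above 1 % raises an error.  The net information flow for a
(cortex a, hippocampus b) pair is Delta-Granger = GC_{b->a} - GC_{a->b}
averaged over a band with inclusive endpoints; Delta < 0 means net flow
cortex -> hippocampus.

Wilson's iteration initializes from the Cholesky factor of the
frequency-averaged spectrum and applies plus-operator (causal-truncation)
updates; tolerance 1e-9 relative reconstruction residual, at most 100
iterations.  Two numerical facts matter.  First, analytic spectra on a
sufficiently dense grid converge below 1e-9 (the causal factor's
coefficients decay geometrically with the companion spectral radius, which
is why the random-model validator bounds that radius at 0.9).  Second,
*empirical* padded multitaper spectra have a residual floor set by the
finite lag support of the grid (about 1e-8 at 20 s padding); the iteration
detects the stall (< 1 % improvement) and stops rather than burning
iterations, reporting the achieved residual.  Permutation batches factor
many re-averaged spectra at once (vectorized over the batch axis) at a
relaxed tolerance of 1e-7, which perturbs null statistics far below their
sampling noise.

Time-resolved maps slide a 1 s window (a default; the original window
length is unpublished, so exact map values are not claimed) in 0.1 s steps
and record the Delta spectrum per window.

### Estimator validation against closed-form oracles

Two independent oracles validate the chain.  (a) Factorization: for random
stable bivariate VAR(2) models, the closed-form spectrum
S(f) = H(f) Sigma H(f)*/fs is factorized and must reproduce Sigma within
1 % and S within a 1e-9 residual.  (b) Causality: data simulated from a
unidirectional theta VAR are analyzed nonparametrically and compared with
the parametric Geweke spectrum written directly from the generating
coefficients.  The validation experiment uses 400 trials of 40 s at 40 Hz
with 12 sine tapers — 4800 spectral averages, chosen so Monte-Carlo noise
(which scales as the inverse square root of trials x tapers) sits well
below the 5 % comparison tolerance while the smoothing half-bandwidth
(12 / 80 s = 0.15 Hz) stays an order of magnitude below the oscillator
line width; under these conditions the median in-band error is ~3 % and
the analytically-zero reverse direction stays below 1e-3.

## Permutation statistics

All tests floor p at 1/(n_perm + 1) and take explicit seeds.

* **Cluster permutation test** (two conditions, per-trial observations):
  pointwise two-sample t statistic; the cluster-forming threshold is the
  pointwise two-sided 5 % quantile of the permutation distribution itself
  (no parametric reference); clusters are connected components under a
  chain (frequency), 4-neighbour grid, or arbitrary sparse adjacency;
  cluster mass is the summed t; the null is the maximum |mass| per
  permutation.
* **Direction-swap null** for Delta-Granger: each permutation exchanges
  the two channels' labels in a random half of the trials — trial counts
  per channel are unchanged, consistent directionality is destroyed — and
  recomputes both directional spectra from the re-averaged cross-products;
  two-sided exceedance of |Delta|.
* **Spatial spread test**: the TRUE distribution collects scalar products
  of mean-map vectors over random 50/50 splits of the task trials; the
  NULL distribution does the same over trials mixed across task and
  fixation.  The headline criterion is median(TRUE) > 95th
  percentile(NULL), with a stricter 5th-percentile variant also reported.
  That criterion is deliberately conservative (a concentrated median is
  compared against a tail quantile), so the test *additionally* returns a
  calibrated p-value from an outer permutation that recomputes the median
  statistic under random task/fixation relabelings; the type-I-error
  checks use this p.
* **Balanced subsampling**: a statistic over n_reps random subsets of 10 %
  of the correct trials (the incorrect-trial count in the emulated data),
  median reported with the full distribution.
* **Paired permutation test** on per-participant scalars: sign-flip null
  of mean(a - b), exact enumeration whenever 2^n <= n_perm.
* **FDR**: Benjamini-Hochberg step-up (via statsmodels) at q = 0.05.

Type-I calibration checks run each test on pure-null data; with reduced
permutation counts (100 for cluster, 50 for direction-swap, 60 for spread,
150 for paired — chosen to keep 200-replicate calibrations tractable) the
achievable level is floor((n_perm+1) * alpha)/(n_perm+1), and the observed
rejection rate is required to sit inside the binomial 95 % interval around
that level.

## Synthetic task generator

Every channel is an AR(2) oscillator with poles at radius 0.95 and angle
2 pi f0 / fs (f0 = 6 Hz, fs = 200 Hz), giving a controllable theta peak.
Directed interaction is a single lagged linear term (lag 25 ms): during
encoding each grid contact drives the hippocampal channel with gain
g * exp(-d / lambda) (d = contact distance to the focus C2, lambda = 1
spacing); during maintenance the hippocampus drives each contact with the
same spatial profile.  Gains are expressed in innovation-SD units (the
lagged source is normalized by its stationary SD).  The default gain 0.06
was calibrated once, via the pipeline's own estimate on the generator,
so that the band-averaged |Delta-Granger| is ~0.05 — the per-participant
effect scale of the emulated study — and then frozen.  Incorrect trials
carry zero directed coupling; this generates direction-free error trials
and is a modeling choice, not a mechanistic claim.

Epoch-locked bursts are amplitude-modulated band-passed noise: gamma
([60, 80] Hz) on cortical contacts during the last encoding second, beta
([12, 24] Hz) on the hippocampus during the last maintenance second.  The
burst amplitude parameter is the *added in-band power as a multiple of the
channel's baseline in-band power* (computed from the AR(2) spectrum); the
default of 4 leaves a measured relative-PSD increase comfortably above
100 % after the 0.2 x f spectral smoothing of the time-frequency
estimator spreads the burst energy.

Behavioral labels: set size uniform over {4, 6, 8}; correctness Bernoulli
with accuracies {4: 0.97, 6: 0.89, 8: 0.83}; reaction time
0.9 s + 0.053 s/item + N(0, 0.3 s) (the 0.3 s trial-to-trial SD is a
choice; the emulated study reports ~0.5 s total SD including between-
participant spread).  Fixed seeds give byte-identical datasets.

Pair-level analyses (the Delta-Granger experiments) simulate only the
hippocampal channel and the focus contact — for that pair the remaining
contacts only add small decayed inputs — while spatial-map analyses (PLV /
power maps) simulate a multi-contact grid.  This is a problem-size choice,
stated with each analysis.

What the generator does *not* emulate: 1/f broadband background, volume
conduction and shared-reference leakage, electrode impedance drift,
inter-participant anatomical variability, and any nonlinear or
cross-frequency coupling.  Passing tests therefore demonstrate estimator
correctness and pipeline integrity under the generative model, not
robustness to those real-data confounds.

## Forward model and LCMV beamforming

The synthetic head is a homogeneous unit sphere; surface potentials of
interior dipoles use the classical Legendre-series solution, truncated
when (b/R)^n < 1e-12 (checked against the closed-form center-dipole
pattern, rotation equivariance and mirror symmetry).  Sources sit on a
cubic grid strictly inside the sphere; octant labels stand in for atlas
parcels and the hemisphere of a source is the sign of its x coordinate.

LCMV filters are W = (L' C_r^-1 L)^-1 L' C_r^-1 with diagonal loading
C_r = C + 0.05 * mean_eig(C) * I (regularization fraction exposed; the
original value is unpublished).  The covariance is estimated over the
combined task + baseline windows by default (common-filter approach, so a
window contrast cannot be an artifact of window-specific filters).  Power
maps are trace-over-orientations of the filtered covariance, contrasted
against fixation or noise-normalized (neural activity index) when scanning
for maxima.  Virtual channels collapse the three orientations onto the
dominant eigenvector of the filtered covariance (max-power orientation)
and feed directly into the spectral / PLV / GC modules.

## Known limitations

* At the Delta-Granger-calibrated default gain the theta PLV increment
  (~0.05-0.1) sits near the Rayleigh bias floor for realistic trial
  counts, so PLV grid-map demonstrations use a stronger maintenance
  coupling (gain 0.3, PLV ~0.6 at the focus).  Real recordings reach high
  PLV partly through common drive and volume conduction, which the
  generator omits; a single lagged-linear coupling cannot match the
  observed PLV and Delta-Granger scales simultaneously.
* The band-restricted time-reversal sign flip of Delta-Granger holds in
  the weak/moderate coupling regime only; at strong coupling the reversed
  process moves dependence into instantaneous causality (verified in
  closed form).
* Empirical Wilson factorizations have a padding-dependent residual floor
  (~1e-8 at 20 s padding); `converged` refers to the 1e-9 target and the
  achieved residual is always reported.
* EDF support is interchange-only: 16-bit quantization, trials written as
  fixed-length records, metadata in a JSON sidecar.
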