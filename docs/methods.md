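# Methods

This note documents the models, estimators and numerical conventions
implemented in `plicrit`, the defaults they ship with, and what the
synthetic benchmarks do and do not demonstrate.

## Phase synchronization and phase-lock intervals

### Analytic wavelet transform

Scale-resolved instantaneous phase is obtained from an undecimated,
exactly-quadrature analytic filterbank (config key
`wavelet_phase.FILTERBANK = "analytic-raised-cosine"`). For dyadic scale
*j* at sampling rate *fs*, the band is [*fs*/2^(j+1), *fs*/2^j] Hz. The
filter is applied in the frequency domain: a raised-cosine window with
transition half-width 0.25× each band-edge frequency multiplies the
positive half of the spectrum (negative frequencies zeroed), so the
imaginary part of each coefficient series is exactly the Hilbert transform
of the real part. This is the ideal limit of the approximate Hilbert
wavelet pairs used in dual-tree constructions; results downstream are
tested against invariances (unit modulus, antisymmetry, band energy,
run-length oracles), not against any specific FIR filter pair. At the top
scale the passband is held open up to Nyquist.

Coefficients are aligned to the input grid (no decimation), so interval
durations are sample counts. Samples within `8 * 2**j` of either record
edge are marked insignificant, covering both the effective filter length
of the frequency window and the smoothing window below. Samples where
either coefficient's magnitude falls below 1e-10 of the record's peak
(e.g. constant signals) get coherence 0 and are excluded, avoiding 0/0 in
the normalisation.

### Phase difference, coherence, and PLI

For two coefficient series the instantaneous complex phase vector is
`C(t) = W_x W_y* / |W_x W_y*|`; its sliding mean `<C>` over `avg_window`
samples gives the local mean phase difference `dphi = arg<C>` and the
coherence `|<C>|^2`. Defaults:

| parameter | default | meaning |
|---|---|---|
| `avg_window` | `2 * 2**j` samples (two wavelet periods) | smoothing span of `<C>` |
| `min_coherence` | 0.5 | significance gate on `|<C>|^2` |
| `lock_threshold` | pi/4 rad | `abs(dphi)` bound defining locking |

A phase-lock interval (PLI) is a maximal run of samples that are
significant and have `abs(dphi) < lock_threshold`; its duration is the run
length in samples, converted to seconds only at reporting time.

The smoothing window deserves comment. With the default two-period window
the coherence gate is permissive: Monte-Carlo calibration on independent
white noise gives median null coherence ≈ 0.65 at this window (≈ 0.30 at
four periods, ≈ 0.145 at eight periods, where only ~7% of null samples
pass the 0.5 gate). Short smoothing is kept as the default because it
preserves the temporal resolution of the locking dynamics — long windows
smear interval boundaries by the window length and dominate the short end
of the duration distribution. Users who want the 0.5 gate to carry real
significance (e.g. for noisy recordings) should pass
`avg_window >= 8 * 2**j`; the tests exercise both regimes.

## Power-law fitting and the Delta statistic

Durations are treated as continuous (they are sample counts divided by
*fs*). The tail exponent of the density `p(x) ~ x**-alpha` is fit by the
closed-form continuous MLE above a cutoff `xmin` chosen to minimise the
Kolmogorov–Smirnov distance between the tail sample and the fitted model;
candidate cutoffs are the smallest 90% of unique values (thinned to at
most 200), each required to leave at least 10 tail points. The empirical
CCDF is right-continuous (`P(X >= x)`), which handles the inevitable ties
of integer sample counts. A fixed `xmin` can be supplied to skip the
search (used for reference fits over a known scaling range).

Alternatives are compared with Vuong-normalised log-likelihood ratios
against exponential and truncated-lognormal tails (positive ratio favours
the power law). Goodness of fit uses the semi-parametric bootstrap: each
synthetic sample mixes empirical draws below `xmin` with Pareto draws
above it in the observed proportion and is refit from scratch; the
p-value is the fraction of synthetic KS distances exceeding the observed
one. Its calibration under the null (rejection rate ≈ 0.1 at level 0.1)
is verified in the test suite.

For distributions that are scale-free over a finite range only, the
package also provides a direct cumulative-slope estimator:
`ccdf_slope_regression` regresses log10 CCDF on log10 duration at
log-spaced points restricted to where the CCDF lies in [1e-3, 0.5] —
excluding the saturated head and the noisy extreme tail. For a clean
power law it returns `-(alpha - 1)`; unlike the KS-cutoff MLE it is not
drawn to whichever regime happens to minimise KS, which matters for the
network model's interval distributions (below).

The Delta statistic quantifies deviation from a frozen reference fit:

    Delta = (1/n) * sum_i [ F_emp(l_i) - P_ref(l_i) ]

evaluated at the observed durations `l_i >= xmin_ref`, where `F_emp` is
the empirical CCDF conditioned on the reference tail (=1 at the cutoff)
and `P_ref(l) = (l / xmin_ref) ** -(alpha_ref - 1)`. Positive Delta means
an excess of long lock intervals relative to the reference; negative a
deficit. Durations below the reference cutoff are excluded because the
reference model is undefined there.

## Sliding-window pipeline

Recordings are split into windows of 150 s overlapping by 100 s (30000
samples per window at 200 Hz, 38400 at 256 Hz); a trailing partial window
is discarded. PLIs are computed within windows independently (intervals
are cut at window boundaries, boundary-truncated intervals kept) and
pooled over all unordered channel pairs — per-window distributions are
single curves per scale. The reference power law for the Delta timecourse
is fit per scale to window 0 and frozen; window 0's own Delta is ~0 by
construction (bounded by sampling noise, |Delta| < 3/sqrt(n)).

No bandpass preconditioning is applied beyond the wavelet bands
themselves; hardware filter metadata from EDF headers is carried through
verbatim. All channels participate in pairing. Text input is one column
per channel, one row per sample (tab/comma/whitespace sniffed), sampling
rate from a JSON sidecar or flag; EDF input goes through `mne` and
rejects files with mixed per-channel rates.

Whether Delta should be computed per pair and averaged, or on durations
pooled across pairs, is an open representational choice; pooling is
implemented, consistent with the single-curve-per-window convention.

## Adaptive SOC network

The model couples N = 1024 binary threshold elements, states
`sigma_i ∈ {-1, +1}`, through a signed matrix `c` with entries in
{-1, 0, +1} and zero diagonal (`c[i, j]` is the link j → i). Updates are
synchronous: `sigma_i <- sign(sum_j c_ij sigma_j)` with the deterministic
convention sign(0) = -1 (configurable in principle; a fixed convention is
required for reproducibility). States persist across topology updates —
re-randomising each epoch makes transient activity mark nearly every node
active and collapses the connectivity to ~1; with persistent states the
dynamics is on or near its attractor when activity is measured, and the
network self-organizes to the characteristic plateau.

Topology evolves once per epoch of `T_epoch = 1000` steps: one node is
picked uniformly; if its state never changed during the epoch (frozen,
equivalently |epoch-mean state| = 1) it gains an incoming link from a
uniformly chosen distinct source with random sign; if it changed (active)
it loses one incoming link chosen uniformly. Impossible moves leave the
network unchanged, so the link count changes by 0 or ±1 per iteration.
The probability-driven control variant instead adds one uniformly chosen
absent link with `p_add` and deletes one existing link with `p_del` per
iteration, independent of activity; the defaults 0.8/0.2 (and mirrored
0.2/0.8) produce clearly super-/sub-plateau connectivity within ~1500
iterations and are analysis choices, not empirical constants.

The synchronous-update kernel is JIT-compiled and exits an epoch early on
fixed points and period-2 cycles (tiling recorded states over the
remainder); activity flags and recordings are bit-identical to a
full-length run, which the tests verify against a per-node loop oracle.

**Plateau estimation.** Self-organization runs use 8000 topology updates.
At N = 1024 the self-organized connectivity fluctuates slowly (±0.15 on
thousand-iteration scales), so the plateau is estimated by averaging the
final 500 updates of two runs started below (K_init = 1.0) and above
(K_init = 3.5) the plateau. This pooled estimator is stable at ≈ 2.55
links/node; single-run final-500 means are not.

**Frozen component.** The fraction of nodes whose state never changes
along the attractor is approximated by discarding 500 transient steps
from random initial states and observing 500 further steps (exact cycle
detection is infeasible at this size); sweeps average over random
topologies per K (100 at full depth; the bundled driver defaults to 20).

**Model PLI.** The ±1 state series of 20 monitored nodes (chosen
uniformly once per run, recorded in output metadata with the seed),
concatenated over 100 consecutive epochs (10^5 steps at unit rate), are
analysed at wavelet scale 1 and pooled over all node pairs. The plateau
distribution is scale-free over roughly 1.5 decades; its cumulative slope
is reported with the scaling-range regression described above, because
the distribution also carries a shallow multi-epoch tail (node pairs that
stay locked across topology updates) that makes the KS-cutoff MLE
unstable between regimes. Reference fits for model Delta comparisons use
a fixed cutoff at the plateau sample's median (the top of the scaling
range) for the same reason.

## Surrogate recording generator

The generator produces locking structure directly in phase space rather
than simulating tissue: channels are cosines of a shared carrier (centre
of `carrier_band`, default 30–40 Hz inside the scale-2 band at 200 Hz)
plus per-channel offsets driven by a global two-state renewal process.

* Locked dwells: durations are Pareto draws (inverse CDF
  `X = xmin * (1-U) ** (-1/(alpha-1))`), density exponent
  `target_alpha = 2.5`, cutoff `xmin_s = 0.2` s by default. At lock onset
  all offsets are pulled to a common value (jitter 0.05 rad), so every
  pair's phase difference sits near zero for the dwell.
* Unlocked dwells: exponential with mean 0.3 s (memoryless, keeping the
  locked-dwell distribution identifiable). At unlock onset offsets jump
  to independent uniform phases and then rotate at detunings evenly
  spaced over ±4 Hz (shuffled across channels, so every pair separates at
  ≥ 2·4/(m−1) Hz) with mild phase diffusion (0.5 rad/√s).
* Regimes: `seizure` multiplies locked dwells by `lock_excess` (≥ 1);
  `recovery` decays the excess exponentially toward 1 with
  `relax_tau_s`. Additive white noise `noise_sigma = 0.2` on unit-
  amplitude carriers.

The abrupt desynchronisation and the separated detunings are what make
the ground truth recoverable: slow pairwise drift would otherwise
generate false locking with its own duration distribution and bias the
fitted exponent upward (estimator-side interval boundaries are smeared by
the smoothing window plus the time the rotating phase difference needs to
leave the lock zone, ~0.1 s at these settings, which is also why the
ground-truth cutoff defaults to 0.2 s rather than something smaller).

What the generator does **not** emulate: 1/f background spectra, spatial
electrode geometry, per-pair (rather than global) locking episodes,
nonstationary carriers, artifacts. Passing the closed-loop tests
therefore shows the pipeline recovers a known locking-duration law
embedded in noise at matched band and sampling — not that it is robust to
the full complexity of clinical recordings.

## Problem sizes used in the bundled checks

The acceptance script and tests run the network at full size (N = 1024,
1000-step epochs, 8000-update self-organization, 100 recorded epochs,
two runs pooled) and the pipeline benchmarks on 600–1000-s six-channel
surrogates — sizes chosen so the complete suite executes on a single CPU
in minutes while keeping every distributional estimate comfortably in its
large-sample regime (≥ 10^4 intervals per fit, ≥ 2000 per window).

## Known limitations

* The analytic filterbank treats exact-Nyquist content specially (the
  top-scale passband is held open to Nyquist); period-2 oscillations of
  the binary network map to quantized phases {0, pi}, so model-side
  `dphi` is effectively discrete and short intervals partly reflect
  estimator flicker rather than dynamics.
* The KS-cutoff MLE assumes a single tail regime; on mixtures it selects
  whichever regime minimises KS and its output then depends on sample
  size. Use the scaling-range slope (and report both) on such data.
* The bootstrap GOF inherits the usual property that, at very large n, it
  rejects any small systematic deviation from an exact power law.
* `frozen_component` approximates the attractor by transient + observe;
  for chaotic networks with cycle lengths beyond the observation window
  the frozen fraction is overestimated slightly.
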