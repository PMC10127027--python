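# Methods

This note documents the models, estimators, parameter choices and known
limitations of `hippoconn`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The unit of analysis is a *session*: one animal's sequence of maze trials
spanning the three phases of the detour paradigm — acquisition (preferred
route learned), adjustment (route blocked, exploration), recovery (new
route stabilized). Two data streams are analysed per session:

* a multichannel LFP recording (default 16 channels, 2 kHz, already
  low-passed at 0–250 Hz by the acquisition chain), with trial windows
  ("signals of interest") delimited by gate/infrared events;
* a behavioral log: per-trial events, a camera trajectory (default 30 Hz),
  and the ordered sequence of maze pathlets crossed (the *path signature*).

The package ships no acquisition-hardware readers; recordings enter either
from the synthetic generator or as a samples-by-channels matrix with a JSON
sidecar (`hippoconn.io`).

## Preprocessing

* **Filters.** All filters are Butterworth, applied forward–backward
  (zero phase), order 4 by default — the filter order is a free choice;
  forward–backward application doubles the effective order and removes
  phase distortion so that band decomposition does not shift event timing.
* **Bands.** delta 1–4, theta 5–12, beta 13–30, slow gamma 31–45, fast
  gamma 55–80 Hz. The 45–55 Hz gap is kept deliberately (mains avoidance at
  50 Hz); no band ever covers it, and no notch filter is applied. The band
  table is configuration-driven.
* **Channel screen.** "Reliable channel" is operationalized as three
  objective, deterministic criteria, each configurable: variance above
  1e-3 of the median channel variance (flatline screen), at most 1% of
  samples pinned at the channel's min/max rail (saturation screen), and at
  most 50% of spectral power within ±1 Hz of the line frequency
  (line-dominance screen, Welch PSD with 4096-sample segments). Rejecting
  every channel is a hard error.
* **Segmentation.** Trial windows are half-open `[start, end)` in samples,
  0-based, seconds throughout; each segment keeps good channels only. The
  signal of interest is the whole start-to-goal traverse of a trial (not
  sub-windows between intermediate gates).

## Coherence estimation

The cross-spectrum of a channel pair is the average of Hann-tapered
windowed FFT products, `p_xy(f) = (1/n) Σ x_i(f) y_i*(f)`, with 1-second
windows and 50% overlap by default (2000 samples at 2 kHz, giving 1-Hz bin
spacing so even the 1–4 Hz delta band contains several bins); auto-spectra
use the same average with `y = x`. Magnitude-squared coherence
`|p_xy|² / (p_x p_y)` lies in [0, 1] by the Cauchy–Schwarz inequality
applied to the window-averaged products; the implementation never clamps,
and the test suite asserts the bound over 1000 seeded draws. Single-window
estimates are refused rather than returned (they are identically 1). Bins
with numerically zero power are set to 0 and flagged.

Band values are means of the coherence over the FFT bins whose centre
frequency lies in the closed interval `[lo, hi]`; a band containing no bin
is an error suggesting a longer window. The per-trial matrix is the
statistical unit; per-phase summaries (heatmap means, distribution fits)
are computed across that phase's trial matrices, which is what gives the
rank-sum comparisons multiple observations per phase. Whether one should
instead average coherence spectra across trials before band-averaging is
not determinable from first principles; trial-level band-averaging was
chosen and is applied uniformly.

Known estimator property, used as a test oracle: for independent Gaussian
inputs and n independent (non-overlapping) windows the expected coherence
is 1/n, and for a shared source with independent additive noise the
estimate converges to `(P_s/(P_s+P_n))²`.

## Binarization

Two thresholding modes produce the binary network:

* **absolute** (default, threshold 0.3): edge iff band coherence exceeds
  the threshold. This is the default because the phase-dependent *density*
  changes of the binarized networks — sparser low-band networks and denser
  gamma networks during adjustment — can only appear when the edge count is
  free to vary with coherence strength.
* **proportional**: keep the `ceil(d · M(M−1)/2)` strongest off-diagonal
  pairs (default d = 0.3 when selected), ties broken deterministically by
  ascending (row, col). Useful when density must be equated across
  conditions before comparing topology.

The diagonal is never an edge; the chosen mode and parameter are recorded
in every output and in the run manifest.

## Network topology

`Coef` is the mean over nodes of `2E_i / (k_i (k_i−1))` with `E_i` the
number of edges among node i's neighbours; nodes of degree < 2 contribute 0
(their term is 0/0), the convention that keeps Coef in [0, 1] and makes the
star graph evaluate to 0. `Eff` is the mean inverse shortest-path length
over ordered pairs; disconnected pairs contribute 0 (1/∞), a case sparse
binarized networks do reach. Distances use breadth-first search on the
unweighted graph (via `scipy.sparse.csgraph`); the test suite checks both
metrics against an independent exhaustive triangle-count / Floyd–Warshall
recomputation on 500 random graphs.

Distribution summaries pool the strictly-upper-triangle coherence values of
a phase's trial matrices and fit a plain normal by maximum likelihood
(sample mean, population-form standard deviation). The values live in
[0, 1] and are not transformed before fitting — the fitted curve is a
descriptive summary, not a generative claim; a degenerate pool (all values
equal) yields sigma = 0 with a warning rather than an error.

## Behavior

Duration is goal-arrival time minus start-gate time; path length is the
summed Euclidean step distance of the camera trajectory (arena units; no
pixel calibration). Route identity is the ordered pathlet-id sequence, not
trajectory geometry — geometry jitters between trials, gate sequences do
not. Acquisition is complete when strictly more than 90% of a day's trials
follow the preferred route on each of two consecutive days (exactly 90%
does not qualify; the inequality is strict and tested).

The adjustment/recovery boundary is this package's operationalization (the
task description itself does not define one): recovery starts at the first
trial of the earliest run of k consecutive trials (default k = 5) on one
*new* route that is then used in ≥ 90% of trials through session end.
The rule and its k are recorded in the run manifest as a modeling choice.

## Statistics

All contrasts are two-sided Wilcoxon rank-sum tests. Tie-free samples with
pooled size ≤ 12 use the exact null distribution (dynamic-programming
enumeration of rank-sum counts, two-sided p = 2·min(tails) capped at 1);
larger or tied samples use the normal approximation with tie correction and
a 0.5 continuity correction; identical constant samples return p = 1.
Marks are strict: `***` p < 0.001, `**` p < 0.01, `*` p < 0.05, else `ns`.
The observation unit is the trial, pooled across sessions; this
pseudo-replicates animals/sessions and is deliberately left uncorrected but
flagged in the report metadata, as is the absence of multiple-testing
correction (Bonferroni and Benjamini–Hochberg adjustments are available
but off by default). Group summaries always report both the sample standard
deviation and the standard error.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated.

**LFP.** Per trial and band, each channel receives
`sqrt(c)·shared + sqrt(1−c)·private`, where shared/private are independent
unit-variance Gaussian sources confined to the band and `c ∈ [0, 1]` is
the planted coupling strength of that band in that phase (optionally per
channel group, each group with its own shared source). In-band coherence
between coupled channels is then ≈ c², slightly shrunk by broadband noise.
Band-limited sources are drawn directly in the frequency domain (i.i.d.
complex Gaussian rFFT coefficients on in-band bins — the distribution of
brick-wall-filtered white Gaussian noise, synthesized at an FFT-friendly
length and truncated). Sinusoidal sources are avoided on purpose: a
deterministic tone gives degenerate coherence for every estimator setting.
Background noise is white (sd 0.5), 1/f-amplitude pink (sd 0.5), and a
50 Hz line component (sd 0.2) that falls in the inter-gamma gap.

Default coupling plan: delta/theta 0.8 in acquisition and recovery, 0.2 in
adjustment; slow/fast gamma mirrored (0.2 / 0.8 / 0.2); beta 0.7
throughout. No effect sizes exist to copy for these couplings — published
phase effects are reported as significance levels only — so the strengths
were fixed once to produce a clear qualitative contrast (≈0.6 vs ≈0.05
in-band coherence, straddling the 0.3 binarization threshold), not any
particular magnitude. Sessions run 20 trials per phase, 8–12 s per trial
(uniform), 1 s noise-only gaps.

**Behavior.** The maze is a 4×4 grid graph (start (0,0), goal (3,3)).
Acquisition trials follow the preferred shortest route; at the blockade the
last pathlet of that route is removed; adjustment trials are uniform random
walks on the blocked maze absorbed at the goal (capped at 400 steps, then
completed by the shortest path — rarely reached on the default maze);
recovery trials follow the new shortest route, which on this maze has the
same graph length (6 pathlets) as the preferred one, making acquisition
and recovery identically distributed. Waypoints are jittered (sd 0.05
arena units), sampled at 30 Hz along the polyline at walking speed 0.5
units/s. Trial duration is the recorded track's traversal time
(arc length / speed) plus a small half-normal gate latency (sd 0.05 s), so
duration and path length are measurements of the same walk and are almost
perfectly rank-correlated within a phase.

**Determinism.** Every stochastic operation takes an explicit seed;
sub-streams are derived through fixed `SeedSequence` offsets per module,
channel and trial, so identical (config, seed) pairs are bit-identical and
modules are independently reproducible.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: volume conduction and shared
references (which inflate real coherence), nonstationarity within trials,
movement and chewing artifacts, electrode drift, spikes, cross-frequency
coupling, and any realistic hippocampal biophysics. The planted couplings
are spatially uniform by default, so the default binarized networks are
near-complete or near-empty; real networks have intermediate, structured
topology. Parameter-recovery results show that the estimators detect the
planted structure at these effect sizes, not that real effects have any
particular size.

## Numerical and degenerate-case choices

* Coherence bins with zero auto-spectral power → 0, flagged, never NaN.
* Proportional-threshold ties → deterministic (row, col) order.
* Clustering for degree < 2 → 0; efficiency for disconnected pairs → 0.
* Rank-sum with zero variance (all pooled values equal) → p = 1.
* A phase with fewer than 2 observations is skipped in reports, with a
  warning; an empty adjustment phase (immediate re-route) warns.
* Segment windows are half-open; a trial window outside the recording or
  overlapping another is an error naming the trial.

## Problem sizes used in validation

The test suite validates parameter recovery end to end with the default
study conditions (16 channels, 20 trials per phase) over 20 seeded sessions
for the connectivity pattern, and 100 seeded sessions for the behavioral
pattern; estimator identities use 200–1000 seeded draws; graph-metric
oracle equivalence uses 500 random graphs of up to 10 nodes. These sizes
were chosen to keep the full suite to a few minutes on one CPU while
leaving Monte-Carlo margins far from the asserted thresholds.

## Known limitations

* Only magnitude-squared coherence is implemented — no imaginary
  coherence, phase-lag index, Granger causality or wavelet variants — so
  zero-lag common signals (volume conduction) are indistinguishable from
  genuine coupling.
* The behavioral "ns between acquisition and recovery" expectation is a
  true null in the generator; any single comparison still rejects at the
  nominal 5% rate, which is inherent to the test, not a defect of the
  generator or estimator.
* Trial-level pooling across sessions ignores the animal/session
  hierarchy; a mixed-effects treatment is out of scope.
* The normal fit to [0, 1]-supported coherence values is descriptive; its
  tails extend outside the support.
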