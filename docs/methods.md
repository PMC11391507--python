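# Methods

This note documents the models, defaults and numerical choices behind
`burstkit`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite does not itself compute.

## Burst detection

Spike times arrive pre-sorted per channel (seconds, t = 0 at recording
start).  Detection pools the analysis channels (all channels in culture
mode; the motoneuron subset in cord mode) and works on the spans
`s_i = t[i+N−1] − t[i]` of all windows of `N` consecutive pooled spikes.

**Threshold estimation.**  Spans range over four or more orders of
magnitude, so the span histogram uses 64 logarithmically spaced bins from
0.1 ms (or half the smallest positive span, if smaller) to the maximum
observed span, normalized to probabilities and smoothed with a centred
3-bin moving average — the minimum width that suppresses single-bin noise
without filling the valley.  Candidate minima are local minima of the
smoothed histogram, with two robustness rules:

* *Plateaus count.*  In a cleanly bimodal distribution the valley is a run
  of tied (often zero) bins with no strict local minimum; such a run is a
  single candidate, represented by its **middle** bin so the threshold
  sits inside the valley rather than hugging the burst-merge boundary.
* *Prominence floor.*  A candidate must be flanked on both sides by some
  bin exceeding it by at least 0.5% of the total span mass.  Without this,
  sparse counting noise in the far tail (spans crossing whole interburst
  gaps) produces spurious minima that would otherwise win the
  longest-duration rule below.

The threshold `T` is the candidate at the longest duration (bin centre,
seconds).  `threshold_override` bypasses estimation entirely — useful when
the distribution is degenerate (constant interspike interval, unimodal
data), in which case estimation raises instead of guessing.

**Windowing and merging.**  A window qualifies when its span is at most
`T` (closed comparison).  Qualified windows whose closed time intervals
overlap merge into one burst running from the first spike of the first
window to the last spike of the last window; this is exactly the
advance-one-spike-and-lengthen procedure, and the implementation is tested
to be identical to brute-force window enumeration followed by interval
union, including tied (coincident, multi-channel) spike times.  Burst
intervals are closed: a spike exactly at a boundary belongs to the burst.

**Network criteria.**  A candidate is a network burst when it holds at
least `min_total_spikes` spikes across at least `min_channels` channels
(defaults: culture 10 spikes / 5 channels with N = 10; cord 6 spikes / 4
channels with N = 6, the midpoints of the usual 4–8 / 3–5 working ranges).
A configuration with N < `min_total_spikes` is legal but warns, since the
window criterion is then weaker than the network one.

**Channel exclusion.**  Channels that spike in fewer than 5% of bursts
(`exclusion_min_burst_participation`), or whose out-of-burst spike count
exceeds 0.8 (`exclusion_active_fraction`) times what firing continuously
at their overall mean rate would produce in the total interburst time, are
removed, and detection re-runs once on the survivors.  The participation
and density cutoffs operationalize the qualitative rule "does not
contribute to bursts / constantly active"; a single pass (no iteration to
convergence) keeps the procedure predictable.

**Episodes.**  Bursts whose successive gaps are at most 10 s group into
episodes; groups whose span falls in 20–100 s are kept.  The 10 s default
separates the within-episode timescale (seconds between bursts) from the
minutes-long quiescent periods.  Any group meeting the duration range
qualifies; no minimum burst count is imposed.

## Per-bin metrics

Bins are half-open `[start, end)`; bursts and episodes belong wholly to the
bin containing their start time (this avoids splitting spike counts across
bins).  Event-rate metrics (overall spike rate, burst frequency) are 0 in
empty bins; within-structure metrics (SRWB, durations, channels per burst,
episode metrics) are NaN when no structure exists.  The IBI spike rate
divides out-of-burst spikes by the bin duration minus the burst time
actually overlapping the bin, so the identity *spikes-in-bursts +
spikes-in-IBI = total spikes* holds exactly; it is NaN when bursts fill
the bin.  Pooled SRWB equals the duration-weighted mean of per-burst
rates (an algebraic identity the tests check to 1e−9); the per-burst
variant reports mean and SD with the n−1 denominator, warning (SD 0) on a
single burst.  Zero-duration bursts (all spikes coincident) are excluded
from SRWB with a warning.

Culture protocol bins are 900 s windows starting at hour offsets from drug
onset, with the predrug baseline the 900 s immediately before onset —
"0 h" is the first post-drug window, and the baseline is a separate
window.  Cord bins are contiguous 30 min windows, with a 30 min predrug
baseline; cord SRWB and burst duration are the episode-averaged
within-episode values (one value per preparation per bin when several
episodes fall in a bin), and the IEI spike rate uses the out-of-episode
time within the bin (NaN when an episode spans the whole bin).

## Homeostatic index

`index = 100·(extreme − treated_end)/(extreme − control_end)`.  The
first-hour extreme is the value with the largest deviation from 1 (sign
preserved) among bins starting in the half-open hour `[onset,
onset+3600)`; the deviation reading (rather than a plain maximum) handles
suppression-type perturbations, whose trajectories dip below 1,
symmetrically with facilitation.  The index is affine-invariant and
undefined when the extreme equals the control endpoint (no perturbation to
recover from — an error, not a zero).  When several control preparations
exist their mean normalized endpoint is used; a scalar default of 1.0 is
accepted when no controls are supplied.  Summaries report the mean and
coefficient of variation (sd/mean, ddof = 1) across preparations.

## Estimation statistics

Effect size: unpaired mean difference, test − control.  The BCa interval
resamples each group with replacement (default 5,000 resamples), takes the
bias correction `z0 = Φ⁻¹(#{boot < observed}/B)` — ties count as
"not less", and the proportion is clamped to `(1/(B+1), B/(B+1))` in the
degenerate all-below/all-above cases — and the acceleration from the
jackknife skewness of the statistic under the concatenated leave-one-out
scheme (omit one observation from whichever group it belongs to; the
leave-one-out means are computed in closed form).  With `z0 = 0` and
`a = 0` the adjusted quantile levels reduce exactly to the plain
percentile levels.  Zero-variance inputs collapse to a point interval
with a warning.  Permutation p-values are two-sided on |mean difference|
with the `+1/(n+1)` correction (default 5,000 reshuffles).  Every
stochastic routine takes a seed (or a shared `numpy` Generator) and is
bit-reproducible given it.

## ΔF/F

`(I(f) − B)/(B − A)` per frame, with `B` and `A` the ROI and
autofluorescence means over the same `baseline_frames` (default 30)
window immediately preceding episode onset.  Averaging `A` over the fixed
baseline window (rather than subtracting it frame by frame) makes the
transform exactly invariant under a joint affine rescaling of the camera.
No photobleaching detrending is applied; the intended recordings are a
couple of minutes long.  `B ≤ A` is an error (unlabelled or dark ROI).

## Synthetic data

The generator is the package's test bed: it emulates the *structure* of
the two preparations, not their biophysics.

**Culture.**  Per-channel homogeneous Poisson background at 0.4 Hz;
network bursts scheduled as a renewal process with gamma(shape 4)
onset-to-onset intervals (mean 5 s; "semiregular", CV 0.5) and gamma(shape
4) durations (mean 1 s), a 0.2 s minimum quiet gap preventing overlap.
Each burst recruits channels independently with probability 0.6 and draws
per-channel within-burst spike counts as Poisson at 15 Hz × m(t) × duration,
spikes placed uniformly in the interval (no intra-burst envelope).  With 20
channels these defaults give pooled magnitudes representative of MEA
culture reports: pooled SRWB ≈ 190 Hz, burst frequency 0.2 Hz, pooled IBI
rate 8 Hz, 12–14 channels per burst.  The default session is 5,400 s with
drug onset at 2,700 s — one baseline and two post-drug windows; longer
horizons (e.g., onset + 6τ) are configured explicitly where a test needs
them.

**Perturbation.**  m(t) = 1 + (peak − 1)·exp(−(t − onset)/τ) after onset
(single-exponential relaxation; defaults peak 2.0, τ 2 h), plus an
additive recruitment boost to the participation probability (default
+0.2, capped at 1) decaying with the same τ — mirroring the transient
rise in channels per burst.

**Cord.**  24 channels, the first 12 flagged motoneurons; near-silent
quiescence (0.05 Hz/channel).  Episode onsets are spaced by uniform draws
from 300–600 s (onset-to-onset), durations uniform 30–60 s; after drug
onset the interval is multiplied by 3 (a configurable stand-in for the
persistent drop in episode frequency, not a calibrated value).  Each
episode holds 6–10 bursts (capped at duration/(burst duration + 2 s) so
intra-episode gaps stay well under the 10 s episode gap threshold),
tiling the episode from onset to end with ±30% jittered gaps; burst
durations are gamma(shape 16, mean 2 s).  The first episode onset is
drawn from U(5, 15) s so a 3 h drug-free run always contains between 18
and 36 episodes.

**What it does not emulate** — and hence what passing tests do not show
about real data: spike sorting and unit contamination, electrode drift,
non-stationary background, intra-burst rate envelopes (real bursts peak
early and decay), correlated channel recruitment, and any biophysical
mechanism of the recovery.  Parameter-recovery results quantify the
detector/metric chain against a known generative model, not biological
validity.

**Analytic expectations.**  For recovery tests, expected per-bin values
follow from the generative parameters: burst frequency = 1/interval;
pooled SRWB = n_ch·(p_eff(t)·m(t)·R_burst + R_bg); IBI rate = n_ch·R_bg;
overall rate = n_ch·R_bg + expected spikes-per-burst/interval — with the
smooth trajectories averaged over the bin by numerical quadrature.  The
detected SRWB carries a small (few percent) downward bias relative to
these expectations because the last qualified window of a burst can
extend a fraction of T into the background; this is inherent to the
windowing rule, affects baseline and post-drug bins nearly equally, and
cancels in normalized trajectories.

## Problem sizes and determinism

The test suite runs the detector-vs-oracle comparison on 200 random trains
of up to 500 spikes, parameter recovery on 20 replicate culture
simulations at the default 5,400 s session, the perturbation-recovery
check on 20 replicates of a 45,900 s session (onset + 6τ + one window),
BCa coverage on 500 null replicates at 2,000 resamples, and permutation
calibration against exhaustive enumeration on 2-vs-2 groups.  These sizes
give stable Monte-Carlo estimates at interactive runtimes.  Detection is
fully deterministic; all simulation and resampling flows from explicit
seeds.

## Known limitations

* The ISI-threshold detector assumes a separable bimodal span
  distribution; recordings with heavy burst-rate drift or very high tonic
  background blur the valley, and `threshold_override` is the intended
  escape hatch.
* Channel exclusion is a single pass; pathological inputs where exclusion
  changes the threshold enough to re-classify channels would need manual
  iteration.
* Bursts are assigned to bins by start time, so a burst straddling a bin
  edge contributes wholly to the earlier bin; with 900 s bins and ~1 s
  bursts the effect is negligible, but very long episodes near cord bin
  edges shift single episodes between adjacent bins.
* BCa intervals are computed for the mean difference only; other
  statistics would need their own jackknife.
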