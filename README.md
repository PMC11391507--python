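# burstkit

Network-burst detection and burst-dynamics analysis for multielectrode
spike recordings.

Developing neural circuits — dissociated cortical cultures on
multielectrode arrays (MEAs) and the isolated embryonic spinal cord alike —
fire in brief network bursts: near-synchronous periods of elevated spiking
across many channels.  When synaptic transmission is perturbed (for
example, by blocking GABA-A receptors at a known drug-onset time), some
features of this activity drift freely while others are homeostatically
pulled back to baseline.  `burstkit` provides the analysis chain needed to
ask which: burst detection, per-time-bin burst-dynamics features, percent
homeostatic recovery, and estimation statistics, plus a synthetic-data
generator so the whole pipeline can be tested without any recordings.

It is intended for electrophysiologists analysing event-table exports
(channel id + spike time) from MEA or silicon-probe recordings, and for
methodologists who want a tested, scriptable reference implementation of
the adaptive interspike-interval burst detector.

## The method

**Burst detection.**  Spikes are pooled across channels and the detector
examines the span `s_i = t[i+N-1] − t[i]` of every window of `N`
consecutive spikes.  The probability distribution of these spans is
typically bimodal — short within-burst spans, long between-burst spans —
and the threshold `T` is placed automatically at the longest-duration local
minimum of the (log-binned, smoothed) distribution.  A window qualifies
when its span is at most `T`; overlapping qualified windows are chained,
lengthening the burst one spike at a time.  A candidate becomes a *network
burst* when it contains a minimum total number of spikes (culture default
10) across a minimum number of channels (culture default 5); channels that
never join bursts or that fire continuously (noise) are excluded and
detection is re-run once.  For spinal-cord recordings, bursts separated by
short gaps are grouped into *episodes* of spontaneous network activity
(20–100 s clusters separated by minutes of quiescence), and all analysis is
restricted to the channels identified as motoneurons.

**Features per time bin.**  Overall spike rate, burst frequency,
interburst-interval (IBI) spike rate, mean burst duration, channels per
burst, and the headline quantity

    SRWB = (total spikes within bursts) / (summed burst durations)   [Hz]

— the spike rate within bursts, computed pooled or per burst (mean ± SD).
Trajectories are normalized to a predrug baseline bin.

**Homeostatic index.**  For a normalized feature that jumps to an extreme
within the first post-drug hour and then relaxes,

    index = 100 · (extreme − treated_24h) / (extreme − control_24h)  [%]

so 0% means no recovery, 100% a complete return to the control endpoint,
values above 100% an overshoot, negative values continued drift away.

**Estimation statistics.**  Group comparisons report the unpaired mean
difference with a bias-corrected-and-accelerated (BCa) bootstrap 95%
confidence interval (5,000 resamples) and a two-sided permutation p-value
(5,000 label reshuffles, +1/(n+1) correction).

**ΔF/F.**  Calcium-imaging ROI traces are converted to fractional
fluorescence change, `(I − B)/(B − A)`, with `B` the mean ROI intensity
over the 30 frames before episode onset and `A` the matching
autofluorescence baseline.

## Worked example

```python
import burstkit as bk

cfg = bk.SyntheticConfig.culture(seed=1)       # 20-channel culture, drug at t = 2700 s
rec, truth = bk.generate(cfg)                  # 375,334 spikes, 1,086 scheduled bursts
res = bk.analyze_recording(rec, bk.DetectionParams.culture())
print(res.isi.threshold, len(res.bursts))      # 0.152 s, 1080 bursts

bins = bk.make_culture_bins(cfg.drug_onset, [0, 0.25], total_duration=cfg.total_duration)
for m in bk.compute_metrics(res.recording, res.bursts, bins):
    print(m.bin.label, m.overall_spike_rate, m.srwb_pooled)
```

which prints:

```
baseline  rate   42.47  burst_f 0.1844  ibi 7.83  srwb   176.9  ch/burst 14.9
0h        rate  105.52  burst_f 0.2056  ibi 7.58  srwb   430.2  ch/burst 17.6
0.25h     rate   95.53  burst_f 0.1989  ibi 7.72  srwb   391.7  ch/burst 17.0
```

The detector recovers essentially every scheduled burst (1080 of 1086) and
places the threshold (152 ms) in the valley between within-burst and
between-burst timescales.  At drug onset the generator doubles the
within-burst rate and recruits extra channels, and the detected SRWB
follows: normalized to baseline it reads 1.00 → 2.43 → 2.21 across the
three bins, while the IBI spike rate stays at its background value
(≈ 8 Hz).  Running the homeostatic index on its canonical example,
`bk.homeostatic_index(5, 2, 1)`, prints `75.0` — a trajectory that rises
to 5× baseline and settles at 2× (control at 1×) has recovered 75% of the
way back.

The same stages are available from the shell:

```sh
burstkit simulate --mode culture --seed 1 --out spikes.csv --truth truth.csv
burstkit detect --input spikes.csv --out bursts.csv
burstkit metrics --input spikes.csv --bursts bursts.csv --drug-onset 2700 --out metrics.csv
burstkit run --out-dir demo/        # full simulate → detect → metrics → hindex → estimate
```

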