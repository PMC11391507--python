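"""Synthetic culture- and cord-style spike recordings with ground truth.

Two generative regimes are emulated:

* **culture** — tonic background spiking (homogeneous Poisson per channel)
  plus semiregular network bursts: burst onsets form a renewal process with
  gamma-distributed onset-to-onset intervals, each burst recruits a random
  subset of channels, and within-burst spiking is Poisson at an elevated
  per-channel rate.

* **cord** — episodes of spontaneous network activity lasting tens of
  seconds and separated by minutes of quiescence; each episode contains a
  handful of bursts, and only a flagged motoneuron subset of channels
  enters downstream analyses.

A perturbation at ``drug_onset`` multiplies the within-burst spike rate by

    m(t) = 1 + (peak - 1) * exp(-(t - onset) / tau)      (t >= onset)

relaxing exponentially back toward baseline (single-exponential recovery),
optionally boosts channel recruitment with the same time constant, and (cord)
lengthens the interval between episodes.  Generation is fully deterministic
given ``config.seed``; scheduled burst/episode intervals are returned as
ground truth alongside the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import SpikeRecording

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "multiplier",
    "generate",
    "generate_culture",
    "generate_cord",
    "analytic_expectations",
]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror a bursting cortical culture.

    Rates are Hz per channel, durations and times in seconds.  The culture
    defaults produce pooled magnitudes in the range reported for MEA
    cultures (pooled SRWB near 190 Hz, burst frequency 0.2 Hz, pooled
    interburst rate 8 Hz, 12–14 channels per burst).
    """

    mode: str = "culture"
    n_channels: int = 20
    background_rate: float = 0.4
    burst_rate_within: float = 15.0
    burst_duration_mean: float = 1.0
    burst_interval_mean: float = 5.0
    participation_prob: float = 0.6
    drug_onset: float = 2700.0
    srwb_multiplier_peak: float = 2.0
    recovery_tau: float = 7200.0
    recruitment_boost: float = 0.2
    total_duration: float = 5400.0
    seed: int = 0
    # cord-specific settings
    n_motoneuron: int = 12
    episode_duration_range: tuple[float, float] = (30.0, 60.0)
    episode_interval_range: tuple[float, float] = (300.0, 600.0)
    bursts_per_episode: tuple[int, int] = (6, 10)
    episode_interval_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("culture", "cord"):
            raise ValueError(f"unknown mode {self.mode!r}")
        positives = (
            self.background_rate,
            self.burst_rate_within,
            self.burst_duration_mean,
            self.burst_interval_mean,
            self.total_duration,
            self.recovery_tau,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("rates, durations and tau must be positive")
        if not 0 < self.participation_prob <= 1:
            raise ValueError("participation_prob must be in (0, 1]")
        if self.srwb_multiplier_peak < 1:
            raise ValueError("srwb_multiplier_peak must be >= 1")
        if self.recruitment_boost < 0:
            raise ValueError("recruitment_boost must be >= 0")
        if self.mode == "cord" and not 0 < self.n_motoneuron <= self.n_channels:
            raise ValueError("n_motoneuron must be in (0, n_channels]")

    @classmethod
    def culture(cls, **kw) -> "SyntheticConfig":
        return cls(mode="culture", **kw)

    @classmethod
    def cord(cls, **kw) -> "SyntheticConfig":
        """Cord defaults: 24 probe channels (12 motoneurons), near-silent
        quiescence, 30–60 s episodes every 5–10 min, ~2 s bursts, a 30 min
        baseline before the perturbation and a 3 h recording."""
        defaults = dict(
            mode="cord",
            n_channels=24,
            n_motoneuron=12,
            background_rate=0.05,
            burst_rate_within=10.0,
            burst_duration_mean=2.0,
            participation_prob=0.8,
            drug_onset=1800.0,
            recovery_tau=3600.0,
            recruitment_boost=0.1,
            total_duration=10800.0,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Scheduled intervals and the generative perturbation trajectory."""

    burst_intervals: list[tuple[float, float, frozenset[str]]]
    episode_intervals: list[tuple[float, float]] = field(default_factory=list)
    config: SyntheticConfig | None = None

    def multiplier_at(self, t) -> np.ndarray:
        return multiplier(t, self.config)


def multiplier(t, config: SyntheticConfig) -> np.ndarray:
    """Within-burst rate multiplier m(t): 1 before onset, exponential
    relaxation from the peak afterwards."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    post = t >= config.drug_onset
    out[post] += (config.srwb_multiplier_peak - 1.0) * np.exp(
        -(t[post] - config.drug_onset) / config.recovery_tau
    )
    return out


def _participation(t, config: SyntheticConfig) -> np.ndarray:
    """Channel recruitment probability, with the post-drug boost decaying
    at the same time constant as the rate multiplier."""
    t = np.asarray(t, dtype=float)
    p = np.full_like(t, config.participation_prob)
    post = t >= config.drug_onset
    p[post] += config.recruitment_boost * np.exp(
        -(t[post] - config.drug_onset) / config.recovery_tau
    )
    return np.minimum(p, 1.0)


def _channel_names(n: int) -> list[str]:
    return [f"ch{i:02d}" for i in range(n)]


def _background(rng, config, duration) -> list[np.ndarray]:
    out = []
    for _ in range(config.n_channels):
        k = rng.poisson(config.background_rate * duration)
        out.append(np.sort(rng.uniform(0.0, duration, size=k)))
    return out


def _burst_spikes(rng, config, onsets, durs):
    """Draw participation, per-channel Poisson counts and uniform spike
    times for a schedule of bursts.  Returns (times, channel_idx, who)."""
    n_b = onsets.size
    mids = onsets + durs / 2.0
    m = multiplier(mids, config)
    p = _participation(mids, config)
    who = rng.random((n_b, config.n_channels)) < p[:, None]
    lam = who * (config.burst_rate_within * m * durs)[:, None]
    counts = rng.poisson(lam)
    total = int(counts.sum())
    b_idx = np.repeat(np.arange(n_b * config.n_channels) // config.n_channels, counts.ravel())
    c_idx = np.repeat(np.arange(n_b * config.n_channels) % config.n_channels, counts.ravel())
    times = onsets[b_idx] + durs[b_idx] * rng.random(total)
    return times, c_idx, who


def _assemble(config, bg, burst_times, burst_chan, mode, motoneurons) -> SpikeRecording:
    spikes = {}
    names = _channel_names(config.n_channels)
    order = np.argsort(burst_chan, kind="stable")
    burst_times = burst_times[order]
    burst_chan = burst_chan[order]
    bounds = np.searchsorted(burst_chan, np.arange(config.n_channels + 1))
    for i, name in enumerate(names):
        t = np.concatenate((bg[i], burst_times[bounds[i] : bounds[i + 1]]))
        spikes[name] = np.unique(t)  # sorted; exact float ties have measure zero
    return SpikeRecording(
        spikes=spikes,
        duration=config.total_duration,
        mode=mode,
        motoneuron_channels=frozenset(motoneurons),
    )


def generate_culture(config: SyntheticConfig) -> tuple[SpikeRecording, GroundTruth]:
    """Culture-style recording: tonic background plus semiregular network bursts."""
    rng = np.random.default_rng(config.seed)
    shape = 4.0  # semiregular renewal: gamma intervals/durations, CV = 0.5
    onsets, durs = [], []
    t_on = rng.gamma(shape, config.burst_interval_mean / shape)
    while t_on < config.total_duration:
        dur = rng.gamma(shape, config.burst_duration_mean / shape)
        if t_on + dur > config.total_duration:
            break
        onsets.append(t_on)
        durs.append(dur)
        gap = rng.gamma(shape, config.burst_interval_mean / shape)
        t_on = max(t_on + gap, t_on + dur + 0.2)
    onsets = np.asarray(onsets)
    durs = np.asarray(durs)
    bg = _background(rng, config, config.total_duration)
    times, c_idx, who = _burst_spikes(rng, config, onsets, durs)
    recording = _assemble(config, bg, times, c_idx, "culture", frozenset())
    names = _channel_names(config.n_channels)
    truth = GroundTruth(
        burst_intervals=[
            (float(s), float(s + d), frozenset(np.array(names)[w]))
            for s, d, w in zip(onsets, durs, who)
        ],
        config=config,
    )
    return recording, truth


def generate_cord(config: SyntheticConfig) -> tuple[SpikeRecording, GroundTruth]:
    """Cord-style recording: episodes of bursts separated by quiescence.

    Episode onset-to-onset intervals are drawn uniformly from
    ``episode_interval_range`` (multiplied by ``episode_interval_factor``
    once the perturbation is active); episode durations uniformly from
    ``episode_duration_range``.  Bursts tile the episode from its onset to
    its end with jittered gaps.
    """
    rng = np.random.default_rng(config.seed)
    ep_lo, ep_hi = config.episode_duration_range
    onset = rng.uniform(5.0, 15.0)
    ep_intervals: list[tuple[float, float]] = []
    all_onsets: list[float] = []
    all_durs: list[float] = []
    b_lo, b_hi = config.bursts_per_episode
    while True:
        D = rng.uniform(ep_lo, ep_hi)
        if onset + D > config.total_duration:
            break
        n_b = int(rng.integers(b_lo, b_hi + 1))
        n_b = max(2, min(n_b, int(D / (config.burst_duration_mean + 2.0))))
        durs = rng.gamma(16.0, config.burst_duration_mean / 16.0, size=n_b)
        if durs.sum() > 0.8 * D:
            durs *= 0.8 * D / durs.sum()
        gap_total = D - durs.sum()
        w = 1.0 + 0.3 * rng.uniform(-1.0, 1.0, size=n_b - 1)
        gaps = gap_total * w / w.sum()
        starts = onset + np.concatenate(([0.0], np.cumsum(durs[:-1] + gaps)))
        all_onsets.extend(starts)
        all_durs.extend(durs)
        ep_intervals.append((float(onset), float(onset + D)))
        interval = rng.uniform(*config.episode_interval_range)
        if onset >= config.drug_onset:
            interval *= config.episode_interval_factor
        onset = onset + interval
    onsets = np.asarray(all_onsets)
    durs = np.asarray(all_durs)
    bg = _background(rng, config, config.total_duration)
    times, c_idx, who = _burst_spikes(rng, config, onsets, durs)
    motoneurons = _channel_names(config.n_channels)[: config.n_motoneuron]
    recording = _assemble(config, bg, times, c_idx, "cord", motoneurons)
    names = _channel_names(config.n_channels)
    truth = GroundTruth(
        burst_intervals=[
            (float(s), float(s + d), frozenset(np.array(names)[w]))
            for s, d, w in zip(onsets, durs, who)
        ],
        episode_intervals=ep_intervals,
        config=config,
    )
    return recording, truth


def generate(config: SyntheticConfig) -> tuple[SpikeRecording, GroundTruth]:
    return generate_culture(config) if config.mode == "culture" else generate_cord(config)


def analytic_expectations(config: SyntheticConfig, bins) -> dict[str, dict[str, float]]:
    """Closed-form expected metric values per bin from the generative model.

    For each bin the instantaneous expectations are averaged over the bin
    (numerical quadrature of the smooth trajectories m(t) and p_eff(t)):

    * burst_frequency = 1 / burst_interval_mean (culture)
    * srwb_pooled     = n_ch * (p_eff(t) * m(t) * R_burst + R_bg)
    * ibi_spike_rate  = n_ch * R_bg
    * overall rate    = n_ch * R_bg + spikes-per-burst / interval

    Cord bins use the motoneuron channel count and the scheduled episode
    geometry (mean episode duration; episode frequency from the interval
    range, lengthened post-drug).
    """
    out: dict[str, dict[str, float]] = {}
    n_ch = config.n_motoneuron if config.mode == "cord" else config.n_channels
    for b in bins:
        t = np.linspace(b.start, b.end, 201)
        m = multiplier(t, config)
        p = _participation(t, config)
        srwb_inst = n_ch * (p * m * config.burst_rate_within + config.background_rate)
        srwb_mean = float(np.trapezoid(srwb_inst, t) / (b.end - b.start))
        spikes_per_burst = (
            n_ch
            * float(np.trapezoid(p * m, t) / (b.end - b.start))
            * config.burst_rate_within
            * config.burst_duration_mean
        )
        e: dict[str, float] = {
            "ibi_spike_rate": n_ch * config.background_rate,
            "srwb_pooled": srwb_mean,
        }
        if config.mode == "culture":
            e["burst_frequency"] = 1.0 / config.burst_interval_mean
            e["overall_spike_rate"] = (
                n_ch * config.background_rate
                + spikes_per_burst / config.burst_interval_mean
            )
            e["channels_per_burst"] = float(
                np.trapezoid(p, t) / (b.end - b.start)
            ) * config.n_channels
        else:
            iv = float(np.mean(config.episode_interval_range))
            if b.start >= config.drug_onset:
                iv *= config.episode_interval_factor
            e["episode_duration"] = float(np.mean(config.episode_duration_range))
            e["episode_frequency"] = 1.0 / iv
        out[b.label] = e
    return out
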