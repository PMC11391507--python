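"""Per-time-bin burst-dynamics features and baseline normalization.

The features mirror standard MEA burst analysis: overall spike rate, burst
frequency, interburst-interval (IBI) spike rate, mean burst duration, spike
rate within bursts (SRWB, pooled or per-burst averaged), channels per
burst, and — for episodic cord recordings — episode duration, episode
spike rate and interepisode-interval (IEI) spike rate.  Line-graph style
trajectories are normalized to a designated baseline bin.

Missing-value policy: event-rate metrics (overall spike rate, burst
frequency) are 0 in empty bins; within-structure metrics (SRWB, durations,
channels per burst, episode metrics) are NaN when no structure exists —
"no measurement", not zero.  Bursts and episodes are assigned to a bin by
their start time and belong wholly to that bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .detection import Burst, Episode, SpikeRecording

__all__ = [
    "TimeBin",
    "BinnedMetrics",
    "NormalizedSeries",
    "make_culture_bins",
    "make_cord_bins",
    "overall_spike_rate",
    "burst_frequency",
    "ibi_spike_rate",
    "srwb",
    "channels_per_burst",
    "mean_burst_duration",
    "episode_metrics",
    "compute_bin_metrics",
    "compute_metrics",
    "normalize_to_baseline",
]

#: names of the per-bin features carried by :class:`BinnedMetrics`
FEATURES = (
    "overall_spike_rate",
    "burst_frequency",
    "ibi_spike_rate",
    "mean_burst_duration",
    "srwb_pooled",
    "srwb_mean",
    "srwb_sd",
    "channels_per_burst",
    "episode_duration",
    "episode_spike_rate",
    "iei_spike_rate",
)


@dataclass(frozen=True)
class TimeBin:
    """Half-open analysis window [start, end), labelled for display."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("bin end must exceed bin start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BinnedMetrics:
    """Burst-dynamics feature vector for one time bin (NaN = missing)."""

    bin: TimeBin
    overall_spike_rate: float = 0.0
    burst_frequency: float = 0.0
    ibi_spike_rate: float = math.nan
    mean_burst_duration: float = math.nan
    srwb_pooled: float = math.nan
    srwb_mean: float = math.nan
    srwb_sd: float = math.nan
    channels_per_burst: float = math.nan
    episode_duration: float = math.nan
    episode_spike_rate: float = math.nan
    iei_spike_rate: float = math.nan
    n_bursts: int = 0
    n_episodes: int = 0

    def value(self, feature: str) -> float:
        return getattr(self, feature)


@dataclass
class NormalizedSeries:
    """One feature's per-bin values divided by its baseline value."""

    feature: str
    baseline_value: float
    bins: list[TimeBin]
    values: np.ndarray

    def value(self, label: str) -> float:
        for b, v in zip(self.bins, self.values):
            if b.label == label:
                return float(v)
        raise KeyError(label)


def make_culture_bins(
    drug_onset: float,
    offsets_h=(0.0, 0.5, 1.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0),
    width: float = 900.0,
    total_duration: float | None = None,
) -> list[TimeBin]:
    """Culture protocol bins: one predrug baseline window plus 900 s windows
    starting at the given hour offsets after drug onset.  Offsets whose
    window would run past ``total_duration`` are dropped."""
    bins = [TimeBin("baseline", drug_onset - width, drug_onset)]
    for h in offsets_h:
        start = drug_onset + h * 3600.0
        if total_duration is not None and start + width > total_duration:
            continue
        label = f"{h:g}h"
        bins.append(TimeBin(label, start, start + width))
    return bins


def make_cord_bins(
    drug_onset: float, total_duration: float, width: float = 1800.0
) -> list[TimeBin]:
    """Cord protocol bins: a 30 min baseline before drug onset, then
    contiguous 30 min bins until the end of the recording."""
    bins = [TimeBin("baseline", drug_onset - width, drug_onset)]
    k = 0
    while drug_onset + (k + 1) * width <= total_duration + 1e-9:
        start = drug_onset + k * width
        label = f"{int(start - drug_onset) // 60}-{int(start - drug_onset + width) // 60}min"
        bins.append(TimeBin(label, start, start + width))
        k += 1
    return bins


# ---------------------------------------------------------------------------
# spike counting helpers (closed bursts, half-open bins)
# ---------------------------------------------------------------------------


def _bin_spike_count(recording: SpikeRecording, bin: TimeBin, channels) -> int:
    total = 0
    for c in channels:
        t = recording.spikes[c]
        total += int(
            np.searchsorted(t, bin.end, "left") - np.searchsorted(t, bin.start, "left")
        )
    return total


def _bursts_in_bin(bursts: list[Burst], bin: TimeBin) -> list[Burst]:
    return [b for b in bursts if bin.start <= b.start < bin.end]


def _in_burst_count_in_bin(
    recording: SpikeRecording, bursts: list[Burst], bin: TimeBin, channels
) -> tuple[int, float]:
    """Spikes inside any burst AND inside the bin; and the total burst time
    overlapping the bin.  Bursts are closed intervals, the bin half-open."""
    count = 0
    overlap = 0.0
    for b in bursts:
        lo = max(b.start, bin.start)
        hi = min(b.end, bin.end)
        if hi < lo:
            continue
        overlap += max(0.0, min(b.end, bin.end) - max(b.start, bin.start))
        for c in channels:
            t = recording.spikes[c]
            if b.end < bin.end:
                right = np.searchsorted(t, b.end, "right")
            else:
                right = np.searchsorted(t, bin.end, "left")
            left = np.searchsorted(t, lo, "left")
            count += int(max(0, right - left))
    return count, overlap


# ---------------------------------------------------------------------------
# feature operations
# ---------------------------------------------------------------------------


def overall_spike_rate(recording: SpikeRecording, bin: TimeBin, channels=None) -> float:
    """Total spikes across channels in the bin divided by the bin duration (Hz)."""
    channels = recording.analysis_channels() if channels is None else channels
    return _bin_spike_count(recording, bin, channels) / bin.duration


def burst_frequency(bursts: list[Burst], bin: TimeBin) -> float:
    """Number of bursts starting in the bin divided by the bin duration (Hz)."""
    return len(_bursts_in_bin(bursts, bin)) / bin.duration


def ibi_spike_rate(
    recording: SpikeRecording, bursts: list[Burst], bin: TimeBin, channels=None
) -> float:
    """Spikes outside bursts divided by the total interburst time (Hz).

    NaN when bursts fill the whole bin (no interburst time).
    """
    channels = recording.analysis_channels() if channels is None else channels
    total = _bin_spike_count(recording, bin, channels)
    inside, overlap = _in_burst_count_in_bin(recording, bursts, bin, channels)
    ibi_time = bin.duration - overlap
    if ibi_time <= 0:
        return math.nan
    return (total - inside) / ibi_time


def srwb(bursts: list[Burst], mode: str = "pooled") -> float | tuple[float, float]:
    """Spike rate within bursts (Hz).

    ``mode="pooled"``: total spikes in all bursts divided by the summed
    burst durations.  ``mode="per_burst"``: mean and sample standard
    deviation (ddof=1; sd 0 with a warning for a single burst) of the
    per-burst spike/duration ratios.
    """
    usable = [b for b in bursts if b.duration > 0]
    if len(usable) < len(bursts):
        warnings.warn("zero-duration bursts excluded from SRWB", stacklevel=2)
    if not usable:
        return math.nan if mode == "pooled" else (math.nan, math.nan)
    if mode == "pooled":
        return sum(b.n_spikes for b in usable) / sum(b.duration for b in usable)
    if mode == "per_burst":
        rates = np.array([b.n_spikes / b.duration for b in usable])
        if rates.size == 1:
            warnings.warn("single burst: SRWB sd is 0", stacklevel=2)
            return float(rates[0]), 0.0
        return float(rates.mean()), float(rates.std(ddof=1))
    raise ValueError(f"unknown SRWB mode {mode!r}")


def channels_per_burst(bursts: list[Burst]) -> float:
    """Mean number of channels contributing at least one spike per burst."""
    if not bursts:
        return math.nan
    return float(np.mean([b.n_channels for b in bursts]))


def mean_burst_duration(bursts: list[Burst]) -> float:
    if not bursts:
        return math.nan
    return float(np.mean([b.duration for b in bursts]))


def episode_metrics(
    episodes: list[Episode], recording: SpikeRecording, bin: TimeBin, channels=None
) -> dict[str, float]:
    """Per-bin episode features, averaged when several episodes fall in the bin.

    Returns episode_duration, episode_spike_rate (spikes anywhere in the
    episode over its duration), srwb_in_episode (spikes during bursts within
    the episode over the summed burst durations; outside-burst spikes
    excluded), burst_duration (mean burst period within episodes), and
    iei_spike_rate (spikes outside episodes over the outside-episode time in
    the bin; NaN when episodes cover the whole bin).
    """
    channels = recording.analysis_channels() if channels is None else channels
    in_bin = [e for e in episodes if bin.start <= e.start < bin.end]
    out: dict[str, float] = {}
    if in_bin:
        durations, rates, srwbs, bdurs = [], [], [], []
        for e in in_bin:
            durations.append(e.duration)
            n_sp = 0
            for c in channels:
                t = recording.spikes[c]
                n_sp += int(
                    np.searchsorted(t, e.end, "right") - np.searchsorted(t, e.start, "left")
                )
            rates.append(n_sp / e.duration if e.duration > 0 else math.nan)
            srwbs.append(srwb(e.bursts, "pooled"))
            bdurs.append(mean_burst_duration(e.bursts))
        out["episode_duration"] = float(np.mean(durations))
        out["episode_spike_rate"] = float(np.nanmean(rates))
        out["srwb_in_episode"] = float(np.nanmean(srwbs))
        out["burst_duration"] = float(np.nanmean(bdurs))
    else:
        out.update(
            episode_duration=math.nan,
            episode_spike_rate=math.nan,
            srwb_in_episode=math.nan,
            burst_duration=math.nan,
        )
    # interepisode-interval spike rate over the bin
    total = _bin_spike_count(recording, bin, channels)
    inside = 0
    overlap = 0.0
    for e in episodes:
        lo = max(e.start, bin.start)
        hi = min(e.end, bin.end)
        if hi < lo:
            continue
        overlap += hi - lo
        for c in channels:
            t = recording.spikes[c]
            if e.end < bin.end:
                right = np.searchsorted(t, e.end, "right")
            else:
                right = np.searchsorted(t, bin.end, "left")
            inside += int(max(0, right - np.searchsorted(t, lo, "left")))
    iei_time = bin.duration - overlap
    out["iei_spike_rate"] = (total - inside) / iei_time if iei_time > 0 else math.nan
    return out


def compute_bin_metrics(
    recording: SpikeRecording,
    bursts: list[Burst],
    bin: TimeBin,
    episodes: list[Episode] | None = None,
) -> BinnedMetrics:
    """Assemble the full feature vector for one bin."""
    channels = recording.analysis_channels()
    in_bin = _bursts_in_bin(bursts, bin)
    m = BinnedMetrics(bin=bin)
    m.overall_spike_rate = overall_spike_rate(recording, bin, channels)
    m.burst_frequency = burst_frequency(bursts, bin)
    m.ibi_spike_rate = ibi_spike_rate(recording, bursts, bin, channels)
    m.n_bursts = len(in_bin)
    if in_bin:
        m.mean_burst_duration = mean_burst_duration(in_bin)
        m.srwb_pooled = srwb(in_bin, "pooled")
        m.srwb_mean, m.srwb_sd = srwb(in_bin, "per_burst")
        m.channels_per_burst = channels_per_burst(in_bin)
    if recording.mode == "cord" and episodes is not None:
        ep = episode_metrics(episodes, recording, bin, channels)
        m.episode_duration = ep["episode_duration"]
        m.episode_spike_rate = ep["episode_spike_rate"]
        m.iei_spike_rate = ep["iei_spike_rate"]
        m.n_episodes = len([e for e in episodes if bin.start <= e.start < bin.end])
        if not math.isnan(ep["srwb_in_episode"]):
            # cord convention: SRWB and burst duration are the
            # episode-averaged within-episode values
            m.srwb_pooled = ep["srwb_in_episode"]
            m.mean_burst_duration = ep["burst_duration"]
    return m


def compute_metrics(
    recording: SpikeRecording,
    bursts: list[Burst],
    bins: list[TimeBin],
    episodes: list[Episode] | None = None,
) -> list[BinnedMetrics]:
    return [compute_bin_metrics(recording, bursts, b, episodes) for b in bins]


def normalize_to_baseline(
    metrics: list[BinnedMetrics],
    baseline_label: str = "baseline",
    features=FEATURES,
) -> dict[str, NormalizedSeries]:
    """Divide each feature's per-bin values by its baseline-bin value.

    Raises when the baseline value is missing or zero for a requested
    feature; the baseline bin maps to exactly 1.
    """
    by_label = {m.bin.label: m for m in metrics}
    if baseline_label not in by_label:
        raise ValueError(f"baseline bin {baseline_label!r} not present")
    base = by_label[baseline_label]
    out: dict[str, NormalizedSeries] = {}
    for f in features:
        b = base.value(f)
        if b == 0 or math.isnan(b):
            raise ValueError(f"cannot normalize feature {f}")
        values = np.array([m.value(f) / b for m in metrics])
        out[f] = NormalizedSeries(f, float(b), [m.bin for m in metrics], values)
    return out
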