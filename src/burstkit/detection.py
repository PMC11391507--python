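"""Adaptive ISI-threshold detection of network bursts and activity episodes.

A network burst is a brief period of synchronized, elevated-rate spiking
across many electrode channels.  Detection follows the classic adaptive
interspike-interval scheme: pool spikes across channels, look at the
distribution of the time spanned by ``N`` consecutive pooled spikes, place
the threshold ``T`` in the valley of that (typically bimodal) distribution,
and call any maximal chain of windows of ``N`` spikes spanning at most ``T``
a burst.  Network-level criteria (minimum total spikes, minimum number of
participating channels) then filter the candidates.  For episodic
preparations (embryonic spinal cord), bursts separated by short gaps are
further grouped into episodes of spontaneous network activity.

Everything in this module is deterministic given its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionError",
    "SpikeRecording",
    "DetectionParams",
    "ISIDistribution",
    "Burst",
    "Episode",
    "pool_spikes",
    "estimate_threshold",
    "detect_bursts",
    "filter_network_bursts",
    "exclude_channels",
    "detect_episodes",
    "detect_network_bursts",
    "analyze_recording",
    "DetectionResult",
]


class DetectionError(ValueError):
    """Raised when detection cannot proceed on the given input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpikeRecording:
    """Multi-channel extracellular spike-event record.

    Parameters
    ----------
    spikes
        Mapping channel id -> strictly increasing spike times in seconds,
        with t = 0 at the start of the recording.
    duration
        Recording length in seconds.
    mode
        ``"culture"`` (dissociated cortical culture on an MEA) or ``"cord"``
        (isolated embryonic spinal cord probe recording).
    motoneuron_channels
        Channels identified as motoneurons (cord mode); cord-mode analyses
        are restricted to these channels.
    """

    spikes: dict[str, np.ndarray]
    duration: float
    mode: str = "culture"
    motoneuron_channels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mode not in ("culture", "cord"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        clean: dict[str, np.ndarray] = {}
        for ch, t in self.spikes.items():
            t = np.asarray(t, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"channel {ch}: spike times must be 1-d")
            if t.size:
                if np.any(np.diff(t) <= 0):
                    raise ValueError(f"channel {ch}: spike times must be strictly increasing")
                if t[0] < 0 or t[-1] > self.duration:
                    raise ValueError(f"channel {ch}: spike times outside [0, duration]")
            clean[str(ch)] = t
        self.spikes = clean
        self.motoneuron_channels = frozenset(str(c) for c in self.motoneuron_channels)
        if not self.motoneuron_channels <= set(self.spikes):
            raise ValueError("motoneuron_channels must be a subset of channels")
        if self.mode == "cord" and not self.motoneuron_channels:
            warnings.warn("cord-mode recording without motoneuron channels", stacklevel=2)

    @property
    def channels(self) -> list[str]:
        return list(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    def analysis_channels(self) -> list[str]:
        """Channels entering the analysis: motoneurons in cord mode, else all."""
        if self.mode == "cord" and self.motoneuron_channels:
            return [c for c in self.spikes if c in self.motoneuron_channels]
        return self.channels

    def subset(self, channels) -> "SpikeRecording":
        keep = [c for c in self.spikes if c in set(channels)]
        if not keep:
            raise DetectionError("no channels selected")
        return SpikeRecording(
            spikes={c: self.spikes[c] for c in keep},
            duration=self.duration,
            mode=self.mode,
            motoneuron_channels=self.motoneuron_channels & set(keep),
        )


@dataclass
class DetectionParams:
    """Burst/network detection parameters.

    ``n_spikes`` is the window size N of the ISI-threshold detector (a burst
    window is N consecutive pooled spikes spanning at most T seconds).
    ``min_total_spikes`` and ``min_channels`` are the network-burst criteria
    applied to each candidate.  ``threshold_override`` bypasses automatic
    threshold estimation.
    """

    n_spikes: int = 10
    min_total_spikes: int = 10
    min_channels: int = 5
    threshold_override: float | None = None
    exclusion_active_fraction: float = 0.8
    exclusion_min_burst_participation: float = 0.05
    # ISI span-histogram settings for automatic threshold estimation
    isi_n_bins: int = 64
    isi_smooth_window: int = 3
    isi_min_prominence: float = 0.005

    def __post_init__(self) -> None:
        if self.n_spikes < 2:
            raise ValueError("n_spikes (N) must be >= 2")
        if self.min_total_spikes < 1 or self.min_channels < 1:
            raise ValueError("network criteria must be >= 1")
        if not 0 < self.exclusion_active_fraction <= 1:
            raise ValueError("exclusion_active_fraction must be in (0, 1]")
        if not 0 <= self.exclusion_min_burst_participation < 1:
            raise ValueError("exclusion_min_burst_participation must be in [0, 1)")
        if self.n_spikes < self.min_total_spikes:
            warnings.warn(
                "detector window N < min_total_spikes: the window criterion is "
                "weaker than the network criterion",
                stacklevel=2,
            )

    @classmethod
    def culture(cls, **kw) -> "DetectionParams":
        """Defaults for cortical cultures: N=10, >=10 spikes on >=5 channels."""
        return cls(**{"n_spikes": 10, "min_total_spikes": 10, "min_channels": 5, **kw})

    @classmethod
    def cord(cls, **kw) -> "DetectionParams":
        """Defaults for the isolated spinal cord: N=6, >=6 spikes on >=4 channels."""
        return cls(**{"n_spikes": 6, "min_total_spikes": 6, "min_channels": 4, **kw})


@dataclass
class ISIDistribution:
    """Distribution of N-spike spans used to place the burst threshold T.

    ``order`` is N-1 (number of intervals spanned); ``minima`` holds the
    candidate local-minimum durations (bin centres, seconds) and
    ``threshold`` the selected longest-duration minimum (or the override).
    """

    order: int
    bin_edges: np.ndarray
    probabilities: np.ndarray
    smoothed: np.ndarray
    minima: list[float]
    threshold: float

    def __post_init__(self) -> None:
        if self.probabilities.size and abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("span probabilities must sum to 1")
        if self.minima and self.threshold not in self.minima:
            raise ValueError("threshold must be one of the candidate minima")


@dataclass
class Burst:
    """A detected network burst: closed time interval [start, end].

    A spike exactly at a boundary belongs to the burst.  ``spikes_per_channel``
    counts spikes of each analysis channel inside the interval.
    """

    start: float
    end: float
    spikes_per_channel: dict[str, int] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_spikes(self) -> int:
        return int(sum(self.spikes_per_channel.values()))

    @property
    def n_channels(self) -> int:
        return int(sum(1 for v in self.spikes_per_channel.values() if v > 0))


@dataclass
class Episode:
    """A cluster of bursts (spontaneous-network-activity episode)."""

    bursts: list[Burst]

    def __post_init__(self) -> None:
        if not self.bursts:
            raise ValueError("episode must contain at least one burst")
        starts = [b.start for b in self.bursts]
        if starts != sorted(starts):
            raise ValueError("episode bursts must be time-ordered")

    @property
    def start(self) -> float:
        return self.bursts[0].start

    @property
    def end(self) -> float:
        return self.bursts[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_spikes(self) -> int:
        return int(sum(b.n_spikes for b in self.bursts))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def pool_spikes(recording: SpikeRecording, channel_subset=None) -> np.ndarray:
    """Merge per-channel spike times into one nondecreasing pooled train."""
    if channel_subset is None:
        chans = recording.analysis_channels()
    else:
        chans = [c for c in recording.channels if c in set(channel_subset)]
        missing = set(channel_subset) - set(recording.channels)
        if missing:
            raise DetectionError(f"unknown channels in subset: {sorted(missing)}")
    if not chans:
        raise DetectionError("no channels selected")
    arrays = [recording.spikes[c] for c in chans]
    pooled = np.concatenate(arrays) if arrays else np.empty(0)
    pooled.sort(kind="stable")
    return pooled


def _plateau_minima(smoothed: np.ndarray, floor: float) -> list[int]:
    """Indices of (plateau) local minima with a minimum prominence.

    A run of tied values is a local minimum if the nearest differing values
    on both sides are larger.  The candidate must additionally be flanked on
    both sides by some bin exceeding it by ``floor`` probability mass; this
    keeps noise dips in the sparse tail of the span histogram from competing
    with the genuine valley.  The index returned for a plateau (e.g., the
    empty valley of a cleanly bimodal distribution) is its middle bin, so
    the threshold sits inside the valley rather than hugging its upper edge.
    """
    n = smoothed.size
    # group consecutive equal values into runs
    change = np.flatnonzero(np.diff(smoothed) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))  # half-open runs [start, end)
    out: list[int] = []
    for k in range(len(starts)):
        i, j = starts[k], ends[k] - 1
        if i == 0 or j == n - 1:
            continue  # boundary runs cannot be interior minima
        v = smoothed[i]
        if smoothed[i - 1] <= v or smoothed[j + 1] <= v:
            continue
        if smoothed[:i].max() < v + floor or smoothed[j + 1 :].max() < v + floor:
            continue
        out.append((i + j) // 2)
    return out


def estimate_threshold(pooled: np.ndarray, params: DetectionParams) -> ISIDistribution:
    """Estimate the burst threshold T from the pooled N-spike span distribution.

    Spans ``s_i = t[i+N-1] - t[i]`` are histogrammed on logarithmically
    spaced bins, lightly smoothed, and the local minimum at the longest
    duration is taken as T (bin centre, seconds).  With
    ``params.threshold_override`` set, that value is used directly and no
    minima search is performed.
    """
    n = params.n_spikes
    t = np.asarray(pooled, dtype=float)
    if params.threshold_override is not None:
        return ISIDistribution(
            order=n - 1,
            bin_edges=np.empty(0),
            probabilities=np.empty(0),
            smoothed=np.empty(0),
            minima=[],
            threshold=float(params.threshold_override),
        )
    if t.size < 2 * n:
        raise DetectionError("insufficient spikes for threshold estimation")
    spans = t[n - 1 :] - t[: -(n - 1)]
    positive = spans[spans > 0]
    if positive.size == 0:
        raise DetectionError(
            "all spike spans are zero; cannot estimate a threshold — "
            "set threshold_override (T) explicitly"
        )
    lo = min(1e-4, float(positive.min()) / 2.0)
    hi = float(spans.max())
    edges = np.geomspace(lo, hi, params.isi_n_bins + 1)
    edges[-1] = np.nextafter(hi, np.inf)  # include the maximum span
    counts, _ = np.histogram(np.clip(spans, lo, None), bins=edges)
    probabilities = counts / counts.sum()
    # centred moving average; 'nearest' edge handling keeps length fixed
    from scipy.ndimage import uniform_filter1d

    smoothed = uniform_filter1d(
        probabilities, size=params.isi_smooth_window, mode="nearest"
    )
    centers = np.sqrt(edges[:-1] * edges[1:])
    idx = _plateau_minima(smoothed, params.isi_min_prominence)
    minima = [float(centers[i]) for i in idx]
    if not minima:
        raise DetectionError(
            "no local minimum found in the inter-spike-interval span "
            "distribution; inspect the distribution and set "
            "threshold_override (T) explicitly"
        )
    return ISIDistribution(
        order=n - 1,
        bin_edges=edges,
        probabilities=probabilities,
        smoothed=smoothed,
        minima=minima,
        threshold=max(minima),
    )


def detect_bursts(pooled: np.ndarray, threshold: float, n_spikes: int) -> np.ndarray:
    """Detect candidate burst intervals on a pooled spike train.

    A window of ``n_spikes`` consecutive spikes qualifies when it spans at
    most ``threshold`` seconds; qualified windows whose time intervals
    overlap (the detector advances one spike at a time, lengthening a burst
    while the next window still qualifies) merge into a single burst running
    from the first spike of its first window to the last spike of its last
    window.

    Returns an array of shape (k, 2) of [start, end] times, nonoverlapping
    and time-ordered.  Fewer than ``n_spikes`` spikes yields an empty array.
    """
    if threshold <= 0:
        raise ValueError("threshold T must be positive")
    if n_spikes < 2:
        raise ValueError("n_spikes (N) must be >= 2")
    t = np.asarray(pooled, dtype=float)
    if t.size < n_spikes:
        return np.empty((0, 2))
    spans = t[n_spikes - 1 :] - t[: -(n_spikes - 1)]
    q = np.flatnonzero(spans <= threshold)
    if q.size == 0:
        return np.empty((0, 2))
    starts = t[q]
    ends = t[q + n_spikes - 1]  # nondecreasing because t is sorted
    new_burst = np.concatenate(([True], starts[1:] > ends[:-1]))
    group = np.cumsum(new_burst) - 1
    first = np.flatnonzero(new_burst)
    last = np.concatenate((first[1:] - 1, [q.size - 1]))
    return np.column_stack((starts[first], ends[last]))


def _counts_in_intervals(times: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Spikes of one channel inside each closed interval [start, end]."""
    left = np.searchsorted(times, intervals[:, 0], side="left")
    right = np.searchsorted(times, intervals[:, 1], side="right")
    return right - left


def filter_network_bursts(
    candidates: np.ndarray,
    recording: SpikeRecording,
    params: DetectionParams,
    channel_subset=None,
) -> list[Burst]:
    """Apply the network-burst criteria and populate per-channel counts.

    A candidate is kept when its total spike count across channels is at
    least ``min_total_spikes`` and at least ``min_channels`` channels fire
    inside it.
    """
    intervals = np.asarray(candidates, dtype=float).reshape(-1, 2)
    if intervals.size == 0:
        return []
    chans = (
        recording.analysis_channels()
        if channel_subset is None
        else [c for c in recording.channels if c in set(channel_subset)]
    )
    counts = np.vstack(
        [_counts_in_intervals(recording.spikes[c], intervals) for c in chans]
    )  # (n_channels, n_bursts)
    totals = counts.sum(axis=0)
    n_active = (counts > 0).sum(axis=0)
    keep = (totals >= params.min_total_spikes) & (n_active >= params.min_channels)
    bursts = []
    for j in np.flatnonzero(keep):
        per_channel = {c: int(counts[i, j]) for i, c in enumerate(chans)}
        bursts.append(Burst(float(intervals[j, 0]), float(intervals[j, 1]), per_channel))
    return bursts


def exclude_channels(
    recording: SpikeRecording, bursts: list[Burst], params: DetectionParams
) -> SpikeRecording:
    """Drop channels that never join bursts or fire continuously (noise).

    A channel is removed when the fraction of bursts containing at least one
    of its spikes falls below ``exclusion_min_burst_participation``, or when
    its out-of-burst spike count exceeds ``exclusion_active_fraction`` times
    what firing continuously at its overall mean rate would produce in the
    total interburst time (i.e., the channel is about as dense outside
    bursts as overall — constantly active).
    """
    if not bursts:
        warnings.warn("no bursts available; channel exclusion skipped", stacklevel=2)
        return recording
    n_bursts = len(bursts)
    burst_time = sum(b.duration for b in bursts)
    ibi_time = recording.duration - burst_time
    intervals = np.array([[b.start, b.end] for b in bursts])
    keep = []
    for c in recording.analysis_channels():
        t = recording.spikes[c]
        in_counts = _counts_in_intervals(t, intervals)
        participation = float(np.count_nonzero(in_counts)) / n_bursts
        if participation < params.exclusion_min_burst_participation:
            continue
        out_count = t.size - int(in_counts.sum())
        mean_rate = t.size / recording.duration
        if ibi_time > 0 and out_count > params.exclusion_active_fraction * mean_rate * ibi_time:
            continue
        keep.append(c)
    if not keep:
        raise DetectionError("no channels survive exclusion")
    # channels outside the analysis set (non-motoneuron, cord mode) are retained
    extra = [c for c in recording.channels if c not in set(recording.analysis_channels())]
    return recording.subset(keep + extra)


def detect_episodes(
    bursts: list[Burst],
    gap_threshold: float = 10.0,
    duration_range: tuple[float, float] = (20.0, 100.0),
) -> list[Episode]:
    """Group bursts separated by short gaps into episodes.

    Maximal runs of bursts whose successive gaps (next start minus previous
    end) are at most ``gap_threshold`` form a group; groups whose span
    (first burst onset to last burst end) lies within ``duration_range``
    are reported as episodes.
    """
    lo, hi = duration_range
    if not bursts:
        return []
    groups: list[list[Burst]] = [[bursts[0]]]
    for b in bursts[1:]:
        if b.start - groups[-1][-1].end <= gap_threshold:
            groups[-1].append(b)
        else:
            groups.append([b])
    return [
        Episode(g)
        for g in groups
        if lo <= (g[-1].end - g[0].start) <= hi
    ]


# ---------------------------------------------------------------------------
# convenience drivers
# ---------------------------------------------------------------------------


@dataclass
class DetectionResult:
    """Everything produced by a full detection pass."""

    recording: SpikeRecording
    isi: ISIDistribution
    bursts: list[Burst]
    episodes: list[Episode]


def detect_network_bursts(
    recording: SpikeRecording, params: DetectionParams
) -> tuple[ISIDistribution, list[Burst]]:
    """Pool, estimate the threshold, detect windows and apply network filters."""
    pooled = pool_spikes(recording)
    isi = estimate_threshold(pooled, params)
    candidates = detect_bursts(pooled, isi.threshold, params.n_spikes)
    bursts = filter_network_bursts(candidates, recording, params)
    return isi, bursts


def analyze_recording(
    recording: SpikeRecording,
    params: DetectionParams,
    exclude: bool = True,
    gap_threshold: float = 10.0,
    episode_duration_range: tuple[float, float] = (20.0, 100.0),
) -> DetectionResult:
    """Full detection pipeline with one channel-exclusion pass.

    Detection runs once on all analysis channels; channels failing the
    participation or constant-activity rules are removed and detection is
    re-run once on the retained channels.  In cord mode, episodes are then
    assembled from the bursts.
    """
    isi, bursts = detect_network_bursts(recording, params)
    used = recording
    if exclude and bursts:
        retained = exclude_channels(recording, bursts, params)
        if set(retained.channels) != set(recording.channels):
            used = retained
            isi, bursts = detect_network_bursts(used, params)
    episodes = (
        detect_episodes(bursts, gap_threshold, episode_duration_range)
        if used.mode == "cord"
        else []
    )
    return DetectionResult(used, isi, bursts, episodes)
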