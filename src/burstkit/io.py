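"""Readers and writers for the package's delimited text formats.

Spike tables are CSV with a header and two required columns
``channel,time_s`` (times in seconds as decimal text), plus an optional
``is_motoneuron`` (0/1) column for cord recordings.  Burst/episode tables
carry ``kind,start_s,end_s,duration_s,n_spikes,n_channels``.  Configuration
files are YAML key-value documents.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import yaml

from .detection import Burst, DetectionParams, Episode, SpikeRecording
from .metrics import BinnedMetrics, NormalizedSeries
from .synthetic import SyntheticConfig

__all__ = [
    "read_spike_table",
    "write_spike_table",
    "write_intervals",
    "read_intervals",
    "write_metrics",
    "read_metrics",
    "load_config",
    "detection_params_from",
    "synthetic_config_from",
]


def read_spike_table(path, duration: float | None = None, mode: str | None = None) -> SpikeRecording:
    """Read a ``channel,time_s`` spike table into a :class:`SpikeRecording`.

    Within-channel times are sorted (with a warning) if needed; exact
    duplicate timestamps within a channel are dropped with a warning.
    Malformed time values are reported with their file line numbers.
    The recording duration is inferred as the maximum time unless given.
    """
    df = pd.read_csv(path, dtype={"channel": str})
    required = {"channel", "time_s"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = df.index[times.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed time_s values at lines {lines}")
    df = df.assign(time_s=times)
    motoneurons: set[str] = set()
    if "is_motoneuron" in df.columns:
        flagged = df.loc[df["is_motoneuron"].astype(int) == 1, "channel"]
        motoneurons = set(flagged.astype(str))
        if mode is None and motoneurons:
            mode = "cord"
    spikes: dict[str, np.ndarray] = {}
    for ch, grp in df.groupby("channel", sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            warnings.warn(f"channel {ch}: spike times out of order; sorted", stacklevel=2)
            t = np.sort(t)
        if np.any(np.diff(t) == 0):
            warnings.warn(f"channel {ch}: duplicate timestamps dropped", stacklevel=2)
            t = np.unique(t)
        spikes[str(ch)] = t
    if duration is None:
        duration = float(max((t[-1] for t in spikes.values() if t.size), default=1.0))
        duration = max(duration, np.finfo(float).tiny)
    return SpikeRecording(
        spikes=spikes,
        duration=duration,
        mode=mode or "culture",
        motoneuron_channels=frozenset(motoneurons),
    )


def write_spike_table(recording: SpikeRecording, path) -> None:
    rows = []
    for ch, t in recording.spikes.items():
        is_mn = int(ch in recording.motoneuron_channels)
        for v in t:
            rows.append((ch, v, is_mn))
    df = pd.DataFrame(rows, columns=["channel", "time_s", "is_motoneuron"])
    df = df.sort_values(["time_s", "channel"], kind="stable")
    df.to_csv(path, index=False, float_format="%.9f")


def write_intervals(path, bursts: list[Burst], episodes: list[Episode] | None = None) -> None:
    rows = [
        ("burst", b.start, b.end, b.duration, b.n_spikes, b.n_channels) for b in bursts
    ]
    for e in episodes or []:
        n_channels = len(set().union(*[set(c for c, v in b.spikes_per_channel.items() if v) for b in e.bursts]))
        rows.append(("episode", e.start, e.end, e.duration, e.n_spikes, n_channels))
    pd.DataFrame(
        rows, columns=["kind", "start_s", "end_s", "duration_s", "n_spikes", "n_channels"]
    ).to_csv(path, index=False, float_format="%.6f")


def read_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"kind", "start_s", "end_s"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    return df


def write_metrics(
    path,
    metrics: list[BinnedMetrics],
    normalized: dict[str, NormalizedSeries] | None = None,
    preparation: str = "prep0",
) -> None:
    """Long-format metric table: one row per (preparation, bin, feature)."""
    from .metrics import FEATURES

    rows = []
    for m in metrics:
        for f in FEATURES:
            norm = math.nan
            if normalized and f in normalized:
                norm = normalized[f].value(m.bin.label)
            rows.append((preparation, m.bin.label, m.bin.start, m.bin.end, f, m.value(f), norm))
    pd.DataFrame(
        rows,
        columns=["preparation", "bin", "bin_start_s", "bin_end_s", "feature", "value", "normalized"],
    ).to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"preparation": str, "bin": str, "feature": str})


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def detection_params_from(cfg: dict, mode: str = "culture") -> DetectionParams:
    base = DetectionParams.cord if mode == "cord" else DetectionParams.culture
    allowed = set(DetectionParams.__dataclass_fields__)
    section = cfg.get("detection", cfg)
    kw = {k: v for k, v in section.items() if k in allowed}
    return base(**kw)


def synthetic_config_from(cfg: dict, mode: str = "culture") -> SyntheticConfig:
    base = SyntheticConfig.cord if mode == "cord" else SyntheticConfig.culture
    allowed = set(SyntheticConfig.__dataclass_fields__) - {"mode"}
    section = cfg.get("simulate", cfg)
    kw = {}
    for k, v in section.items():
        if k not in allowed:
            continue
        if isinstance(v, list):
            v = tuple(v)
        kw[k] = v
    return base(**kw)
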