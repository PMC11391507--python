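"""Episode-associated fluorescence transients (ΔF/F) from ROI traces.

For a calcium-indicator region of interest (ROI), the fractional
fluorescence change of each frame is::

    ΔF/F(f) = (I(f) - B) / (B - A)

where B is the mean ROI intensity over the ``baseline_frames`` frames
immediately preceding the episode onset and A the mean intensity of a
non-labelled (autofluorescence) ROI over the same window.  The quantity is
dimensionless and invariant under a joint affine rescaling of the camera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RoiTraceSet", "dff", "transient_peak"]


@dataclass
class RoiTraceSet:
    """Per-frame intensities for a set of ROIs plus a background ROI."""

    frame_times: np.ndarray
    roi_intensities: dict[str, np.ndarray]
    auto_roi: np.ndarray
    episode_onset_frame: int

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.auto_roi = np.asarray(self.auto_roi, dtype=float)
        self.roi_intensities = {
            str(k): np.asarray(v, dtype=float) for k, v in self.roi_intensities.items()
        }
        n = self.frame_times.size
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.auto_roi.size != n or any(
            v.size != n for v in self.roi_intensities.values()
        ):
            raise ValueError("all traces must have the same length")
        if not 0 < self.episode_onset_frame <= n:
            raise ValueError("episode onset frame outside the recording")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


def dff(trace: RoiTraceSet, roi_id: str, baseline_frames: int = 30) -> np.ndarray:
    """ΔF/F trace of one ROI (dimensionless, one value per frame)."""
    if trace.episode_onset_frame < baseline_frames:
        raise ValueError("episode onset precedes the baseline window")
    i0 = trace.episode_onset_frame - baseline_frames
    i1 = trace.episode_onset_frame
    intensity = trace.roi_intensities[str(roi_id)]
    baseline = float(intensity[i0:i1].mean())
    auto = float(trace.auto_roi[i0:i1].mean())
    if baseline <= auto:
        raise ValueError("baseline not above autofluorescence")
    return (intensity - baseline) / (baseline - auto)


def transient_peak(dff_trace: np.ndarray, episode_window: tuple[int, int]) -> float:
    """Maximum ΔF/F within a half-open frame window [start, stop)."""
    i0, i1 = episode_window
    trace = np.asarray(dff_trace, dtype=float)
    if not 0 <= i0 < i1 <= trace.size:
        raise ValueError("episode window outside the trace")
    return float(trace[i0:i1].max())
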