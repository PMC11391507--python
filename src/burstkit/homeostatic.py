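"""Homeostatic index: percent recovery of a perturbed, normalized feature.

After a pharmacological perturbation at a known onset, a baseline-normalized
feature typically jumps to an extreme within the first hour and then drifts
back.  The homeostatic index expresses how much of the potential recovery
was realised::

    index = 100 * (extreme - treated_endpoint) / (extreme - control_endpoint)

where ``extreme`` is the most extreme normalized value in the first
post-onset hour, ``treated_endpoint`` the treated preparation's normalized
value at the final time point, and ``control_endpoint`` the untreated
control value there (typically near 1).  0% means no recovery, 100% a full
return to control; values above 100% overshoot past control, negative
values keep moving away from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import NormalizedSeries

__all__ = [
    "HomeostaticIndexResult",
    "extreme_first_hour",
    "homeostatic_index",
    "index_summary",
    "index_from_series",
]

FIRST_HOUR = 3600.0


@dataclass
class HomeostaticIndexResult:
    feature: str
    extreme_value: float
    treated_endpoint: float
    control_endpoint: float
    index_percent: float


def extreme_first_hour(series: NormalizedSeries, drug_onset: float) -> float:
    """Most extreme normalized value among bins starting within one hour of onset.

    "Extreme" is the largest deviation from 1 with the sign preserved, so
    both facilitation (values > 1) and suppression (values < 1) are handled
    symmetrically.
    """
    window = [
        float(v)
        for b, v in zip(series.bins, series.values)
        if drug_onset <= b.start < drug_onset + FIRST_HOUR
    ]
    if not window:
        raise ValueError("no bins start within the first post-onset hour")
    return max(window, key=lambda v: abs(v - 1.0))


def homeostatic_index(
    extreme: float, treated_endpoint: float, control_endpoint: float = 1.0
) -> float:
    """Percent recovery from the first-hour extreme toward the control endpoint."""
    if extreme == control_endpoint:
        raise ValueError("no perturbation relative to control; index undefined")
    return 100.0 * (extreme - treated_endpoint) / (extreme - control_endpoint)


def index_from_series(
    series: NormalizedSeries,
    drug_onset: float,
    endpoint_label: str,
    control_endpoint: float = 1.0,
) -> HomeostaticIndexResult:
    """Compute the index for one normalized feature trajectory."""
    extreme = extreme_first_hour(series, drug_onset)
    treated = series.value(endpoint_label)
    return HomeostaticIndexResult(
        feature=series.feature,
        extreme_value=extreme,
        treated_endpoint=treated,
        control_endpoint=control_endpoint,
        index_percent=homeostatic_index(extreme, treated, control_endpoint),
    )


def index_summary(indices) -> tuple[float, float]:
    """Mean and coefficient of variation (sd/mean) of per-preparation indices."""
    arr = np.asarray(list(indices), dtype=float)
    if arr.size < 2:
        raise ValueError("at least two indices required")
    mean = float(arr.mean())
    if mean == 0:
        return mean, math.nan
    return mean, float(arr.std(ddof=1) / mean)
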