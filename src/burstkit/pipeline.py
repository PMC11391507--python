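"""End-to-end pipeline: simulate/ingest -> detect -> metrics -> normalize ->
homeostatic index -> estimation, writing every intermediate as delimited text.

The pipeline is a demonstration driver over the library: it simulates (or
loads) a small cohort of treated and control preparations, runs detection
and per-bin metrics on each, normalizes trajectories to the predrug
baseline, computes each treated preparation's homeostatic index against the
mean control endpoint, and compares treated vs control normalized values at
the first post-drug bin with estimation statistics.  All randomness flows
from named per-stage seeds derived from the config; running twice with the
same config produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .detection import analyze_recording
from .estimation import estimate_difference
from .homeostatic import index_from_series
from .metrics import compute_metrics, make_cord_bins, make_culture_bins, normalize_to_baseline
from .synthetic import generate

log = logging.getLogger("burstkit")

__all__ = ["run_pipeline"]


def _bins_for(config, sim):
    if sim.mode == "cord":
        return make_cord_bins(sim.drug_onset, sim.total_duration)
    offsets = config.get("bin_offsets_h")
    if offsets is None:
        # every 900 s window that fits after onset
        n = int((sim.total_duration - sim.drug_onset) // 900)
        offsets = [k * 0.25 for k in range(n)]
    return make_culture_bins(sim.drug_onset, offsets, total_duration=sim.total_duration)


def run_pipeline(config: dict, outdir) -> dict[str, Path]:
    """Run the full analysis described by ``config``; return output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode", "culture")
    n_treated = int(config.get("n_treated", 2))
    n_control = int(config.get("n_control", 2))
    base_seed = int(config.get("seed", 0))
    feature = config.get("feature", "srwb_pooled")
    params = bio.detection_params_from(config, mode)
    outputs: dict[str, Path] = {}

    metric_frames = []
    endpoint: dict[str, list[float]] = {"treated": [], "control": []}
    first_post: dict[str, list[float]] = {"treated": [], "control": []}
    hindex_rows = []
    bins = None
    drug_onset = None

    for arm, count in (("treated", n_treated), ("control", n_control)):
        for i in range(count):
            seed = base_seed * 1000 + (0 if arm == "treated" else 500) + i
            sim = bio.synthetic_config_from(config, mode)
            if arm == "control":
                # untreated arm: null perturbation
                sim = type(sim)(**{**sim.__dict__, "seed": seed, "srwb_multiplier_peak": 1.0, "recruitment_boost": 0.0})
            else:
                sim = type(sim)(**{**sim.__dict__, "seed": seed})
            drug_onset = sim.drug_onset
            name = f"{arm}{i}"
            log.info("simulating %s (seed %d)", name, seed)
            recording, truth = generate(sim)
            spike_path = outdir / f"spikes_{name}.csv"
            bio.write_spike_table(recording, spike_path)
            result = analyze_recording(recording, params)
            bio.write_intervals(outdir / f"bursts_{name}.csv", result.bursts, result.episodes)
            bins = _bins_for(config, sim)
            metrics = compute_metrics(result.recording, result.bursts, bins, result.episodes)
            normalized = normalize_to_baseline(metrics, features=[feature])
            series = normalized[feature]
            bio.write_metrics(outdir / f"metrics_{name}.csv", metrics, normalized, preparation=name)
            metric_frames.append(bio.read_metrics(outdir / f"metrics_{name}.csv"))
            endpoint[arm].append(series.value(bins[-1].label))
            first_post[arm].append(series.value(bins[1].label))
            if arm == "treated":
                hindex_rows.append((name, series))

    metrics_path = outdir / "metrics.csv"
    pd.concat(metric_frames, ignore_index=True).to_csv(metrics_path, index=False)
    outputs["metrics"] = metrics_path

    control_endpoint = float(np.mean(endpoint["control"])) if endpoint["control"] else 1.0
    rows = []
    for name, series in hindex_rows:
        r = index_from_series(series, drug_onset, bins[-1].label, control_endpoint)
        rows.append((name, r.feature, r.extreme_value, r.treated_endpoint, r.control_endpoint, r.index_percent))
    hindex_path = outdir / "hindex.csv"
    pd.DataFrame(
        rows,
        columns=["preparation", "feature", "extreme", "treated_endpoint", "control_endpoint", "index_percent"],
    ).to_csv(hindex_path, index=False)
    outputs["hindex"] = hindex_path

    est_path = outdir / "estimate.csv"
    if len(first_post["treated"]) + len(first_post["control"]) >= 4:
        res = estimate_difference(
            first_post["treated"], first_post["control"], seed=base_seed
        )
        pd.DataFrame([res.__dict__]).to_csv(est_path, index=False)
        outputs["estimate"] = est_path
    return outputs
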