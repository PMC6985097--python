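"""End-to-end synthetic study drivers shared by the CLI and the examples.

A "study" mirrors the design the pipeline targets: four timepoints
(DIV 7/14/21/28), several fields per timepoint for imaging, and several
coverslips per timepoint x treatment for Ca2+ recordings.  The built-in
schedules move the generator parameters across DIV the way a maturing
astrocyte culture does (marker-positive fractions and co-expression climb,
the non-responder fraction falls, decay accelerates, rise slows) and model
antagonist treatment as amplitude attenuation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .config import RunConfig, substream_seed
from .imaging import colocalize, count_nuclei, quantify_marker, threshold_with_qc
from .io import read_micrograph, read_traces, write_micrograph, write_traces
from .kinetics import extract_features_batch, summarize_response_rates
from .simulate import ImageSimSpec, TraceSimSpec, generate_micrograph, generate_trace_set

__all__ = [
    "DIVS",
    "image_schedule",
    "trace_schedule",
    "simulate_study_images",
    "simulate_study_traces",
    "quantify_images",
    "analyze_traces",
    "features_to_dataframe",
]

DIVS = (7, 14, 21, 28)

# culture maturation schedules (per-DIV generator parameters)
_GFAP_FRACTION = {7: 0.35, 14: 0.53, 21: 0.65, 28: 0.74}
_ALDH_FRACTION = {7: 0.40, 14: 0.40, 21: 0.40, 28: 0.40}
_COEXPRESSION = {7: 0.17, 14: 0.30, 21: 0.40, 28: 0.49}
_DECAY_TAU = {7: 83.0, 14: 81.0, 21: 65.0, 28: 70.0}
_RISE_DURATION = {7: 4.7, 14: 5.3, 21: 6.6, 28: 7.6}  # RT_10-90 = 0.8 x this
_NONRESPONDER = {7: 0.20, 14: 0.15, 21: 0.10, 28: 0.05}
_ATTENUATION = {"control": 1.0, "suramin": 0.2}


def image_schedule(div: int) -> dict:
    """ImageSimSpec overrides for one timepoint."""
    return {
        "marker_positive_fractions": {
            "GFAP": _GFAP_FRACTION[div],
            "ALDH1L1": _ALDH_FRACTION[div],
        },
        "coexpression_pcc_target": _COEXPRESSION[div],
    }


def trace_schedule(div: int, treatment: str) -> dict:
    """TraceSimSpec overrides for one timepoint x treatment."""
    return {
        "decay_tau_s": _DECAY_TAU[div],
        "rise_duration_s": _RISE_DURATION[div],
        "nonresponder_fraction": _NONRESPONDER[div],
        "treatment_attenuation": _ATTENUATION[treatment],
    }


def simulate_study_images(cfg: RunConfig, outdir: str | Path) -> list[Path]:
    """Simulate ``cfg.n_images`` fields per DIV; TIFF + ground-truth CSV each."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for div in DIVS:
        for img_i in range(cfg.n_images):
            overrides = {**image_schedule(div), **cfg.image_sim}
            seed = substream_seed(cfg.seed, f"image/div{div}/{img_i}")
            spec = ImageSimSpec(**{**overrides, "seed": seed})
            micro, truth = generate_micrograph(spec)
            micro.metadata.update(div=div, treatment="control", replicate=img_i)
            p = outdir / f"div{div:02d}_img{img_i + 1}.tif"
            write_micrograph(micro, p)
            truth.cells.to_csv(
                p.with_suffix(".truth.csv"), index=False, float_format="%.10g"
            )
            paths.append(p)
    return paths


def simulate_study_traces(cfg: RunConfig, outdir: str | Path) -> list[Path]:
    """Simulate ``cfg.n_coverslips`` recordings per DIV x treatment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for div in DIVS:
        for treatment in ("control", "suramin"):
            for cs in range(cfg.n_coverslips):
                overrides = {**trace_schedule(div, treatment), **cfg.trace_sim}
                seed = substream_seed(cfg.seed, f"trace/div{div}/{treatment}/{cs}")
                spec = TraceSimSpec(**{**overrides, "seed": seed})
                traces, truth = generate_trace_set(
                    spec,
                    group={
                        "div": str(div),
                        "treatment": treatment,
                        "coverslip": str(cs),
                    },
                )
                p = outdir / f"div{div:02d}_{treatment}_cs{cs + 1}.csv"
                write_traces(traces, p)
                truth.traces.to_csv(
                    p.with_suffix(".truth.csv"), index=False, float_format="%.10g"
                )
                paths.append(p)
    return paths


def quantify_images(
    paths: list[str | Path], cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Run segmentation + marker quantification (+ co-localization) per image.

    Returns (quantifications, colocalizations, segmentation log).
    """
    q_rows, c_rows, log = [], [], []
    for path in paths:
        micro = read_micrograph(path, pixel_size_um=cfg.pixel_size_um)
        meta = micro.metadata
        n_nuclei, centroids = count_nuclei(
            micro.channels["nuclei"], **cfg.imaging.get("nuclei", {})
        )
        entry = {"image": str(path), "n_nuclei": n_nuclei, "channels": {}}
        seg_masks = {}
        for marker in micro.marker_names:
            seg = threshold_with_qc(
                micro.channels[marker], **cfg.imaging.get("threshold", {})
            )
            seg_masks[marker] = seg.mask
            quant = quantify_marker(
                seg, centroids, micro.pixel_size_um, marker=marker
            )
            q_rows.append(
                {
                    "image": str(path),
                    "marker": marker,
                    "div": meta.get("div", ""),
                    "treatment": meta.get("treatment", ""),
                    "replicate": meta.get("replicate", ""),
                    "n_nuclei": quant.n_nuclei,
                    "n_positive_cells": quant.n_positive_cells,
                    "cells_per_mm2": quant.cells_per_mm2,
                    "percent_positive_cells": quant.percent_positive_cells,
                    "percent_area": quant.percent_area,
                    "percent_area_per_avg_cell": quant.percent_area_per_avg_cell,
                }
            )
            entry["channels"][marker] = {
                "threshold": seg.threshold,
                "qc_pcc": seg.qc_pcc,
                "qc_passed": seg.qc_passed,
                "fallback_applied": seg.fallback_applied,
                "method": seg.method,
            }
        if len(micro.marker_names) == 2:
            m1, m2 = micro.marker_names
            res = colocalize(
                micro.channels[m1],
                micro.channels[m2],
                policy=cfg.coloc_policy,
                masks=(seg_masks[m1], seg_masks[m2]),
                names=(m1, m2),
            )
            c_rows.append(
                {
                    "image": str(path),
                    "channel_a": m1,
                    "channel_b": m2,
                    "div": meta.get("div", ""),
                    "treatment": meta.get("treatment", ""),
                    "pcc": res.pcc,
                    "n_pixels": res.n_pixels,
                    "mask_policy": res.mask_policy,
                }
            )
        log.append(entry)
    return pd.DataFrame(q_rows), pd.DataFrame(c_rows), log


def features_to_dataframe(features) -> pd.DataFrame:
    """Flatten TransientFeatures (+ their group metadata) into a tidy table."""
    rows = []
    for ft in features:
        row = {
            "roi_id": ft.roi_id,
            **{k: v for k, v in ft.metadata.items()},
            "responder": ft.responder,
            "latency_s": ft.latency_s,
            "rise_time_s": ft.rise_time_s,
            "peak_amplitude": ft.peak_amplitude,
            "auc": ft.auc,
            "decay_tau_s": ft.decay_tau_s,
            "fit_error": ft.fit_error,
            "t_end_s": ft.t_end_s,
            "phase": ft.phase,
            "error": ft.error,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_traces(
    paths: list[str | Path], cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract kinetic features for every ROI in the given trace CSVs."""
    features = []
    for path in paths:
        traces = read_traces(path)
        features.extend(extract_features_batch(traces, **cfg.kinetics))
    summary = summarize_response_rates(features, by=("div", "treatment"))
    return features_to_dataframe(features), summary


def write_provenance(path: str | Path, cfg: RunConfig, **extra) -> Path:
    """Persist the effective config and counts of one run stage."""
    from .report import config_hash

    path = Path(path)
    record = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg.to_dict()),
        "seed": cfg.seed,
        **extra,
    }
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
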