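"""Tidy result tables and the machine-readable run summary.

Aggregates per-image marker quantifications, co-localization results and
per-ROI kinetic features into mean +/- SEM tables keyed by
(measure, timepoint, treatment), attaches the group comparisons with their
significance stars, and persists everything as sorted CSV plus a JSON
summary and a run-metadata record.  Re-running with the same inputs, config
and seed reproduces the CSVs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .stats import compare_groups, mean_sem

__all__ = ["build_report", "config_hash"]

_FLOAT_FMT = "%.10g"


def config_hash(config: Mapping) -> str:
    """Deterministic sha256 of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _summarize(
    df: pd.DataFrame, group_cols: list[str], value_cols: list[str]
) -> pd.DataFrame:
    rows = []
    for key, sub in df.groupby(group_cols, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_cols, key))
        for col in value_cols:
            vals = sub[col].dropna().to_numpy()
            if vals.size:
                mean, sem, n = mean_sem(vals)
                row[f"{col}_mean"] = mean
                row[f"{col}_sem"] = np.nan if sem is None else sem
                row[f"{col}_n"] = n
            else:
                row[f"{col}_mean"] = np.nan
                row[f"{col}_sem"] = np.nan
                row[f"{col}_n"] = 0
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(group_cols, kind="stable").reset_index(drop=True)


def _comparisons(
    df: pd.DataFrame, group_col: str, value_cols: list[str], split_cols: list[str]
) -> pd.DataFrame:
    """Compare ``group_col`` levels for each measure, within each split."""
    rows = []
    splits = (
        df.groupby(split_cols, dropna=False) if split_cols else [((), df)]
    )
    for key, sub in splits:
        key = key if isinstance(key, tuple) else (key,)
        for col in value_cols:
            groups = {
                str(g): s[col].dropna().to_list()
                for g, s in sub.groupby(group_col, dropna=False)
            }
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            res = compare_groups(groups)
            base = dict(zip(split_cols, key))
            base.update(measure=col, test=res.test_name)
            for pw in res.pairwise:
                rows.append(
                    {
                        **base,
                        "group_a": pw["group_a"],
                        "group_b": pw["group_b"],
                        "p_raw": pw["p_raw"],
                        "p_adjusted": pw["p_adjusted"],
                        "stars": pw["stars"],
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(out.columns.to_list(), kind="stable").reset_index(
            drop=True
        )
    return out


def build_report(
    outdir: str | Path,
    *,
    quantifications: Optional[pd.DataFrame] = None,
    colocalizations: Optional[pd.DataFrame] = None,
    features: Optional[pd.DataFrame] = None,
    kinetics_summary: Optional[pd.DataFrame] = None,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> dict:
    """Write the report bundle; absent sections are simply omitted.

    Inputs are tidy per-observation tables: ``quantifications`` one row per
    image x marker (columns ``marker, div, treatment`` plus measures),
    ``colocalizations`` one row per image pair, ``features`` one row per ROI.
    Returns a manifest of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    summary_json: dict = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written[name] = str(p)

    if quantifications is not None and not quantifications.empty:
        measures = [
            c
            for c in (
                "n_positive_cells",
                "cells_per_mm2",
                "percent_positive_cells",
                "percent_area",
                "percent_area_per_avg_cell",
            )
            if c in quantifications.columns
        ]
        keys = [c for c in ("marker", "div", "treatment") if c in quantifications.columns]
        summ = _summarize(quantifications, keys, measures)
        _write(summ, "marker_summary.csv")
        if "div" in keys:
            comp = _comparisons(
                quantifications, "div", measures,
                [c for c in keys if c != "div"],
            )
            if not comp.empty:
                _write(comp, "marker_comparisons.csv")
        summary_json["markers"] = json.loads(summ.to_json(orient="records"))

    if colocalizations is not None and not colocalizations.empty:
        keys = [c for c in ("channel_a", "channel_b", "div", "treatment")
                if c in colocalizations.columns]
        summ = _summarize(colocalizations, keys, ["pcc"])
        _write(summ, "coloc_summary.csv")
        summary_json["colocalization"] = json.loads(summ.to_json(orient="records"))

    if features is not None and not features.empty:
        _write(
            features.sort_values(features.columns.to_list()[:2], kind="stable"),
            "kinetics_features.csv",
        )
        measures = [
            c
            for c in ("latency_s", "rise_time_s", "peak_amplitude", "auc", "decay_tau_s")
            if c in features.columns
        ]
        keys = [c for c in ("div", "treatment") if c in features.columns]
        if keys:
            comp = _comparisons(
                features.dropna(subset=measures, how="all"),
                keys[0], measures, keys[1:],
            )
            if not comp.empty:
                _write(comp, "kinetics_comparisons.csv")

    if kinetics_summary is not None and not kinetics_summary.empty:
        _write(kinetics_summary, "kinetics_summary.csv")
        summary_json["kinetics"] = json.loads(kinetics_summary.to_json(orient="records"))

    cfg = dict(config or {})
    run_meta = {
        "astroquant_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "tables": sorted(written),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary_json, indent=2, sort_keys=True)
    )
    (outdir / "run_metadata.json").write_text(
        json.dumps(run_meta, indent=2, sort_keys=True)
    )
    written["summary.json"] = str(outdir / "summary.json")
    written["run_metadata.json"] = str(outdir / "run_metadata.json")
    return written
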