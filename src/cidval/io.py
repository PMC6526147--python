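"""Delimited/JSON readers and writers for targets, areas and reports.

Conventions: channel indices are 0-based (M0 = unlabeled); user-facing
tables carry percentages, internal computation uses fractions; every report
records a provenance block (isotope-table version, seed, config hash) so a
result can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import __version__
from .chem import default_table
from .screen import BlankResult, InterferenceHit, TargetEntry, target_from_row
from .validate import MeasurementSet, ValidationReport

__all__ = [
    "SchemaError",
    "read_targets",
    "read_areas",
    "write_areas",
    "write_reports_csv",
    "write_reports_json",
    "write_hits",
    "write_blanks",
    "provenance",
]

TARGET_COLUMNS = ["name", "formula", "rt_min", "polarity"]
AREA_COLUMNS = ["metabolite", "channel_index", "replicate", "area"]


class SchemaError(ValueError):
    """Input table violates the expected schema; message names the row."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_targets(path: str | Path) -> list[TargetEntry]:
    """Read a target panel: name, formula, rt_min, polarity[, adduct]."""
    df = pd.read_csv(path)
    _require_columns(df, TARGET_COLUMNS, path)
    targets = []
    for i, row in df.iterrows():
        try:
            targets.append(
                target_from_row(
                    str(row["name"]),
                    str(row["formula"]),
                    float(row["rt_min"]),
                    str(row["polarity"]),
                    str(row["adduct"]) if "adduct" in df.columns and pd.notna(row["adduct"]) else "",
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return targets


def read_areas(path: str | Path) -> dict[str, MeasurementSet]:
    """Read long-format replicate areas: metabolite, channel_index, replicate, area."""
    df = pd.read_csv(path)
    _require_columns(df, AREA_COLUMNS, path)
    bad = df.index[pd.to_numeric(df["area"], errors="coerce").isna() | (df["area"] < 0)]
    if len(bad):
        raise SchemaError(f"{path}: row {bad[0] + 2}: negative or non-numeric area")
    out: dict[str, MeasurementSet] = {}
    for met, grp in df.groupby("metabolite", sort=False):
        wide = grp.pivot_table(
            index="replicate", columns="channel_index", values="area", aggfunc="sum"
        ).sort_index(axis=1)
        if wide.isna().any().any():
            rep = wide.index[wide.isna().any(axis=1)][0]
            raise SchemaError(
                f"{path}: metabolite {met!r} replicate {rep!r} is missing channels"
            )
        channels = tuple(f"M{int(c)}" for c in wide.columns)
        if list(wide.columns) != list(range(len(channels))):
            raise SchemaError(
                f"{path}: metabolite {met!r}: channel indices must be 0..n contiguous"
            )
        out[str(met)] = MeasurementSet(
            metabolite=str(met), channels=channels, areas=wide.to_numpy()
        )
    return out


def write_areas(measurements: dict[str, MeasurementSet], path: str | Path) -> None:
    rows = []
    for met, ms in measurements.items():
        for r in range(ms.n_replicates):
            for k in range(len(ms.channels)):
                rows.append((met, k, r, ms.areas[r, k]))
    pd.DataFrame(rows, columns=AREA_COLUMNS).to_csv(path, index=False)


def provenance(config: dict[str, Any] | None = None, seed: int | None = None) -> dict[str, Any]:
    """Provenance block stamped into every report."""
    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "cidval_version": __version__,
        "isotope_table_version": default_table().version,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest()[:16],
    }


def write_reports_csv(
    reports: Iterable[ValidationReport], path: str | Path, prov: dict | None = None
) -> None:
    """Tabular report, percentages rounded to 3 decimals; provenance in header comments."""
    frames = [r.to_frame() for r in reports]
    df = pd.concat(frames, ignore_index=True)
    for col in ("cid_pred", "pred_error", "cid_meas", "trueness_bias", "precision"):
        df[col] = df[col].round(3)
    with open(path, "w") as fh:
        for key, val in (prov or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def write_reports_json(
    reports: Iterable[ValidationReport], path: str | Path, prov: dict | None = None
) -> None:
    """Full-precision JSON report with provenance block."""
    payload = {
        "provenance": prov or provenance(),
        "reports": [
            {
                "metabolite": r.metabolite,
                "contamination_suspect": r.contamination_suspect,
                "interference_suspect": r.interference_suspect,
                "notes": list(r.notes),
                "channels": r.table.to_dict(orient="list"),
            }
            for r in reports
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_hits(hits: list[InterferenceHit], path: str | Path, prov: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "affected": h.affected,
                "affected_channel": h.affected_channel,
                "interferer": h.interferer,
                "interferer_channel": h.interferer_channel,
                "ppm": round(h.ppm, 3),
                "delta_rt_min": round(h.delta_rt, 3),
            }
            for h in hits
        ],
        columns=[
            "affected",
            "affected_channel",
            "interferer",
            "interferer_channel",
            "ppm",
            "delta_rt_min",
        ],
    )
    with open(path, "w") as fh:
        for key, val in (prov or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def write_blanks(blanks: list[BlankResult], path: str | Path, prov: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "name": b.name,
                "blank_ratio_percent": None if b.ratio_percent is None else round(b.ratio_percent, 3),
                "classification": b.classification,
            }
            for b in blanks
        ],
        columns=["name", "blank_ratio_percent", "classification"],
    )
    with open(path, "w") as fh:
        for key, val in (prov or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)
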