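"""On-disk formats: recording CSVs, session manifests, score and feature tables.

Formats are deliberately minimal and text-based:

* recording CSV — columns ``time_s, acc_x, acc_y, acc_z``, header row,
  UTF-8, '.' decimal separator;
* session manifest — one JSON file per subject with the sensor table,
  the condition cue table and the sampling rate;
* ``scores.csv`` — subject_id, condition, av_in_per_s, pl_in;
* feature table CSV — 4 metadata columns, the 42 feature columns in
  canonical order, and the ground-truth AV;
* ``results.json`` — cross-validation metrics, per-fold selections and
  winning hyperparameters.

Readers validate strictly and name the offending row or field.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .types import (
    CENTER_PLACEMENTS,
    CONDITIONS,
    HANDEDNESS,
    PLACEMENTS,
    SIDES,
    CueInterval,
    SensorRecording,
    SessionManifest,
    SubjectRecord,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "manifest_from_record",
    "write_cohort",
    "read_scores",
    "write_feature_table",
    "read_feature_table",
    "write_results",
]

RECORDING_COLUMNS = ("time_s", "acc_x", "acc_y", "acc_z")


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    """Write one recording as a ``time_s, acc_x, acc_y, acc_z`` CSV."""
    df = pd.DataFrame(
        {"time_s": rec.t, "acc_x": rec.x, "acc_y": rec.y, "acc_z": rec.z}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_recording(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a recording CSV → (time, 3×N axes array, inferred fs).

    Validates column presence, finiteness of every sample (naming the first
    offending row), strictly increasing time and a constant sampling step
    within 1e-6 s.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap for a stable error type
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    values = df[list(RECORDING_COLUMNS)].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        col = RECORDING_COLUMNS[int(np.argwhere(bad)[0, 1])]
        raise FormatError(
            f"{path}: non-finite value in column {col!r} at data row {row}"
        )
    t = values[:, 0]
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0))
        raise FormatError(f"{path}: non-monotone time at data row {row + 1}")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > 1e-6):
        row = int(np.argmax(np.abs(dt - step) > 1e-6))
        raise FormatError(
            f"{path}: non-uniform sampling step at data row {row + 1}"
        )
    return t, values[:, 1:].T.copy(), 1.0 / step


def _validate_manifest(m: SessionManifest) -> None:
    if m.handedness not in HANDEDNESS:
        raise SchemaError(f"unknown handedness {m.handedness!r}")
    if m.fs <= 0:
        raise SchemaError("fs must be positive")
    seen: list[str] = []
    for cue in m.cues:
        if cue.condition not in CONDITIONS:
            raise SchemaError(f"unknown condition {cue.condition!r}")
        if cue.condition in seen:
            raise SchemaError(f"duplicate condition {cue.condition!r} in cues")
        seen.append(cue.condition)
        if not (cue.stop_s > cue.start_s):
            raise SchemaError(
                f"cue {cue.condition}: stop_s must exceed start_s"
            )
    intervals = sorted((c.start_s, c.stop_s, c.condition) for c in m.cues)
    for (s0, e0, c0), (s1, e1, c1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise SchemaError(f"cues {c0} and {c1} overlap")
    for placement, side, _file in m.sensors:
        if placement not in PLACEMENTS:
            raise SchemaError(f"unknown placement {placement!r}")
        if side not in SIDES:
            raise SchemaError(f"unknown side {side!r}")
        if placement in CENTER_PLACEMENTS and side != "center":
            raise SchemaError(f"{placement} sensor must have side 'center'")
        if placement not in CENTER_PLACEMENTS and side == "center":
            raise SchemaError(f"{placement} sensor cannot have side 'center'")


def write_manifest(m: SessionManifest, path: str | Path) -> None:
    _validate_manifest(m)
    payload = {
        "subject_id": m.subject_id,
        "handedness": m.handedness,
        "fs": m.fs,
        "sensors": [
            {"placement": p, "side": s, "file": f} for p, s, f in m.sensors
        ],
        "cues": [
            {
                "condition": c.condition,
                "start_s": c.start_s,
                "stop_s": c.stop_s,
            }
            for c in m.cues
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_manifest(path: str | Path) -> SessionManifest:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    try:
        manifest = SessionManifest(
            subject_id=str(payload["subject_id"]),
            handedness=str(payload["handedness"]),
            fs=float(payload["fs"]),
            sensors=[
                (str(s["placement"]), str(s["side"]), str(s["file"]))
                for s in payload["sensors"]
            ],
            cues=[
                CueInterval(
                    condition=str(c["condition"]),
                    start_s=float(c["start_s"]),
                    stop_s=float(c["stop_s"]),
                )
                for c in payload["cues"]
            ],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed manifest ({exc})") from exc
    _validate_manifest(manifest)
    return manifest


def manifest_from_record(
    record: SubjectRecord, file_pattern: str = "{subject}_{placement}_{side}.csv"
) -> SessionManifest:
    """Build the session manifest describing one simulated subject."""
    sensors = [
        (
            placement,
            side,
            file_pattern.format(
                subject=record.subject_id, placement=placement, side=side
            ),
        )
        for placement, side in record.sessions
    ]
    fs = next(iter(record.sessions.values())).fs
    m = SessionManifest(
        subject_id=record.subject_id,
        handedness=record.handedness,
        fs=fs,
        sensors=sensors,
        cues=list(record.cues),
    )
    _validate_manifest(m)
    return m


def write_cohort(records: list[SubjectRecord], out_dir: str | Path) -> None:
    """Serialize a simulated cohort: recording CSVs, manifests, scores.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    score_rows = []
    for record in records:
        manifest = manifest_from_record(record)
        for (placement, side, fname), key in zip(
            manifest.sensors, record.sessions
        ):
            write_recording(record.sessions[key], out_dir / fname)
        write_manifest(manifest, out_dir / f"{record.subject_id}_manifest.json")
        for cond in CONDITIONS:
            score = record.scores[cond]
            score_rows.append(
                {
                    "subject_id": record.subject_id,
                    "condition": cond,
                    "av_in_per_s": score.av,
                    "pl_in": score.pl,
                }
            )
    pd.DataFrame(score_rows).to_csv(
        out_dir / "scores.csv", index=False, float_format="%.12g"
    )


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "condition", "av_in_per_s", "pl_in"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: scores.csv missing columns {sorted(missing)}")
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-recording feature table, enforcing the full feature set."""
    from .features import FEATURE_NAMES

    meta = ["subject_id", "condition", "placement", "role"]
    missing = [c for c in meta + list(FEATURE_NAMES) + ["av_in_per_s"]
               if c not in table.columns]
    if missing and not table.empty:
        raise FormatError(f"feature table missing columns {missing}")
    cols = meta + list(FEATURE_NAMES) + ["av_in_per_s"]
    out = table[cols] if not table.empty else pd.DataFrame(columns=cols)
    for col in FEATURE_NAMES:
        if not table.empty and not np.isfinite(out[col].to_numpy(float)).all():
            raise FormatError(f"feature column {col!r} contains non-finite values")
    out.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    from .features import FEATURE_NAMES

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [
        c
        for c in ("subject_id", "condition", "placement", "role", "av_in_per_s")
        if c not in df.columns
    ]
    missing += [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_results(results: dict, path: str | Path) -> None:
    """Write an evaluation report (metrics, selections, hyperparameters) as JSON."""
    Path(path).write_text(
        json.dumps(_jsonable(results), indent=2), encoding="utf-8"
    )
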