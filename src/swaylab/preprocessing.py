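"""Raw session streams → per-condition, trimmed, harmonized segments.

The stages mirror the study protocol: vocal-cue timestamps cut one session
stream into the four condition blocks (half-open intervals, so boundary
samples are never double-counted); 0.5 s is trimmed from each edge to drop
platform-transition artifacts; device axes X/Y/Z are relabelled to body
axes ML/AP/VT (the upper arm swaps its horizontal axes); and left/right
sensor sides become dominant / non-dominant via the subject's handedness.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError, SegmentationError
from .types import (
    BILATERAL_PLACEMENTS,
    CENTER_PLACEMENTS,
    HANDEDNESS,
    IMURecording,
    SensorRecording,
    SessionManifest,
)

__all__ = [
    "segment_by_cues",
    "trim_edges",
    "assign_dominance",
    "harmonize_axes",
]


def segment_by_cues(
    raw: SensorRecording, manifest: SessionManifest
) -> dict[str, SensorRecording]:
    """Cut a session stream into per-condition segments.

    Each cue [start_s, stop_s) selects exactly the samples with
    start_s <= t < stop_s; sample values are copied, never altered.
    """
    t = raw.t
    out: dict[str, SensorRecording] = {}
    for cue in manifest.cues:
        if cue.start_s < t[0] or cue.stop_s > t[-1] + 1.0 / raw.fs:
            raise SegmentationError(
                f"cue {cue.condition} [{cue.start_s}, {cue.stop_s}) lies "
                f"outside the recording span [{t[0]}, {t[-1]}]"
            )
        mask = (t >= cue.start_s) & (t < cue.stop_s)
        if not mask.any():
            raise SegmentationError(
                f"cue {cue.condition} selects no samples"
            )
        out[cue.condition] = SensorRecording(
            subject_id=raw.subject_id,
            placement=raw.placement,
            side=raw.side,
            fs=raw.fs,
            t=t[mask].copy(),
            x=raw.x[mask].copy(),
            y=raw.y[mask].copy(),
            z=raw.z[mask].copy(),
            condition=cue.condition,
        )
    return out


def trim_edges(segment: SensorRecording, trim_s: float = 0.5) -> SensorRecording:
    """Drop round(trim_s * fs) samples from each end of a segment."""
    if trim_s < 0:
        raise InvalidParameterError("trim_s must be >= 0")
    k = int(round(trim_s * segment.fs))
    if k == 0:
        return segment
    if segment.n_samples <= 2 * k:
        raise InvalidParameterError(
            f"segment of {segment.n_samples} samples too short to trim "
            f"{k} samples from each end"
        )
    sl = slice(k, segment.n_samples - k)
    return SensorRecording(
        subject_id=segment.subject_id,
        placement=segment.placement,
        side=segment.side,
        fs=segment.fs,
        t=segment.t[sl].copy(),
        x=segment.x[sl].copy(),
        y=segment.y[sl].copy(),
        z=segment.z[sl].copy(),
        condition=segment.condition,
    )


def assign_dominance(placement: str, side: str, handedness: str) -> str:
    """Relabel a sensor side as dominant / nondominant / center.

    Midline placements (lumbar, sternum) are 'center'; for bilateral
    placements the side matching the subject's handedness is 'dominant'.
    """
    if handedness not in HANDEDNESS:
        raise InvalidParameterError(f"unknown handedness {handedness!r}")
    if placement in CENTER_PLACEMENTS:
        if side != "center":
            raise InvalidParameterError(
                f"{placement} sensors must have side 'center', got {side!r}"
            )
        return "center"
    if placement in BILATERAL_PLACEMENTS:
        if side not in ("left", "right"):
            raise InvalidParameterError(
                f"{placement} sensors must be left or right, got {side!r}"
            )
        return "dominant" if side == handedness else "nondominant"
    raise InvalidParameterError(f"unknown placement {placement!r}")


def harmonize_axes(
    segment: SensorRecording, role: str | None = None
) -> IMURecording:
    """Relabel device axes X/Y/Z as body axes ML/AP/VT.

    Non-arm placements record ML on X and AP on Y; the upper-arm mounting
    swaps the horizontal axes (AP on X, ML on Y). Z is vertical everywhere.
    """
    if segment.condition is None:
        raise InvalidParameterError("segment has no condition label")
    if segment.placement == "arm":
        ml, ap = segment.y, segment.x
    else:
        ml, ap = segment.x, segment.y
    return IMURecording(
        subject_id=segment.subject_id,
        placement=segment.placement,
        role=role if role is not None else segment.side,
        condition=segment.condition,
        fs=segment.fs,
        ml=np.asarray(ml, dtype=float).copy(),
        ap=np.asarray(ap, dtype=float).copy(),
        vt=np.asarray(segment.z, dtype=float).copy(),
    )
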