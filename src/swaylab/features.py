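"""Tri-axial accelerometer feature extraction.

Thirteen per-axis features on each of the three body axes (ML, AP, VT) plus
three zero-lag cross-axis correlations give 42 features per recording, in a
fixed deterministic order. Features are computed on the full trimmed
segment — no windowing — and degenerate inputs (constant or all-zero
signals) map to finite guard values of 0 so downstream design matrices are
always finite.

Per-axis features and the conventions chosen for them:

* ``sd`` — sample standard deviation (n−1 denominator).
* ``skewness`` — standardized third central moment; ``kurtosis`` — Fisher
  excess (Gaussian → 0).
* ``sparsity`` — Hoyer sparsity (√N − L1/L2) / (√N − 1): 0 for
  constant-magnitude vectors, 1 for one-hot vectors.
* ``shannon_entropy`` — histogram entropy in bits over 16 equal-width bins
  spanning [min, max]; affine-invariant because the bins track the range.
* ``sample_entropy`` — SampEn(m=2, r=0.2·sd) with Chebyshev distance,
  self-matches excluded, both template lengths drawn from the same N−m
  start positions; degenerate match counts are capped at ln(N−m).
* ``spectral_entropy``, ``main_freq``, ``main_freq_power``,
  ``secondary_freq``, ``secondary_freq_power`` — from a one-sided
  rectangular-window periodogram with the DC bin excluded; the secondary
  peak skips bins adjacent to the main one so leakage shoulders are not
  reported as a second rhythm.
* ``difference_sum`` — total variation Σ|x[i+1] − x[i]|.
* ``average_jerk`` — mean |x[i+1] − x[i]| · fs, a first-difference reading
  of movement smoothness.

All of these follow the most standard reading of the feature names; every
threshold (bins, m, r fraction) is an overridable keyword.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import InvalidParameterError
from .preprocessing import assign_dominance, harmonize_axes, segment_by_cues, trim_edges
from .types import AXES, IMURecording, SubjectRecord

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "PER_AXIS_FEATURES",
    "FEATURE_NAMES",
    "stat_features",
    "sparsity",
    "shannon_entropy",
    "sample_entropy",
    "spectral_features",
    "difference_sum",
    "average_jerk",
    "cross_correlation",
    "extract_features",
    "features_from_cohort",
]

PER_AXIS_FEATURES: tuple[str, ...] = (
    "sd",
    "skewness",
    "kurtosis",
    "sparsity",
    "shannon_entropy",
    "sample_entropy",
    "spectral_entropy",
    "main_freq_power",
    "secondary_freq_power",
    "main_freq",
    "secondary_freq",
    "difference_sum",
    "average_jerk",
)

XCORR_FEATURES: tuple[str, ...] = ("xcorr_MLAP", "xcorr_MLVT", "xcorr_APVT")

#: canonical 42-entry feature order: 13 per axis for ML, AP, VT, then xcorrs
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{axis}_{feat}" for axis in AXES for feat in PER_AXIS_FEATURES
) + XCORR_FEATURES


def stat_features(x: np.ndarray) -> tuple[float, float, float]:
    """(sample sd, skewness, Fisher excess kurtosis); constant input → zeros."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InvalidParameterError("stat_features needs >= 4 samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0, 0.0, 0.0
    skew = float(sp_stats.skew(x, bias=True))
    kurt = float(sp_stats.kurtosis(x, fisher=True, bias=True))
    return sd, skew, kurt


def sparsity(x: np.ndarray) -> float:
    """Hoyer sparsity (√N − L1/L2)/(√N − 1) of the signal values."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("sparsity needs >= 2 samples")
    l2 = float(np.linalg.norm(x))
    if l2 == 0.0:
        return 0.0
    n = x.size
    l1 = float(np.abs(x).sum())
    return (math.sqrt(n) - l1 / l2) / (math.sqrt(n) - 1.0)


def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Histogram Shannon entropy in bits over equal-width bins on [min, max]."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


if _HAVE_NUMBA:

    @njit(fastmath=False)
    def _sampen_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover
        n = x.shape[0]
        nt = n - m
        a = 0
        b = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    dk = abs(x[i + k] - x[j + k])
                    if dk > d:
                        d = dk
                if d <= r:
                    b += 1
                    dk = abs(x[i + m] - x[j + m])
                    if dk <= r:
                        a += 1
        return a, b

else:

    def _sampen_counts(x: np.ndarray, m: int, r: float):
        n = x.shape[0]
        nt = n - m
        tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
        tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
        a = 0
        b = 0
        for i in range(nt - 1):
            dm = np.abs(tm[i + 1 :] - tm[i]).max(axis=1)
            hit = dm <= r
            b += int(hit.sum())
            dm1 = np.abs(tm1[i + 1 :] - tm1[i]).max(axis=1)
            a += int((dm1 <= r).sum())
        return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy SampEn(m, r = r_frac · sd(x)) of a signal.

    −ln(A/B) where B counts unordered template pairs of length ``m`` within
    Chebyshev distance r (self-matches excluded) and A the same for length
    ``m``+1; both lengths use the same N−m template start positions. If
    either count is zero the conventional finite cap ln(N−m) is returned so
    feature vectors stay finite.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.size < m + 2:
        raise InvalidParameterError("sample_entropy needs >= m + 2 samples")
    r = r_frac * float(np.std(x, ddof=1))
    a, b = _sampen_counts(x, m, r)
    if a == 0 or b == 0:
        return math.log(x.size - m)
    return -math.log(a / b)


def spectral_features(
    x: np.ndarray, fs: float
) -> tuple[float, float, float, float, float]:
    """(spectral_entropy, main_freq, main_power, secondary_freq, secondary_power).

    One-sided rectangular-window periodogram, DC bin excluded. Power values
    are normalized to a distribution for the entropy (bits) but reported as
    raw periodogram densities for the peak powers. Constant input → all 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise InvalidParameterError("spectral_features needs >= 8 samples")
    freqs, power = sp_signal.periodogram(
        x, fs=fs, window="boxcar", detrend="constant"
    )
    freqs, power = freqs[1:], power[1:]  # drop DC
    total = float(power.sum())
    if total <= 0.0 or not math.isfinite(total):
        return 0.0, 0.0, 0.0, 0.0, 0.0
    p = power / total
    pos = p[p > 0]
    ent = float(-(pos * np.log2(pos)).sum())
    i_main = int(np.argmax(power))
    main_freq = float(freqs[i_main])
    main_power = float(power[i_main])
    # secondary peak: largest bin not adjacent to the main bin
    mask = np.abs(np.arange(power.size) - i_main) > 1
    if mask.any() and float(power[mask].max()) > 0.0:
        i_sec = int(np.arange(power.size)[mask][np.argmax(power[mask])])
        sec_freq = float(freqs[i_sec])
        sec_power = float(power[i_sec])
    else:
        sec_freq, sec_power = 0.0, 0.0
    return ent, main_freq, main_power, sec_freq, sec_power


def difference_sum(x: np.ndarray) -> float:
    """Total variation Σ|x[i+1] − x[i]| of the signal."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("difference_sum needs >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def average_jerk(x: np.ndarray, fs: float) -> float:
    """Mean absolute first difference scaled to per-second: mean|Δx| · fs."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("average_jerk needs >= 2 samples")
    return float(np.abs(np.diff(x)).mean() * fs)


def cross_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation of two axes; constant input → 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError(
            "cross_correlation needs equal lengths >= 3"
        )
    sx = np.std(x)
    sy = np.std(y)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def _axis_features(x: np.ndarray, fs: float, **kw) -> dict[str, float]:
    sd, skew, kurt = stat_features(x)
    ent, f_main, p_main, f_sec, p_sec = spectral_features(x, fs)
    return {
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "sparsity": sparsity(x),
        "shannon_entropy": shannon_entropy(x, n_bins=kw.get("n_bins", 16)),
        "sample_entropy": sample_entropy(
            x, m=kw.get("m", 2), r_frac=kw.get("r_frac", 0.2)
        )
        if np.std(x) > 0
        else 0.0,
        "spectral_entropy": ent,
        "main_freq_power": p_main,
        "secondary_freq_power": p_sec,
        "main_freq": f_main,
        "secondary_freq": f_sec,
        "difference_sum": difference_sum(x),
        "average_jerk": average_jerk(x, fs),
    }


def extract_features(recording: IMURecording, **kw) -> dict[str, float]:
    """The 42 named features of one harmonized recording, in canonical order.

    Never raises on degenerate-but-valid signals: each primitive's guard
    value is propagated so the result is always 42 finite scalars.
    """
    out: dict[str, float] = {}
    for axis in AXES:
        vals = _axis_features(recording.axis(axis), recording.fs, **kw)
        for feat in PER_AXIS_FEATURES:
            out[f"{axis}_{feat}"] = vals[feat]
    out["xcorr_MLAP"] = cross_correlation(recording.ml, recording.ap)
    out["xcorr_MLVT"] = cross_correlation(recording.ml, recording.vt)
    out["xcorr_APVT"] = cross_correlation(recording.ap, recording.vt)
    assert tuple(out) == FEATURE_NAMES
    return out


def features_from_cohort(
    records: list[SubjectRecord],
    placements: list[str] | None = None,
    trim_s: float = 0.5,
):
    """Feature table for a simulated cohort: one row per subject × condition × sensor.

    Runs the full preprocessing path (cue segmentation, edge trimming, axis
    harmonization, dominance relabeling) on each subject's session streams,
    then extracts the 42 features. Returns a pandas DataFrame with metadata
    columns subject_id, condition, placement, role, followed by the feature
    columns and the ground-truth ``av_in_per_s``.
    """
    import pandas as pd

    from .session_io import manifest_from_record

    rows = []
    for record in records:
        manifest = manifest_from_record(record)
        for (placement, side), session in record.sessions.items():
            if placements is not None and placement not in placements:
                continue
            role = assign_dominance(placement, side, record.handedness)
            segments = segment_by_cues(session, manifest)
            for cond, seg in segments.items():
                trimmed = trim_edges(seg, trim_s=trim_s)
                rec = harmonize_axes(trimmed, role=role)
                row = {
                    "subject_id": record.subject_id,
                    "condition": cond,
                    "placement": placement,
                    "role": role,
                }
                row.update(extract_features(rec))
                row["av_in_per_s"] = record.scores[cond].av
                rows.append(row)
    return pd.DataFrame(rows)
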