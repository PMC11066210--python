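"""Center-of-pressure posturography scores.

Path length (PL, inches) is the discrete Euclidean arc length of the COP
trajectory; average velocity (AV, inches/second) is PL divided by elapsed
time. Higher values indicate greater postural instability. No smoothing is
applied: scores are functions of the raw trace.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .types import BalanceScore, COPTrace

__all__ = ["path_length", "average_velocity", "score_trace"]


def path_length(cop: COPTrace) -> float:
    """Total distance travelled by the COP, in inches.

    Sum over consecutive samples of sqrt(dx^2 + dy^2); zero iff the trace is
    constant, and never less than the straight-line first-to-last distance.
    """
    if cop.n_samples < 2:
        raise InvalidParameterError("path length needs >= 2 samples")
    return float(np.hypot(np.diff(cop.x), np.diff(cop.y)).sum())


def average_velocity(cop: COPTrace) -> float:
    """Mean COP speed in inches/second: path length over elapsed time.

    Elapsed time is taken from the timestamps (last minus first), not from
    the sample count, so irregular traces fail upstream rather than being
    silently rescaled here.
    """
    elapsed = cop.duration_s
    if elapsed <= 0:
        raise InvalidParameterError("average velocity needs positive duration")
    return path_length(cop) / elapsed


def score_trace(cop: COPTrace, condition: str) -> BalanceScore:
    """Bundle PL and AV for one condition's trace into a :class:`BalanceScore`."""
    pl = path_length(cop)
    elapsed = cop.duration_s
    if elapsed <= 0:
        raise InvalidParameterError("scoring needs positive duration")
    return BalanceScore(
        condition=condition, pl=pl, av=pl / elapsed, duration_s=elapsed
    )
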