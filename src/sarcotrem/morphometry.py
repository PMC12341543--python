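"""Spine-curvature morphometry and inverted-hang summaries.

The kyphotic index (KI) quantifies spinal curvature from two vertebral
landmarks and the dorsal spine profile: KI is the C7-L6 chord length
divided by the maximal perpendicular distance from that chord to the
dorsal curve. A straighter spine gives a larger KI; pathological kyphosis
lowers it. The inverted-hang assay measures whole-body neuromuscular
endurance as hang time, capped at 180 s per trial, averaged over the
(typically 3) trials of one animal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

HANG_CAP_S = 180.0


@dataclass
class SpineLandmarks:
    """C7 and L6 vertebral points plus the dorsal spine polyline."""

    c7: tuple[float, float]
    l6: tuple[float, float]
    dorsal_curve: np.ndarray  # (n, 2) ordered points, same units as landmarks

    def __post_init__(self) -> None:
        self.c7 = (float(self.c7[0]), float(self.c7[1]))
        self.l6 = (float(self.l6[0]), float(self.l6[1]))
        self.dorsal_curve = np.atleast_2d(
            np.asarray(self.dorsal_curve, dtype=float)
        )
        if self.dorsal_curve.shape[1] != 2 or self.dorsal_curve.size == 0:
            raise ValueError("dorsal_curve must be a nonempty (n, 2) array")
        if np.allclose(self.c7, self.l6):
            raise ValueError("C7 and L6 landmarks must differ")


def kyphotic_index(s: SpineLandmarks, tol: float = 1e-12) -> float:
    """Chord length / maximal perpendicular dorsal deviation.

    Perpendicular distances are measured to the infinite line through
    C7-L6. A perfectly straight profile (zero maximal deviation) yields
    ``inf`` with a warning.
    """
    c7 = np.array(s.c7)
    l6 = np.array(s.l6)
    chord_vec = l6 - c7
    chord_len = float(np.linalg.norm(chord_vec))
    rel = s.dorsal_curve - c7
    # scalar cross product gives signed area; |.| / chord = point-line distance
    cross = chord_vec[0] * rel[:, 1] - chord_vec[1] * rel[:, 0]
    max_perp = float(np.max(np.abs(cross)) / chord_len)
    if max_perp <= tol * max(chord_len, 1.0):
        warnings.warn(
            "dorsal profile lies on the C7-L6 chord: kyphotic index is "
            "infinite (perfectly straight spine)",
            stacklevel=2,
        )
        return math.inf
    return chord_len / max_perp


@dataclass
class HangTrials:
    """Per-trial inverted-hang times for one animal."""

    times_s: list[float] = field(default_factory=list)
    cap_s: float = HANG_CAP_S


def hang_summary(h: HangTrials) -> float:
    """Mean hang time after clipping each trial at the cap (180 s)."""
    times = np.asarray(h.times_s, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one hang trial")
    if np.any(times < 0):
        raise ValueError("hang times must be nonnegative")
    return float(np.clip(times, 0.0, h.cap_s).mean())
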