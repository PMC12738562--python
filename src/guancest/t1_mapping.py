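"""Dual-flip-angle (DESPOT1) T1 mapping from a spoiled gradient-echo pair.

The SPGR signal S(a) = M0 sin(a) (1 - E1) / (1 - E1 cos(a)), E1 = exp(-TR/T1),
is linear in the coordinates y = S/sin(a), x = S/tan(a) with slope E1.  Two
flip angles determine the line exactly, so T1 = -TR / ln(slope) in closed
form; no iterative fitting is involved.  Flip angles are taken as nominal
(no B1 correction map exists in the protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

T1_MAX_MS = 10_000.0


@dataclass(frozen=True)
class DFAAcquisition:
    tr_ms: float = 25.0
    flip_deg_low: float = 5.0
    flip_deg_high: float = 30.0

    def __post_init__(self):
        if not (0.0 < self.flip_deg_low < self.flip_deg_high < 90.0):
            raise ValueError("require 0 < low flip < high flip < 90 degrees")
        if self.tr_ms <= 0:
            raise ValueError("TR must be > 0")


@dataclass
class T1Map:
    t1_ms: np.ndarray
    valid: np.ndarray       # True where 0 < T1 < 10 s and the slope was physical


def compute_t1_dfa(s_low: np.ndarray, s_high: np.ndarray,
                   acq: DFAAcquisition = DFAAcquisition()) -> T1Map:
    """Closed-form two-point DESPOT1 inversion.

    Voxels where the linearized slope falls outside (0, 1) — air, pure noise,
    or non-physical signal ratios — are flagged invalid rather than raising.
    """
    s1 = np.asarray(s_low, dtype=float)
    s2 = np.asarray(s_high, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("flip-angle volumes must share a shape")
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("SPGR magnitudes must be >= 0")

    a1 = np.deg2rad(acq.flip_deg_low)
    a2 = np.deg2rad(acq.flip_deg_high)
    y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
    y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)

    with np.errstate(divide="ignore", invalid="ignore"):
        dx = x2 - x1
        slope = np.where(dx != 0, (y2 - y1) / np.where(dx != 0, dx, 1.0), np.nan)
        t1 = -acq.tr_ms / np.log(slope)
    valid = np.isfinite(t1) & (slope > 0) & (slope < 1) & (t1 > 0) & (t1 < T1_MAX_MS)
    t1 = np.where(valid, t1, np.nan)
    return T1Map(t1_ms=t1, valid=valid)
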