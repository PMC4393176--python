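"""Dyskinesia index: cycle-averaged coherence of regional radial wall motion.

After myocardial infarction the structurally weakened infarct zone can bulge
outward under systolic pressure while the remote myocardium contracts inward
(early dyskinesia).  The efficiency of endocardial displacement at a time
point t is

    eff(t) = |Σ_i d_i(t)| / Σ_i |d_i(t)|

where d_i(t) is the mean radial displacement of segment i (inward positive).
The dyskinesia index DI is the mean of eff(t) over the cardiac cycle.  DI lies
in [0, 1]: unity means completely polar (coherent) motion, and smaller values
indicate increasing dyskinesis.  Time points where all segments are at rest
(the denominator vanishes — always including the reference frame) carry no
directional information and are excluded from the average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import SegmentDisplacementField

__all__ = ["DyskinesiaResult", "efficiency_series", "dyskinesia_index", "ZERO_MOTION_EPS"]

#: Denominator threshold (mm) below which a frame is treated as motionless.
ZERO_MOTION_EPS = 1e-9


@dataclass
class DyskinesiaResult:
    """Displacement-efficiency series and its cycle average.

    Attributes
    ----------
    eff : ndarray, shape (T,)
        eff(t) per frame; NaN at excluded (motionless) frames.
    di : float
        Dyskinesia index — mean of eff over included frames, in [0, 1].
    excluded_frames : list of int
        Frames excluded for a zero denominator (includes the reference frame).
    frame_times : ndarray
        Copied from the input field.
    """

    eff: np.ndarray
    di: float
    excluded_frames: list
    frame_times: np.ndarray


def efficiency_series(field: SegmentDisplacementField, eps: float = ZERO_MOTION_EPS) -> np.ndarray:
    """eff(t) = |Σ d|/Σ|d| per frame; NaN where Σ|d| <= eps.

    By the triangle inequality every returned value lies in [0, 1].
    """
    d = field.d
    num = np.abs(d.sum(axis=0))
    den = np.abs(d).sum(axis=0)
    eff = np.full(d.shape[1], np.nan)
    ok = den > eps
    eff[ok] = num[ok] / den[ok]
    return eff


def dyskinesia_index(field: SegmentDisplacementField, eps: float = ZERO_MOTION_EPS) -> DyskinesiaResult:
    """Dyskinesia index of a segment displacement field.

    Raises
    ------
    ValueError
        If every frame is excluded (no motion anywhere in the cycle), in which
        case the index is undefined.
    """
    eff = efficiency_series(field, eps=eps)
    excluded = [int(i) for i in np.nonzero(np.isnan(eff))[0]]
    if len(excluded) == eff.size:
        raise ValueError("DI undefined: all frames have zero total displacement")
    di = float(np.nanmean(eff))
    return DyskinesiaResult(eff=eff, di=di, excluded_frames=excluded, frame_times=field.frame_times)
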