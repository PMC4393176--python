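"""3D LV volumetrics by short-axis disc summation.

End-diastole (ED) and end-systole (ES) are detected independently per slice
as the frames of maximal and minimal endocardial cross-sectional area — the
per-slice (asynchronous) definition; a dyssynchronous ventricle therefore
contributes each slice at its own extremes.  Volumes sum slice area × slice
spacing over the apex-to-base stack (plain discs, no apex/base cap
correction).  Units: mm³ ≡ µL, reported as µL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .io import CineStack

__all__ = [
    "VolumetricsResult",
    "contour_area",
    "ed_es_frames",
    "lv_volumes",
    "ef_sv",
    "relative_change",
]


def contour_area(vertices) -> float:
    """Enclosed area of a simple closed polygon, mm² (orientation-independent)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError(f"polygon needs >= 3 (x, y) vertices, got shape {v.shape}")
    return float(Polygon(v).area)


def ed_es_frames(frames) -> tuple[int, int]:
    """(ED, ES) frame indices: max- and min-area frames, earliest on ties."""
    areas = np.array([contour_area(f) for f in frames])
    if areas.size < 2:
        raise ValueError("need at least 2 frames to locate ED and ES")
    return int(np.argmax(areas)), int(np.argmin(areas))


@dataclass
class VolumetricsResult:
    """Disc-summation volumetrics of one cine stack.

    ``per_slice`` columns: slice, ed_frame, es_frame, area_ed_mm2, area_es_mm2.
    Volumes in µL (≡ mm³), ``ef`` in percent.
    """

    per_slice: pd.DataFrame
    lvedv: float
    lvesv: float
    ef: float
    sv: float
    slice_spacing: float


def ef_sv(lvedv: float, lvesv: float) -> tuple[float, float]:
    """Ejection fraction (%) and stroke volume (µL) from the two volumes."""
    if lvedv <= 0:
        raise ValueError(f"LVEDV must be positive, got {lvedv}")
    if not 0 <= lvesv <= lvedv:
        raise ValueError(
            f"LVESV ({lvesv}) must lie in [0, LVEDV={lvedv}] — "
            "suspect ED/ES mis-detection upstream"
        )
    sv = lvedv - lvesv
    return 100.0 * sv / lvedv, sv


def lv_volumes(stack: CineStack) -> VolumetricsResult:
    """LVEDV/LVESV by disc summation, with per-slice ED/ES detail.

    Each slice contributes its own ED-frame (max area) and ES-frame (min
    area) cross-section; V = Σ area × spacing.
    """
    stack.validate()
    rows = []
    for i, sl in enumerate(stack.slices):
        areas = np.array([contour_area(f) for f in sl.endo])
        ed, es = int(np.argmax(areas)), int(np.argmin(areas))
        rows.append(
            {
                "slice": i,
                "ed_frame": ed,
                "es_frame": es,
                "area_ed_mm2": float(areas[ed]),
                "area_es_mm2": float(areas[es]),
            }
        )
    per_slice = pd.DataFrame(rows)
    h = stack.slice_spacing
    lvedv = float(per_slice["area_ed_mm2"].sum() * h)
    lvesv = float(per_slice["area_es_mm2"].sum() * h)
    ef, sv = ef_sv(lvedv, lvesv)
    return VolumetricsResult(
        per_slice=per_slice, lvedv=lvedv, lvesv=lvesv, ef=ef, sv=sv, slice_spacing=h
    )


def relative_change(series, baseline: float) -> np.ndarray:
    """Fold-change of a longitudinal series relative to the animal's baseline.

    Used for volumes (the study design normalises LVEDV/LVESV/SV to baseline
    because of between-group baseline differences); EF is reported absolute —
    which metrics are normalised is a pipeline-config decision, not done here.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return np.asarray(series, dtype=float) / float(baseline)
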