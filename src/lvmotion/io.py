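"""Contour-cine and displacement-table formats.

Two plain-text interchange formats are supported:

* **Cine stack (JSON)** — the full 3D+t contour dataset: an apex-to-base list
  of short-axis slices, each a list of frames, each frame an ordered closed
  endocardial polygon (optionally paired with an epicardial polygon), all in
  mm::

      {"slice_spacing_mm": 1.0,
       "frame_times": [0.0, ...],
       "slices": [[{"endo": [[x, y], ...], "epi": [[x, y], ...]}, ...], ...]}

  Coordinates are mm with y increasing toward anterior; the origin is
  arbitrary per slice (only relative geometry matters) and angles are
  measured counterclockwise from the +x axis.

* **Displacement table (CSV)** — the per-segment radial-displacement export of
  a speckle tracker: columns ``segment_id`` (1-based), ``frame_index``
  (0-based), ``displacement_mm``; ``#``-prefixed ``key=value`` header lines
  carry metadata (``units``, ``frame_times``, ``reference_frame``, ``source``).
  A ``units=um`` header (or a ``displacement_um`` column) is converted to mm
  on read.

On read, vertex order is normalised to counterclockwise and structural
integrity is validated (simple polygons, >= 8 vertices, consistent frame
counts across slices, complete segment × frame grids).
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .kinematics import SegmentDisplacementField, signed_area

__all__ = [
    "SliceCine",
    "CineStack",
    "read_cine_stack",
    "write_cine_stack",
    "read_displacement_table",
    "write_displacement_table",
    "write_report",
]


def _as_ccw(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    return v if signed_area(v) > 0 else v[::-1].copy()


@dataclass
class SliceCine:
    """One short-axis slice: endocardial (and optional epicardial) contour per frame."""

    endo: list
    epi: list | None = None

    def __post_init__(self) -> None:
        self.endo = [_as_ccw(f) for f in self.endo]
        if self.epi is not None:
            self.epi = [_as_ccw(f) for f in self.epi]

    @property
    def n_frames(self) -> int:
        return len(self.endo)


@dataclass
class CineStack:
    """Short-axis contour cine stack, ordered apex → base.

    Attributes
    ----------
    slices : list of SliceCine
    slice_spacing : float
        Inter-slice distance, mm.
    frame_times : ndarray
        Fraction-of-cycle per frame, shared by all slices, in [0, 1).
    """

    slices: list
    slice_spacing: float
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_frames(self) -> int:
        return self.slices[0].n_frames if self.slices else 0

    def validate(self) -> "CineStack":
        """Check structural invariants; raise ValueError naming the offender."""
        if not self.slices:
            raise ValueError("cine stack has no slices")
        if self.slice_spacing <= 0:
            raise ValueError(f"slice_spacing must be positive, got {self.slice_spacing}")
        counts = [s.n_frames for s in self.slices]
        if len(set(counts)) != 1:
            offenders = ", ".join(
                f"slice {i} has {c} frames" for i, c in enumerate(counts)
            )
            raise ValueError(f"inconsistent frame counts across slices: {offenders}")
        if self.frame_times.shape != (counts[0],):
            raise ValueError(
                f"frame_times length {self.frame_times.size} does not match "
                f"{counts[0]} frames"
            )
        if np.any(np.diff(self.frame_times) <= 0) or np.any(
            (self.frame_times < 0) | (self.frame_times >= 1)
        ):
            raise ValueError("frame_times must be strictly increasing in [0, 1)")
        for i, sl in enumerate(self.slices):
            contours = [("endo", sl.endo)]
            if sl.epi is not None:
                if len(sl.epi) != len(sl.endo):
                    raise ValueError(f"slice {i}: epi/endo frame counts differ")
                contours.append(("epi", sl.epi))
            for name, frames in contours:
                for t, v in enumerate(frames):
                    if v.shape[0] < 8:
                        raise ValueError(
                            f"slice {i} frame {t} ({name}): polygon has "
                            f"{v.shape[0]} vertices, need >= 8"
                        )
                    if not Polygon(v).is_valid:
                        raise ValueError(
                            f"slice {i} frame {t} ({name}): polygon is not simple"
                        )
        return self


def write_cine_stack(stack: CineStack, path) -> None:
    """Serialise a cine stack to the canonical JSON document."""
    doc = {
        "slice_spacing_mm": float(stack.slice_spacing),
        "frame_times": [float(t) for t in stack.frame_times],
        "slices": [
            [
                {
                    "endo": np.asarray(f).tolist(),
                    **(
                        {"epi": np.asarray(sl.epi[k]).tolist()}
                        if sl.epi is not None
                        else {}
                    ),
                }
                for k, f in enumerate(sl.endo)
            ]
            for sl in stack.slices
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_cine_stack(path) -> CineStack:
    """Load and validate a cine stack from its JSON document."""
    doc = json.loads(Path(path).read_text())
    try:
        slices = [
            SliceCine(
                endo=[np.asarray(fr["endo"], dtype=float) for fr in sl],
                epi=(
                    [np.asarray(fr["epi"], dtype=float) for fr in sl]
                    if sl and "epi" in sl[0]
                    else None
                ),
            )
            for sl in doc["slices"]
        ]
        stack = CineStack(
            slices=slices,
            slice_spacing=float(doc["slice_spacing_mm"]),
            frame_times=np.asarray(doc["frame_times"], dtype=float),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed cine-stack document {path}: {exc}") from None
    return stack.validate()


def write_displacement_table(
    field: SegmentDisplacementField, path, source: str = "lvmotion"
) -> None:
    """Write a displacement field as the instrument-style long CSV."""
    m, t = field.d.shape
    seg, fr = np.meshgrid(np.arange(1, m + 1), np.arange(t), indexing="ij")
    df = pd.DataFrame(
        {
            "segment_id": seg.ravel(),
            "frame_index": fr.ravel(),
            "displacement_mm": field.d.ravel(),
        }
    )
    header = (
        f"# source={source}\n"
        f"# units=mm\n"
        f"# n_segments={m}\n"
        f"# n_frames={t}\n"
        f"# reference_frame={field.reference_frame}\n"
        f"# frame_times={','.join(repr(float(x)) for x in field.frame_times)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _parse_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_displacement_table(path) -> SegmentDisplacementField:
    """Read a displacement CSV into a dense M×T field.

    Fails loudly on duplicate or missing (segment, frame) cells and on
    non-numeric displacement values; µm tables are converted to mm.
    """
    meta = _parse_header(path)
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if "displacement_mm" in cols:
        value_col, scale = "displacement_mm", 1.0
    elif "displacement_um" in cols:
        value_col, scale = "displacement_um", 1e-3
    else:
        raise ValueError(
            f"{path}: expected a displacement_mm (or displacement_um) column, "
            f"got {sorted(cols)}"
        )
    if not {"segment_id", "frame_index"} <= cols:
        raise ValueError(f"{path}: expected columns segment_id, frame_index")
    units = meta.get("units", "mm").lower()
    if units in ("um", "µm", "micron", "microns"):
        scale = 1e-3
    elif units != "mm":
        raise ValueError(f"{path}: unsupported units {units!r}")

    values = pd.to_numeric(df[value_col], errors="coerce")
    if values.isna().any():
        row = int(df.index[values.isna()][0])
        raise ValueError(f"{path}: non-numeric displacement at row {row}")

    dup = df.duplicated(subset=["segment_id", "frame_index"])
    if dup.any():
        s, f = df.loc[dup.idxmax(), ["segment_id", "frame_index"]]
        raise ValueError(f"{path}: duplicate cell (segment {int(s)}, frame {int(f)})")

    segments = np.sort(df["segment_id"].unique())
    frames = np.sort(df["frame_index"].unique())
    m, t = segments.size, frames.size
    if not np.array_equal(segments, np.arange(1, m + 1)):
        raise ValueError(f"{path}: segment_id must be 1..{m} with no gaps")
    if not np.array_equal(frames, np.arange(t)):
        raise ValueError(f"{path}: frame_index must be 0..{t - 1} with no gaps")
    if len(df) != m * t:
        grid = pd.MultiIndex.from_product([segments, frames])
        have = pd.MultiIndex.from_frame(df[["segment_id", "frame_index"]])
        missing = grid.difference(have)[0]
        raise ValueError(
            f"{path}: missing cell (segment {int(missing[0])}, frame {int(missing[1])})"
        )

    wide = (
        df.assign(value=values * scale)
        .pivot(index="segment_id", columns="frame_index", values="value")
        .sort_index()
    )
    d = wide.to_numpy()

    if "frame_times" in meta:
        frame_times = np.array([float(x) for x in meta["frame_times"].split(",")])
    else:
        frame_times = np.arange(t) / t
    if "reference_frame" in meta:
        reference = int(meta["reference_frame"])
    else:
        reference = int(np.argmin(np.abs(d).sum(axis=0)))
    if np.abs(d[:, reference]).max() > 1e-9:
        raise ValueError(
            f"{path}: reference frame {reference} has nonzero displacement"
        )
    d[:, reference] = 0.0  # absorb float-formatting dust
    return SegmentDisplacementField(d=d, frame_times=frame_times, reference_frame=reference)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": list(obj.columns),
            "rows": json.loads(obj.to_json(orient="values")),
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, out_dir) -> list:
    """Serialise study results deterministically.

    DataFrames are written both as individual CSV files and inside a single
    ``report.json`` (sorted keys); everything else goes to the JSON only.
    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            p = out / f"{key}.csv"
            value.to_csv(p, index=False)
            written.append(p)
    p = out / "report.json"
    p.write_text(json.dumps(_jsonable(results), sort_keys=True, indent=1))
    written.append(p)
    return written
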