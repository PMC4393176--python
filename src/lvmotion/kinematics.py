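"""Per-segment radial endocardial kinematics from short-axis contour cines.

The endocardium in a short-axis view is an approximately star-shaped closed
contour.  Motion is quantified as the mean radial displacement of each of M
equal angular segments (default 96), measured along rays cast from a fixed
centroid.  The centroid is taken from the reference (end-diastolic) frame and
held fixed across the cycle: a per-frame centroid would translate with a
bulging wall and mask dyskinetic motion, so the fixed choice is the
conservative one.

Sign convention: inward motion (toward the centroid) is positive, so a
normally contracting ventricle has positive systolic displacement everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "SegmentDisplacementField",
    "contour_centroid",
    "segment_radial_displacements",
]


@dataclass
class SegmentDisplacementField:
    """Mean radial displacement of M angular segments over a cardiac cycle.

    Attributes
    ----------
    d : ndarray, shape (M, T)
        Mean radial displacement in mm, signed, inward positive.  The
        reference-frame column is identically zero.
    frame_times : ndarray, shape (T,)
        Frame times as fraction of the cardiac cycle, in [0, 1), strictly
        increasing.
    reference_frame : int
        Index of the frame displacements are measured against (end-diastole).
    """

    d: np.ndarray
    frame_times: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.d.ndim != 2:
            raise ValueError(f"displacement matrix must be 2-D, got shape {self.d.shape}")
        m, t = self.d.shape
        if m < 2:
            raise ValueError(f"need at least 2 segments, got {m}")
        if self.frame_times.shape != (t,):
            raise ValueError(
                f"frame_times length {self.frame_times.shape} does not match "
                f"{t} frames"
            )
        if not (0 <= self.reference_frame < t):
            raise ValueError(f"reference_frame {self.reference_frame} out of range 0..{t - 1}")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("displacement field contains non-finite values")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.any(self.frame_times < 0) or np.any(self.frame_times >= 1):
            raise ValueError("frame_times must lie in [0, 1)")
        if np.any(self.d[:, self.reference_frame] != 0.0):
            raise ValueError("displacement at the reference frame must be zero")

    @property
    def n_segments(self) -> int:
        return self.d.shape[0]

    @property
    def n_frames(self) -> int:
        return self.d.shape[1]


def _close_polygon(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError(f"polygon must be an (n>=3, 2) vertex array, got shape {v.shape}")
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("polygon degenerates to fewer than 3 distinct vertices")
    return v


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise vertex order."""
    v = _close_polygon(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple closed polygon.

    Parameters
    ----------
    vertices : (n, 2) array
        Polygon vertices in order (either orientation); an explicitly closed
        ring (first vertex repeated) is accepted.

    Returns
    -------
    (2,) ndarray — centroid coordinates, same units as the input.
    """
    v = _close_polygon(vertices)
    poly = Polygon(v)
    if poly.area == 0.0:
        raise ValueError("degenerate polygon: zero area")
    c = poly.centroid
    return np.array([c.x, c.y])


def _ray_radii(vertices: np.ndarray, centre: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from `centre` to the polygon boundary along each ray angle.

    Requires the polygon to be star-shaped about `centre`: each ray must cross
    the boundary exactly once.  Vectorised over rays × edges.
    """
    v = _close_polygon(vertices) - centre
    p1 = v
    e = np.roll(v, -1, axis=0) - v  # edge vectors
    u = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (Q, 2)

    # Solve p1 + s*e = r*u for each (ray, edge) pair via 2-D cross products.
    denom = u[:, 0, None] * e[None, :, 1] - u[:, 1, None] * e[None, :, 0]  # (Q, E)
    cross_pu = u[:, 0, None] * p1[None, :, 1] - u[:, 1, None] * p1[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -cross_pu / denom
        px = p1[None, :, 0] + s * e[None, :, 0]
        py = p1[None, :, 1] + s * e[None, :, 1]
        r = px * u[:, 0, None] + py * u[:, 1, None]
    tiny = 1e-12
    hit = (np.abs(denom) > tiny) & (s >= 0.0) & (s < 1.0) & (r > tiny)
    n_hits = hit.sum(axis=1)
    bad = np.nonzero(n_hits != 1)[0]
    if bad.size:
        a = float(angles[bad[0]])
        raise ValueError(
            f"contour is not star-shaped about the reference centroid: ray at "
            f"angle {a:.4f} rad crosses the boundary {int(n_hits[bad[0]])} times"
        )
    return np.where(hit, r, 0.0).sum(axis=1)


def segment_radial_displacements(
    frames,
    n_segments: int = 96,
    rays_per_segment: int = 4,
    reference_frame: int | None = None,
    frame_times: np.ndarray | None = None,
) -> SegmentDisplacementField:
    """Mean radial displacement per angular segment, per frame.

    The reference frame defaults to the frame of maximal endocardial area
    (end-diastole).  The centroid of that frame is fixed; radii are sampled
    along ``rays_per_segment`` rays per segment at equal angular spacing
    (segment 1 starts at the +x axis, counterclockwise), averaged per segment,
    and displacement is ``r_ref - r_t`` so that inward motion is positive.

    Parameters
    ----------
    frames : sequence of (n, 2) arrays
        Endocardial contour per frame, simple closed polygons in mm.
    n_segments : int
        Number of equal angular segments (M ≥ 2); 96 matches the segment
        density of clinical speckle-tracking exports.
    rays_per_segment : int
        Radial samples per segment (K ≥ 1; ≥ 4 recommended).
    reference_frame : int, optional
        Frame index displacements are measured against.
    frame_times : array, optional
        Fraction-of-cycle per frame; defaults to a uniform grid.

    Raises
    ------
    ValueError
        For non-simple contours, or a contour that is not star-shaped with
        respect to the reference centroid (the error names the frame).
    """
    frames = [_close_polygon(f) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to measure displacement")
    if n_segments < 2:
        raise ValueError(f"n_segments must be >= 2, got {n_segments}")
    if rays_per_segment < 1:
        raise ValueError(f"rays_per_segment must be >= 1, got {rays_per_segment}")
    for k, f in enumerate(frames):
        if not Polygon(f).is_valid:
            raise ValueError(f"frame {k}: contour is not a simple polygon")

    if reference_frame is None:
        areas = [abs(signed_area(f)) for f in frames]
        reference_frame = int(np.argmax(areas))
    if not (0 <= reference_frame < len(frames)):
        raise ValueError(f"reference_frame {reference_frame} out of range")

    centre = contour_centroid(frames[reference_frame])
    q = n_segments * rays_per_segment
    # Offset by half a ray spacing so rays avoid segment-boundary vertices.
    angles = (np.arange(q) + 0.5) * (2.0 * np.pi / q)

    seg_radii = np.empty((len(frames), n_segments))
    for k, f in enumerate(frames):
        try:
            radii = _ray_radii(f, centre, angles)
        except ValueError as exc:
            raise ValueError(f"frame {k}: {exc}") from None
        seg_radii[k] = radii.reshape(n_segments, rays_per_segment).mean(axis=1)

    d = (seg_radii[reference_frame][None, :] - seg_radii).T  # (M, T), inward positive
    d[:, reference_frame] = 0.0
    if frame_times is None:
        frame_times = np.arange(len(frames)) / len(frames)
    return SegmentDisplacementField(d=d, frame_times=frame_times, reference_frame=reference_frame)
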