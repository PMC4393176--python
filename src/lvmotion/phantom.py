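"""Synthetic mouse left-ventricle motion phantom.

Emulates a murine short-axis echo acquisition as a stack of star-shaped
endocardial contours: 6–7 slices at 1.0 mm spacing, 30–40 frames per cardiac
cycle, ~1.5 mm end-diastolic endocardial radius and ~1 mm end-diastolic wall
thickness.  Each of M angular segments contracts radially with a shared
raised-cosine systolic waveform s(t) (s(0)=0, peaking at the end-systolic
fraction, returning to 0), scaled by a signed per-segment amplitude: positive
amplitudes move inward (normal contraction), negative amplitudes bulge outward
(dyskinesis).  Optional zero-mean Gaussian radial noise models tracking
jitter.

Because all segments share s(t), the dyskinesia index of the noiseless
phantom has the closed form DI = |Σ A_i| / Σ |A_i|, independent of the
waveform — the oracle every downstream stage is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CineStack, SliceCine
from .kinematics import SegmentDisplacementField

__all__ = [
    "MotionParams",
    "GroupSpec",
    "CohortAnimal",
    "dyskinetic_amplitudes",
    "systolic_waveform",
    "simulate_displacement_field",
    "simulate_cine_stack",
    "analytic_di",
    "analytic_volumes",
    "simulate_cohort",
    "simulate_displacement_cohort",
]


def systolic_waveform(t, es_fraction: float = 0.4):
    """Raised-cosine contraction waveform on the unit cycle.

    Rises smoothly from 0 at t=0 to 1 at ``es_fraction`` (end-systole), then
    relaxes back to 0 at t=1.
    """
    t = np.asarray(t, dtype=float)
    if not 0 < es_fraction < 1:
        raise ValueError(f"es_fraction must be in (0, 1), got {es_fraction}")
    up = 0.5 * (1 - np.cos(np.pi * t / es_fraction))
    down = 0.5 * (1 - np.cos(np.pi * (1 - t) / (1 - es_fraction)))
    return np.where(t <= es_fraction, up, down)


def dyskinetic_amplitudes(
    n_segments: int = 96,
    n_dyskinetic: int = 0,
    healthy: float = 0.4,
    dyskinetic: float = -0.3,
    start: int = 0,
) -> np.ndarray:
    """Amplitude vector with a contiguous dyskinetic (outward) sector.

    ``healthy`` mm of inward excursion everywhere except ``n_dyskinetic``
    consecutive segments beginning at index ``start``, which get the (negative)
    ``dyskinetic`` amplitude.
    """
    if not 0 <= n_dyskinetic <= n_segments:
        raise ValueError(f"n_dyskinetic must be in 0..{n_segments}, got {n_dyskinetic}")
    a = np.full(n_segments, float(healthy))
    idx = (start + np.arange(n_dyskinetic)) % n_segments
    a[idx] = float(dyskinetic)
    return a


@dataclass
class MotionParams:
    """Generative parameters of the LV motion phantom.

    Attributes
    ----------
    n_segments : int
        Angular segments per slice (speckle-tracker export density).
    n_frames : int
        Frames per cardiac cycle.
    amplitudes : (n_segments,) array
        Peak radial excursion per segment, mm, signed: positive = inward
        (contractile), negative = outward (dyskinetic).  Defaults to a uniform
        healthy +0.4 mm.
    base_radius : float
        End-diastolic endocardial radius at the basal slice, mm.
    wall_thickness_ed : float
        End-diastolic wall thickness, mm (normal mouse ≈ 1 mm).
    wall_thickness_dyskinetic : float or None
        If set, wall thickness (mm) over segments with negative amplitude —
        models infarct-zone thinning.  None keeps a uniform wall.
    n_slices, slice_spacing : stack geometry (apex → base), mm.
    apex_taper : float
        Linear per-slice fractional reduction of the base radius toward apex.
    es_fraction : float
        Fraction of the cycle at which end-systole occurs.
    noise_sd : float
        SD of additive radial noise, mm.
    vertices_per_segment : int
        Contour sampling density per angular segment.
    seed : int or None
        Seed for the noise generator.
    """

    n_segments: int = 96
    n_frames: int = 35
    amplitudes: np.ndarray | None = None
    base_radius: float = 1.5
    wall_thickness_ed: float = 1.0
    wall_thickness_dyskinetic: float | None = None
    n_slices: int = 6
    slice_spacing: float = 1.0
    apex_taper: float = 0.08
    es_fraction: float = 0.4
    noise_sd: float = 0.0
    vertices_per_segment: int = 8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amplitudes is None:
            self.amplitudes = np.full(self.n_segments, 0.4)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.n_segments < 2:
            raise ValueError(f"n_segments must be >= 2, got {self.n_segments}")
        if self.n_frames < 3:
            raise ValueError(f"n_frames must be >= 3, got {self.n_frames}")
        if self.amplitudes.shape != (self.n_segments,):
            raise ValueError(
                f"amplitudes must have shape ({self.n_segments},), "
                f"got {self.amplitudes.shape}"
            )
        if self.base_radius <= 0:
            raise ValueError(f"base_radius must be positive, got {self.base_radius}")
        if self.wall_thickness_ed <= 0:
            raise ValueError("wall_thickness_ed must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_slices < 1 or self.slice_spacing <= 0:
            raise ValueError("need n_slices >= 1 and positive slice_spacing")
        if not 0 <= self.apex_taper < 1:
            raise ValueError(f"apex_taper must be in [0, 1), got {self.apex_taper}")
        if self.vertices_per_segment < 4:
            raise ValueError("vertices_per_segment must be >= 4")
        if np.max(np.abs(self.amplitudes)) >= self.base_radius:
            raise ValueError(
                "amplitudes must satisfy |a| < base_radius (contour would self-invert)"
            )

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.n_frames

    @property
    def slice_radii(self) -> np.ndarray:
        """End-diastolic endocardial radius per slice, apex (index 0) → base."""
        k = np.arange(self.n_slices)
        return self.base_radius * (1 - self.apex_taper * (self.n_slices - 1 - k))


def simulate_displacement_field(params: MotionParams) -> SegmentDisplacementField:
    """Direct emulation of a speckle-tracker displacement export.

    d[i, t] = amplitudes[i] · s(t) + ε with ε ~ N(0, noise_sd²) on every frame
    except the reference (frame 0, where displacement is zero by definition).
    Inward motion is positive.
    """
    t = params.frame_times
    s = systolic_waveform(t, params.es_fraction)
    d = params.amplitudes[:, None] * s[None, :]
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        noise = rng.normal(0.0, params.noise_sd, size=d.shape)
        noise[:, 0] = 0.0
        d = d + noise
    return SegmentDisplacementField(d=d, frame_times=t, reference_frame=0)


def _thickness_map(params: MotionParams, amp_per_vertex: np.ndarray) -> np.ndarray:
    th = np.full(amp_per_vertex.size, params.wall_thickness_ed)
    if params.wall_thickness_dyskinetic is not None:
        th[amp_per_vertex < 0] = params.wall_thickness_dyskinetic
    return th


def simulate_cine_stack(params: MotionParams) -> CineStack:
    """Generate the short-axis contour cine stack for one phantom heart.

    Each slice's endocardial radius is r(θ, t) = R_slice − A(θ)·s(t) + ε with
    A(θ) piecewise-constant over the angular segments; the epicardium rides
    outside the endocardium at the (possibly sector-thinned) wall thickness.
    Radial noise ε is drawn per (frame, segment) and shared by the segment's
    vertices — the granularity at which a speckle tracker actually jitters —
    so noisy contours stay locally smooth.

    Raises
    ------
    ValueError
        If any radius would be ≤ 0 (invalid geometry).
    """
    nv = params.n_segments * params.vertices_per_segment
    theta = (np.arange(nv) + 0.5) * (2 * np.pi / nv)
    sector = np.arange(nv) // params.vertices_per_segment
    amp_v = params.amplitudes[sector]
    s = systolic_waveform(params.frame_times, params.es_fraction)
    thickness = _thickness_map(params, amp_v)
    rng = np.random.default_rng(params.seed)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    slices = []
    for r_ed in params.slice_radii:
        r = float(r_ed) - amp_v[None, :] * s[:, None]  # (T, nv)
        if params.noise_sd > 0:
            seg_noise = rng.normal(
                0.0, params.noise_sd, size=(len(s), params.n_segments)
            )
            r = r + seg_noise[:, sector]
        if np.any(r <= 0):
            raise ValueError(
                "phantom parameters produce a non-positive endocardial radius"
            )
        r_epi = r + thickness[None, :]
        endo = [np.column_stack([rt * cos_t, rt * sin_t]) for rt in r]
        epi = [np.column_stack([rt * cos_t, rt * sin_t]) for rt in r_epi]
        slices.append(SliceCine(endo=endo, epi=epi))
    return CineStack(
        slices=slices, slice_spacing=params.slice_spacing, frame_times=params.frame_times
    )


def analytic_di(params: MotionParams) -> float:
    """Closed-form dyskinesia index of the noiseless shared-waveform phantom.

    With every segment driven by the same waveform, eff(t) is constant over
    all moving frames and DI = |Σ A_i| / Σ |A_i| regardless of the waveform.
    Defined only for noise_sd = 0.
    """
    if params.noise_sd != 0:
        raise ValueError("analytic DI is defined only for the noiseless phantom")
    denom = np.abs(params.amplitudes).sum()
    if denom == 0:
        raise ValueError("DI undefined: all amplitudes are zero")
    return float(abs(params.amplitudes.sum()) / denom)


def analytic_volumes(params: MotionParams) -> tuple[float, float]:
    """Exact disc-summation (LVEDV, LVESV) of the noiseless phantom, µL.

    Treats each angular segment as a circular sector: slice area
    = Σ_i (π/M)·r_i², summed over slices × spacing.  ED radii are the slice
    radii (s=0); ES radii subtract the full amplitude (s=1).
    """
    if params.noise_sd != 0:
        raise ValueError("analytic volumes are defined only for the noiseless phantom")
    m = params.n_segments
    v_ed = v_es = 0.0
    for r_ed in params.slice_radii:
        v_ed += params.slice_spacing * np.pi * r_ed**2
        r_es = r_ed - params.amplitudes
        v_es += params.slice_spacing * (np.pi / m) * float(np.sum(r_es**2))
    return float(v_ed), float(v_es)


@dataclass
class GroupSpec:
    """A cohort arm: a parameter template plus between-animal variability.

    ``amplitude_jitter_sd`` is the SD (mm) of independent zero-mean Gaussian
    perturbations added to each segment amplitude per animal.
    """

    name: str
    params: MotionParams
    amplitude_jitter_sd: float = 0.0


@dataclass
class CohortAnimal:
    """One simulated animal with its ground-truth generative parameters."""

    animal_id: str
    group: str
    params: MotionParams
    stack: CineStack | None = None
    field: SegmentDisplacementField | None = None


def _cohort_params(group_specs, n_per_group, seed) -> list:
    if isinstance(n_per_group, int):
        n_per_group = [n_per_group] * len(group_specs)
    if len(n_per_group) != len(group_specs):
        raise ValueError("n_per_group must match the number of groups")
    if any(n < 2 for n in n_per_group):
        raise ValueError("need n >= 2 animals per group (statistics undefined below)")
    children = iter(np.random.SeedSequence(seed).spawn(int(np.sum(n_per_group))))
    out = []
    for spec, n in zip(group_specs, n_per_group):
        base = spec.params
        cap = 0.99 * base.base_radius
        for j in range(n):
            rng = np.random.default_rng(next(children))
            amp = base.amplitudes.copy()
            if spec.amplitude_jitter_sd > 0:
                amp = amp + rng.normal(0.0, spec.amplitude_jitter_sd, size=amp.shape)
                amp = np.clip(amp, -cap, cap)
            animal_seed = int(rng.integers(2**31))
            p = replace(base, amplitudes=amp, seed=animal_seed)
            out.append((f"{spec.name}-{j + 1:02d}", spec.name, p))
    return out


def simulate_cohort(group_specs, n_per_group, seed=None) -> list:
    """Simulate labelled contour-cine cohorts with recorded ground truth.

    Deterministic given ``seed``; per-animal MotionParams (with jittered
    amplitudes and the animal's own noise seed) are returned alongside each
    stack so recovered quantities can be compared with the generative truth.
    """
    return [
        CohortAnimal(animal_id=a, group=g, params=p, stack=simulate_cine_stack(p))
        for a, g, p in _cohort_params(group_specs, n_per_group, seed)
    ]


def simulate_displacement_cohort(group_specs, n_per_group, seed=None) -> list:
    """Like :func:`simulate_cohort` but emitting displacement fields directly
    (the speckle-tracker-export route), which is much cheaper when only the
    dyskinesia stage is under study."""
    return [
        CohortAnimal(animal_id=a, group=g, params=p, field=simulate_displacement_field(p))
        for a, g, p in _cohort_params(group_specs, n_per_group, seed)
    ]
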