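"""Vessel edge sharpness from paired contours.

The metric mirrors how readers quantify vessel border quality: an inner and
an outer contour bracket the vessel edge in one slice plane; every outer
vertex is paired with its nearest inner vertex to form a segment crossing the
border; the image intensity is sampled along each segment at 10 points/mm by
bilinear interpolation; the 20% and 80% relative thresholds

    T_min = I_min + 0.2 (I_max - I_min),   T_max = I_min + 0.8 (I_max - I_min)

define a transition length ``L`` (mm), and the per-segment sharpness is
``1/L`` (1/mm). Per-vessel sharpness is the mean over retained segments.

Because the thresholds are relative, the metric is invariant under affine
intensity rescaling. For an ideal linear-ramp edge of width ``w`` the
transition length is ``0.6 w``, i.e. sharpness ``1/(0.6 w)`` — the analytic
oracle used throughout the tests.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist

from .geometry import ContourPair, PlaneRef
from .phantom import ImageVolume

__all__ = [
    "Segment",
    "ProfileSegment",
    "SharpnessResult",
    "SegmentRejected",
    "SharpnessError",
    "pair_contours",
    "sample_profile",
    "transition_length",
    "pv_sharpness",
    "results_to_frame",
]

PROFILE_STEP_MM = 0.1  # 10 points/mm


class SegmentRejected(Exception):
    """A profile that yields no valid transition (flat, non-monotone, ...)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class SharpnessError(ValueError):
    """A vessel for which no sharpness value can be reported."""


@dataclasses.dataclass
class Segment:
    """One virtual segment crossing the vessel border (mm, in-plane)."""

    outer_mm: np.ndarray  # (2,)
    inner_mm: np.ndarray  # (2,)
    plane: PlaneRef
    vessel: str = ""
    index: int = 0

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.inner_mm - self.outer_mm))


@dataclasses.dataclass
class ProfileSegment:
    """Intensity samples along one (extended) segment, outer end first."""

    segment: Segment
    samples: np.ndarray
    step_mm: float = PROFILE_STEP_MM
    extension_mm: float = 0.0
    # filled by transition_length
    I_min: float | None = None
    I_max: float | None = None
    T_min: float | None = None
    T_max: float | None = None
    L: float | None = None


@dataclasses.dataclass
class SharpnessResult:
    """Per-vessel sharpness: retained per-segment 1/L values and their mean."""

    vessel: str
    values: np.ndarray  # retained per-segment sharpness, 1/mm
    n_used: int
    n_rejected: int
    reject_reasons: dict[str, int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def pair_contours(pair: ContourPair) -> list[Segment]:
    """Pair each outer vertex with the Euclidean-nearest inner vertex.

    Zero-length segments (coincident vertices) are discarded; the caller can
    recover the discarded count from ``len(pair.outer) - len(segments)``.
    """
    d = cdist(pair.outer, pair.inner)
    nearest = np.argmin(d, axis=1)
    segments = []
    for i, (o, j) in enumerate(zip(pair.outer, nearest)):
        seg = Segment(
            outer_mm=np.asarray(o, dtype=float),
            inner_mm=np.asarray(pair.inner[j], dtype=float),
            plane=pair.plane,
            vessel=pair.name,
            index=i,
        )
        if seg.length_mm > 1e-9:
            segments.append(seg)
    return segments


def _plane_slice(image: ImageVolume, plane: PlaneRef) -> np.ndarray:
    if not (0 <= plane.index < image.shape[plane.axis]):
        raise ValueError(f"plane index {plane.index} outside axis {plane.axis}")
    sl = [slice(None)] * 3
    sl[plane.axis] = plane.index
    data = image.data[tuple(sl)]
    return np.abs(data) if np.iscomplexobj(data) else data


def sample_profile(
    image: ImageVolume, segment: Segment, extension_mm: float = 1.0
) -> ProfileSegment:
    """Sample the intensity profile along a segment at 10 points/mm.

    Samples run from the outer end to the inner end, each end extended
    symmetrically by ``extension_mm`` so the background and plateau extremes
    are captured. Bilinear interpolation in the contour plane of the slice.
    """
    direction = segment.inner_mm - segment.outer_mm
    length = float(np.linalg.norm(direction))
    if length <= 1e-12:
        raise SegmentRejected("zero_length")
    unit = direction / length
    start = segment.outer_mm - unit * extension_mm
    total = length + 2.0 * extension_mm
    n = int(np.floor(total / PROFILE_STEP_MM + 1e-9)) + 1
    t = np.arange(n) * PROFILE_STEP_MM
    pts = start[None, :] + t[:, None] * unit[None, :]

    slab = _plane_slice(image, segment.plane)
    axes = segment.plane.inplane_axes
    coords = []
    for k, ax in enumerate(axes):
        idx = (pts[:, k] - image.origin_mm[ax]) / image.spacing_mm - 0.5
        n_ax = image.shape[ax]
        if idx.min() < -0.5 - 1e-9 or idx.max() > n_ax - 0.5 + 1e-9:
            raise ValueError(
                f"segment {segment.vessel}#{segment.index} extends outside the image"
            )
        coords.append(idx)
    samples = map_coordinates(slab, np.stack(coords), order=1, mode="nearest")
    return ProfileSegment(
        segment=segment, samples=samples, extension_mm=extension_mm
    )


def _falling_crossings(values: np.ndarray, positions: np.ndarray, level: float):
    """Sub-sample positions where the profile falls through ``level``."""
    v0, v1 = values[:-1], values[1:]
    hit = (v0 >= level) & (v1 < level)
    idx = np.flatnonzero(hit)
    frac = (v0[idx] - level) / (v0[idx] - v1[idx])
    return positions[idx] + frac * (positions[idx + 1] - positions[idx])


def transition_length(profile: ProfileSegment, min_range: float = 0.0) -> float:
    """Length of the 80% -> 20% edge transition, walking outward.

    The profile is oriented from the bright lumen toward the dark background
    (outward); ``L`` is the distance from the last falling crossing of
    ``T_max`` to the first subsequent falling crossing of ``T_min``, with
    sub-sample positions by linear interpolation. Flat profiles (intensity
    range below ``min_range``) and profiles without a monotone 80->20
    transition raise :class:`SegmentRejected`.
    """
    samples = np.asarray(profile.samples, dtype=float)
    if samples.size < 2:
        raise SegmentRejected("too_few_samples")
    outward = samples[::-1]  # stored outer->inner; walk inner->outer
    positions = np.arange(outward.size) * profile.step_mm

    i_min, i_max = float(outward.min()), float(outward.max())
    rng = i_max - i_min
    if rng <= max(min_range, 1e-12 * max(abs(i_max), 1.0)):
        raise SegmentRejected("flat_profile")
    t_min = i_min + 0.2 * rng
    t_max = i_min + 0.8 * rng
    profile.I_min, profile.I_max = i_min, i_max
    profile.T_min, profile.T_max = t_min, t_max

    x_min = _falling_crossings(outward, positions, t_min)
    if x_min.size == 0:
        raise SegmentRejected("no_transition")
    first_min = x_min[0]
    x_max = _falling_crossings(outward, positions, t_max)
    x_max = x_max[x_max <= first_min]
    if x_max.size == 0:
        raise SegmentRejected("no_transition")
    L = float(first_min - x_max[-1])
    if L <= 0:
        raise SegmentRejected("no_transition")
    profile.L = L
    return L


def pv_sharpness(
    image: ImageVolume,
    pairs: list[ContourPair],
    extension_mm: float = 1.0,
    flat_floor_frac: float = 0.05,
    min_retained_frac: float = 0.5,
) -> list[SharpnessResult]:
    """Per-vessel mean sharpness 1/L over all contour pairs.

    Segments whose intensity range is below ``flat_floor_frac`` of the
    image's robust range (1st-99th percentile of the magnitude) are rejected,
    as are segments without a monotone transition or outside the image. A
    vessel must retain at least ``min_retained_frac`` of its segments to
    report a value; otherwise :class:`SharpnessError` is raised.
    """
    if not pairs:
        raise ValueError("need at least one contour pair")
    mag = np.abs(image.data)
    robust = float(np.percentile(mag, 99) - np.percentile(mag, 1))
    min_range = flat_floor_frac * robust

    results = []
    for pair in pairs:
        segments = pair_contours(pair)
        reasons: dict[str, int] = {}
        n_zero = len(pair.outer) - len(segments)
        if n_zero:
            reasons["zero_length"] = n_zero
        values = []
        for seg in segments:
            try:
                prof = sample_profile(image, seg, extension_mm=extension_mm)
                L = transition_length(prof, min_range=min_range)
                values.append(1.0 / L)
            except SegmentRejected as exc:
                reasons[exc.reason] = reasons.get(exc.reason, 0) + 1
            except ValueError:
                reasons["out_of_bounds"] = reasons.get("out_of_bounds", 0) + 1
        n_total = len(pair.outer)
        if not values or len(values) < min_retained_frac * n_total:
            raise SharpnessError(
                f"vessel '{pair.name}': only {len(values)}/{n_total} segments usable"
            )
        results.append(
            SharpnessResult(
                vessel=pair.name,
                values=np.asarray(values),
                n_used=len(values),
                n_rejected=n_total - len(values),
                reject_reasons=reasons,
            )
        )
    return results


def results_to_frame(results: list[SharpnessResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vessel": [r.vessel for r in results],
            "n_segments": [r.n_used for r in results],
            "n_rejected": [r.n_rejected for r in results],
            "mean_sharpness_mm^-1": [r.mean for r in results],
        }
    )


def results_to_csv(results: list[SharpnessResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(Path(path), index=False)
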