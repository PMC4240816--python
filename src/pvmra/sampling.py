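"""Prospective random Cartesian undersampling of the ky-kz plane.

The acquisition design keeps a fully sampled rectangular block of central
phase/slice-encode lines, never samples outside the elliptical window
inscribed in the (n_y, n_z) grid ("elliptical shutter"), and discards random
outer lines uniformly until the sampled-line count is ``round(N_ell / R)``,
where ``N_ell`` is the number of lines inside the elliptical window and ``R``
the nominal acceleration with respect to that window. The same fixed pattern
(one seed) is reused for every subject of a study. Lines are acquired in a
radial order (sorted by angle about DC, then radius) so consecutive k-space
jumps stay small, which limits eddy-current artifacts on the scanner.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._fft import dc_index

__all__ = [
    "SamplingPattern",
    "AcquisitionOrder",
    "elliptical_window",
    "generate_pattern",
    "effective_acceleration",
    "radial_reorder",
    "DEFAULT_PATTERN_SEED",
]

#: Seed of the single pattern reused by all fixtures (one pattern per study).
DEFAULT_PATTERN_SEED = 7


def elliptical_window(n_y: int, n_z: int) -> np.ndarray:
    """Boolean (n_y, n_z) grid of lines inside the inscribed elliptical window.

    Line (i, j) is inside iff ((i-cy)/(n_y/2))^2 + ((j-cz)/(n_z/2))^2 <= 1,
    with (cy, cz) the DC indices. The boundary is closed.
    """
    if n_y < 2 or n_z < 2:
        raise ValueError("elliptical window needs n_y, n_z >= 2")
    cy, cz = dc_index(n_y), dc_index(n_z)
    iy = (np.arange(n_y) - cy) / (n_y / 2.0)
    iz = (np.arange(n_z) - cz) / (n_z / 2.0)
    return (iy[:, None] ** 2 + iz[None, :] ** 2) <= 1.0 + 1e-12


def _center_block_mask(n_y: int, n_z: int, center_block: tuple[int, int]) -> np.ndarray:
    """Mask of the fully sampled center block, centered on DC.

    For odd block sizes the extra line extends toward positive index.
    """
    c_y, c_z = center_block
    if c_y < 1 or c_z < 1:
        raise ValueError("center block sizes must be >= 1")
    if c_y > n_y or c_z > n_z:
        raise ValueError("center block larger than grid")
    mask = np.zeros((n_y, n_z), dtype=bool)
    y0 = dc_index(n_y) - (c_y - 1) // 2
    z0 = dc_index(n_z) - (c_z - 1) // 2
    if y0 < 0 or z0 < 0 or y0 + c_y > n_y or z0 + c_z > n_z:
        raise ValueError("center block does not fit in the grid")
    mask[y0 : y0 + c_y, z0 : z0 + c_z] = True
    return mask


@dataclasses.dataclass
class SamplingPattern:
    """Boolean sampling mask over the (n_y, n_z) phase/slice-encode plane."""

    mask: np.ndarray
    center_block: tuple[int, int]
    R_elliptical: float
    seed: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D over (n_y, n_z)")
        if self.R_elliptical <= 0:
            raise ValueError("R_elliptical must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())

    def validate(self) -> None:
        """Assert the pattern invariants (center full, shutter empty, count)."""
        n_y, n_z = self.shape
        window = elliptical_window(n_y, n_z)
        center = _center_block_mask(n_y, n_z, self.center_block)
        if not self.mask[center].all():
            raise AssertionError("center block not fully sampled")
        if self.mask[~window].any():
            raise AssertionError("sampled lines outside the elliptical window")
        expected = int(round(window.sum() / self.R_elliptical))
        if self.n_sampled != expected:
            raise AssertionError(
                f"sampled count {self.n_sampled} != round(N_ell/R) = {expected}"
            )

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        runs = _rle_encode(self.mask.ravel())
        Path(path).write_text(
            json.dumps(
                {
                    "n_y": self.shape[0],
                    "n_z": self.shape[1],
                    "center_block": list(self.center_block),
                    "R_elliptical": self.R_elliptical,
                    "seed": self.seed,
                    "mask_rle": runs,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SamplingPattern":
        d = json.loads(Path(path).read_text())
        mask = _rle_decode(d["mask_rle"], d["n_y"] * d["n_z"]).reshape(d["n_y"], d["n_z"])
        return cls(
            mask=mask,
            center_block=tuple(d["center_block"]),
            R_elliptical=float(d["R_elliptical"]),
            seed=int(d["seed"]),
        )

    def to_png(self, path: str | Path) -> None:
        """Write the mask as a greyscale PNG for visual inspection."""
        from PIL import Image

        Image.fromarray((self.mask.astype(np.uint8) * 255)).save(Path(path))


def _rle_encode(flat: np.ndarray) -> list[int]:
    """Run lengths of alternating values starting with the run of ``False``."""
    flat = flat.astype(bool)
    runs: list[int] = []
    current = False
    count = 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(count)
            current = v
            count = 1
    runs.append(count)
    return runs


def _rle_decode(runs: list[int], n: int) -> np.ndarray:
    out = np.empty(n, dtype=bool)
    pos = 0
    val = False
    for r in runs:
        out[pos : pos + r] = val
        pos += r
        val = not val
    if pos != n:
        raise ValueError("run-length data does not match mask size")
    return out


def generate_pattern(
    n_y: int,
    n_z: int,
    R_elliptical: float,
    center_block: tuple[int, int] = (32, 19),
    seed: int = DEFAULT_PATTERN_SEED,
) -> SamplingPattern:
    """Build the study undersampling pattern.

    The full center block is always acquired; outer lines inside the
    elliptical window are kept as a uniform random subset (no variable-density
    taper) so that the total sampled count is ``round(N_ell / R_elliptical)``.
    A fixed seed reproduces the same pattern exactly.
    """
    window = elliptical_window(n_y, n_z)
    center = _center_block_mask(n_y, n_z, center_block)
    if not window[center].all():
        raise ValueError("center block extends outside the elliptical window")
    n_ell = int(window.sum())
    n_target = int(round(n_ell / R_elliptical))
    n_center = int(center.sum())
    if n_center > n_target:
        r_min = n_ell / n_center
        raise ValueError(
            f"infeasible budget: center block alone has {n_center} lines but the "
            f"target is {n_target}; minimum achievable R is {r_min:.3f}"
        )
    candidates = np.flatnonzero((window & ~center).ravel())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_target - n_center, replace=False)
    mask = center.copy().ravel()
    mask[chosen] = True
    return SamplingPattern(
        mask=mask.reshape(n_y, n_z),
        center_block=center_block,
        R_elliptical=R_elliptical,
        seed=seed,
    )


def effective_acceleration(pattern: SamplingPattern, reference: str = "elliptical") -> float:
    """Acceleration N_ref / N_sampled w.r.t. the elliptical window or full grid."""
    n_sampled = pattern.n_sampled
    if n_sampled == 0:
        raise ValueError("empty sampling mask")
    n_y, n_z = pattern.shape
    if reference == "elliptical":
        n_ref = int(elliptical_window(n_y, n_z).sum())
    elif reference == "full":
        n_ref = n_y * n_z
    else:
        raise ValueError("reference must be 'elliptical' or 'full'")
    return n_ref / n_sampled


@dataclasses.dataclass
class AcquisitionOrder:
    """Sampled lines in acquisition order, split into per-heartbeat segments."""

    lines: np.ndarray  # (N, 2) int indices (k_y, k_z)
    segment_size: int

    @property
    def segments(self) -> list[np.ndarray]:
        return [
            self.lines[i : i + self.segment_size]
            for i in range(0, len(self.lines), self.segment_size)
        ]


def radial_reorder(pattern: SamplingPattern, segment_size: int) -> AcquisitionOrder:
    """Order sampled lines by angle about DC, then radius, then raw index.

    The angle is ``atan2(k_z - cz, k_y - cy)``; the total order is
    deterministic, and the ordered list is a permutation of the sampled lines.
    """
    if segment_size < 1:
        raise ValueError("segment_size must be >= 1")
    n_y, n_z = pattern.shape
    cy, cz = dc_index(n_y), dc_index(n_z)
    ky, kz = np.nonzero(pattern.mask)
    dy, dz = ky - cy, kz - cz
    angle = np.arctan2(dz, dy)
    radius = np.hypot(dy, dz)
    raw = ky * n_z + kz
    order = np.lexsort((raw, radius, angle))
    lines = np.stack([ky[order], kz[order]], axis=1)
    return AcquisitionOrder(lines=lines, segment_size=segment_size)


def mean_segment_jump(order: AcquisitionOrder) -> float:
    """Mean Euclidean jump between consecutive lines within segments."""
    jumps: list[float] = []
    for seg in order.segments:
        if len(seg) > 1:
            jumps.extend(np.linalg.norm(np.diff(seg, axis=0), axis=1))
    if not jumps:
        return 0.0
    return float(np.mean(jumps))
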