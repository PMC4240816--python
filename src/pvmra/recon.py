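"""Iterative patch-thresholding / data-consistency CS reconstruction.

The reconstruction alternates two steps, starting from the combined
zero-filled image:

1. *Patch-similarity thresholding* of the combined coil image. For every
   reference patch on a stride grid, the most similar patches (L2 distance)
   inside a local search window are stacked into a group; an orthonormal
   transform (DCT within each patch, DCT across the group) is applied, small
   coefficients are hard-thresholded, the group is inverted, and overlapping
   patch estimates are averaged. This exploits the low-dimensional structure
   of groups of similar patches, the same principle as self-learning
   block-matching reconstructions.
2. *Data consistency*: the estimate is projected through the coil
   sensitivities to per-coil k-space and the values at sampled lines are
   replaced by the measured data, which keeps the iterate exactly consistent
   with the acquisition at every sampled line.

The threshold decays geometrically across iterations as a fraction of the
current image's maximum magnitude. Everything is deterministic: there is no
randomized grouping, and all arithmetic is double precision.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as _sp_fft

from ._fft import fftc, ifftc
from .phantom import CoilMaps, ImageVolume, KSpaceSet

__all__ = [
    "ReconConfig",
    "zero_filled_recon",
    "combine_coils",
    "patch_threshold",
    "data_consistency",
    "cs_reconstruct",
]

_B1_EPS = 1e-8


@dataclasses.dataclass
class ReconConfig:
    """Knobs of the iterative reconstruction.

    ``threshold_initial``/``threshold_final`` are fractions of the current
    image's maximum magnitude; the per-iteration threshold decays
    geometrically between them. ``patch_mode`` selects full 3D patch grouping
    or the faster per-readout-slice 2D variant.
    """

    n_iterations: int = 10
    threshold_initial: float = 0.1
    threshold_final: float = 0.01
    patch_size: int = 4
    stride: int = 2
    search_window: int = 16
    group_size: int = 8
    transform: str = "dct"
    combine: str = "b1"
    patch_mode: str = "3d"  # "3d" | "slice"

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not (0 < self.threshold_final <= self.threshold_initial <= 1):
            raise ValueError("need 0 < threshold_final <= threshold_initial <= 1")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if self.transform != "dct":
            raise ValueError("only the orthonormal DCT transform is implemented")
        if self.combine not in ("b1", "rss"):
            raise ValueError("combine must be 'b1' or 'rss'")
        if self.patch_mode not in ("3d", "slice"):
            raise ValueError("patch_mode must be '3d' or 'slice'")

    def threshold_schedule(self) -> np.ndarray:
        """Geometric decay from initial to final over ``n_iterations`` steps."""
        n = self.n_iterations
        if n == 0:
            return np.empty(0)
        if n == 1:
            return np.array([self.threshold_initial])
        ratio = (self.threshold_final / self.threshold_initial) ** (1.0 / (n - 1))
        return self.threshold_initial * ratio ** np.arange(n)


def zero_filled_recon(k: KSpaceSet) -> np.ndarray:
    """Per-coil centered inverse FFT of the masked k-space, shape (C, nx, ny, nz)."""
    return ifftc(k.data, axes=(1, 2, 3))


def combine_coils(images: np.ndarray, coils: CoilMaps, mode: str = "b1") -> np.ndarray:
    """Combine per-coil images into one.

    ``b1``: sensitivity-weighted combination ``sum(conj(S_c) x_c) /
    max(sum |S_c|^2, eps)``, which is the least-squares estimate of the
    underlying image and stays complex. ``rss``: root sum of squares
    (magnitude only).
    """
    images = np.asarray(images)
    if images.shape != coils.maps.shape:
        raise ValueError("per-coil images and coil maps shapes do not match")
    if mode == "b1":
        denom = np.maximum((np.abs(coils.maps) ** 2).sum(axis=0), _B1_EPS)
        return (np.conj(coils.maps) * images).sum(axis=0) / denom
    if mode == "rss":
        return np.sqrt((np.abs(images) ** 2).sum(axis=0))
    raise ValueError("mode must be 'b1' or 'rss'")


# ---------------------------------------------------------------------------
# patch grouping and thresholding
# ---------------------------------------------------------------------------


def _box_sum(a: np.ndarray, p: int) -> np.ndarray:
    """Sum over p-cubes anchored at each valid corner, via running sums."""
    out = a
    for ax in range(a.ndim):
        c = np.cumsum(out, axis=ax)
        lead = [slice(None)] * out.ndim
        lag = [slice(None)] * out.ndim
        lead[ax] = slice(p - 1, None)
        lag[ax] = slice(None, -p)
        first = c[tuple(lead)]
        shifted = np.zeros_like(first)
        idx_rest = [slice(None)] * out.ndim
        idx_rest[ax] = slice(1, None)
        shifted[tuple(idx_rest)] = c[tuple(lag)]
        out = first - shifted
    return out


def _ref_positions(valid: int, stride: int) -> np.ndarray:
    """Stride grid of reference-patch corners, always including the last corner."""
    pos = list(range(0, valid, stride))
    if pos[-1] != valid - 1:
        pos.append(valid - 1)
    return np.asarray(pos)


def _dctn(a: np.ndarray, axes, inverse: bool = False):
    fn = _sp_fft.idctn if inverse else _sp_fft.dctn
    if np.iscomplexobj(a):
        return fn(a.real, axes=axes, norm="ortho") + 1j * fn(
            a.imag, axes=axes, norm="ortho"
        )
    return fn(a, axes=axes, norm="ortho")


def _patch_threshold_nd(img: np.ndarray, cfg: ReconConfig, tau_abs: float) -> np.ndarray:
    """Group-and-threshold one 2D or 3D array; returns the aggregated estimate."""
    ndim = img.ndim
    p = cfg.patch_size
    if any(s < p for s in img.shape):
        raise ValueError("patch larger than image")
    valid = tuple(s - p + 1 for s in img.shape)

    w2 = cfg.search_window // 2
    off_1d = np.arange(-w2, w2 + 1, cfg.stride)
    offsets = np.stack(
        [g.ravel() for g in np.meshgrid(*([off_1d] * ndim), indexing="ij")], axis=1
    )
    zero_idx = int(np.flatnonzero((offsets == 0).all(axis=1))[0])

    # squared L2 distance between the patch at every corner and the patch at
    # corner + offset, computed as a box sum of squared differences
    n_off = len(offsets)
    dist = np.full((n_off,) + valid, np.inf)
    for oi, off in enumerate(offsets):
        if oi == zero_idx:
            continue
        sl_a, sl_b, sl_d = [], [], []
        ok = True
        for ax, o in enumerate(off):
            n = img.shape[ax]
            lo, hi = max(0, -o), min(n, n - o)
            if hi - lo < p:
                ok = False
                break
            sl_a.append(slice(lo, hi))
            sl_b.append(slice(lo + o, hi + o))
            sl_d.append(slice(lo, hi - p + 1))
        if not ok:
            continue
        e = np.abs(img[tuple(sl_a)] - img[tuple(sl_b)]) ** 2
        dist[(oi,) + tuple(sl_d)] = _box_sum(e, p)

    refs_1d = [_ref_positions(v, cfg.stride) for v in valid]
    ref_grid = np.meshgrid(*refs_1d, indexing="ij")
    refs = np.stack([g.ravel() for g in ref_grid], axis=1)  # (n_ref, ndim)
    n_ref = len(refs)

    d_ref = dist[(slice(None),) + tuple(refs.T)]  # (n_off, n_ref)
    g = min(cfg.group_size, n_off)
    take = g - 1
    if take > 0:
        sel = np.argpartition(d_ref, kth=min(take - 1, n_off - 1), axis=0)[:take]
        sel_d = np.take_along_axis(d_ref, sel, axis=0)
        # replace unusable (inf-distance) candidates with the reference itself
        sel = np.where(np.isfinite(sel_d), sel, zero_idx)
        sel = np.concatenate([np.full((1, n_ref), zero_idx), sel], axis=0)
    else:
        sel = np.full((1, n_ref), zero_idx)

    member = refs[None, :, :] + offsets[sel]  # (g, n_ref, ndim)
    patches = sliding_window_view(img, (p,) * ndim)
    groups = patches[tuple(member[..., ax] for ax in range(ndim))]  # (g, n_ref, p, ...)

    patch_axes = tuple(range(2, 2 + ndim))
    coef = _dctn(groups, axes=patch_axes)
    coef = _dctn(coef, axes=(0,))
    coef[np.abs(coef) < tau_abs] = 0.0
    rec = _dctn(coef, axes=(0,), inverse=True)
    rec = _dctn(rec, axes=patch_axes, inverse=True)

    acc = np.zeros(img.shape, dtype=rec.dtype)
    wacc = np.zeros(img.shape)
    corner_idx = tuple(
        member[..., ax][..., None, None] if ndim == 2 else member[..., ax][..., None, None, None]
        for ax in range(ndim)
    )
    patch_offsets = np.meshgrid(*([np.arange(p)] * ndim), indexing="ij")
    idx = tuple(
        corner_idx[ax] + patch_offsets[ax][(None, None) + (Ellipsis,)]
        for ax in range(ndim)
    )
    np.add.at(acc, idx, rec)
    np.add.at(wacc, idx, 1.0)
    return acc / np.maximum(wacc, 1e-30)


def patch_threshold(
    image: np.ndarray, config: ReconConfig, tau: float | None = None
) -> np.ndarray:
    """Hard-threshold the image in the grouped-patch transform domain.

    ``tau`` is a fraction of the image's maximum magnitude (defaults to the
    schedule's initial value). In ``slice`` mode the grouping runs per
    readout slice (axis 0) with 2D patches.
    """
    image = np.asarray(image)
    if tau is None:
        tau = config.threshold_initial
    p = config.patch_size
    spatial = image.shape[1:] if (config.patch_mode == "slice" and image.ndim == 3) else image.shape
    if any(s < p for s in spatial):
        raise ValueError("patch larger than image")
    tau_abs = tau * float(np.abs(image).max())
    if tau_abs == 0:
        return np.array(image, copy=True)
    if config.patch_mode == "slice" and image.ndim == 3:
        out = np.empty_like(image)
        for i in range(image.shape[0]):
            out[i] = _patch_threshold_nd(image[i], config, tau_abs)
        return out
    return _patch_threshold_nd(image, config, tau_abs)


# ---------------------------------------------------------------------------
# data consistency and the CS loop
# ---------------------------------------------------------------------------


def _dc_percoil(image: np.ndarray, k: KSpaceSet, coils: CoilMaps) -> np.ndarray:
    """Project ``image`` through the coils, restore measured lines, invert.

    Returns per-coil images whose k-space equals the measured data exactly at
    every sampled line.
    """
    kk = fftc(image[None, ...] * coils.maps, axes=(1, 2, 3))
    m = k.pattern.mask[None, None, :, :]
    kk = np.where(m, k.data, kk)
    return ifftc(kk, axes=(1, 2, 3))


def data_consistency(image: np.ndarray, k: KSpaceSet, coils: CoilMaps) -> np.ndarray:
    """One data-consistency projection of a combined image.

    The image is expanded through the coil maps to per-coil k-space, the
    values at sampled lines are replaced by the measured data, and the result
    is transformed back and recombined (B1-weighted).
    """
    image = np.asarray(image)
    if image.shape != k.vol_shape:
        raise ValueError("image and k-space shapes do not match")
    return combine_coils(_dc_percoil(image, k, coils), coils, mode="b1")


def cs_reconstruct(
    k: KSpaceSet,
    coils: CoilMaps,
    config: ReconConfig | None = None,
    magnitude: bool = True,
) -> ImageVolume:
    """Iterative thresholding / data-consistency reconstruction.

    Starts from the combined zero-filled image and alternates
    ``patch_threshold`` with the data-consistency projection for
    ``n_iterations`` with the geometric threshold schedule; with zero
    iterations this is exactly the combined zero-filled reconstruction.
    Returns the magnitude image unless ``magnitude=False``.
    """
    if config is None:
        config = ReconConfig()
    if coils.vol_shape != k.vol_shape:
        raise ValueError("coil maps and k-space shapes do not match")
    x = combine_coils(zero_filled_recon(k), coils, mode="b1")
    for tau in config.threshold_schedule():
        x = patch_threshold(x, config, tau=float(tau))
        x = combine_coils(_dc_percoil(x, k, coils), coils, mode="b1")
    data = np.abs(x) if magnitude else x
    return ImageVolume(data, spacing_mm=k.spacing_mm, origin_mm=k.origin_mm)
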