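"""Image preprocessing for habitat analysis.

The stages run in a fixed order on each (volume, region) pair:
intensity normalization -> mask erosion -> ROI cropping -> local entropy
-> voxel-wise fusion.  The fused image, which adds a local texture-
complexity term to the normalized intensities, is the input to
superpixel segmentation.  Everything in this module is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class DegenerateInputError(ValueError):
    """Raised when an input has no usable signal (e.g. constant ROI)."""


@dataclass
class Volume3D:
    """One channel's 3D scalar field.

    Parameters
    ----------
    values : (nx, ny, nz) float array
    spacing : voxel spacing in mm
    channel : role of the sequence, one of ``{"T1", "T1C", "T2"}``
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = "T1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume3D.values must be 3-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume3D.values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class RegionMask:
    """Binary 3D mask for one region of interest (GTVp or MLN)."""

    values: np.ndarray
    region: str = "GTVp"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("RegionMask.values must be 3-dimensional")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class FusedImage:
    """Entropy-enhanced image on the cropped ROI grid.

    ``crop_offset`` records where the cropped grid starts in the original
    volume so that habitat maps can be mapped back to original coordinates.
    """

    values: np.ndarray
    crop_offset: tuple[int, int, int] = (0, 0, 0)
    source_channel: str = "T1"
    region: str = "GTVp"


@dataclass
class PreprocessParams:
    """Tunable preprocessing settings (defaults used throughout)."""

    erosion_radius: int = 1
    crop_margin: int = 2
    entropy_window_radius: int = 2
    entropy_bins: int = 32


def normalize_intensity(vol: Volume3D, mask: RegionMask) -> Volume3D:
    """Z-score the volume within the mask; zero elsewhere.

    Uses the population standard deviation so that e.g. in-mask values
    {1, 2, 3} map exactly to {-1.2247, 0, 1.2247}.
    """
    m = mask.values
    if not m.any():
        raise ValueError(f"empty mask for region {mask.region}")
    inside = vol.values[m]
    mu = inside.mean()
    sd = inside.std()  # population SD (ddof=0)
    if sd == 0:
        raise DegenerateInputError(
            f"constant intensities inside region {mask.region} "
            f"(channel {vol.channel}): cannot normalize"
        )
    out = np.zeros_like(vol.values, dtype=float)
    out[m] = (inside - mu) / sd
    return replace(vol, values=out)


def _ball(radius: int) -> np.ndarray:
    """Euclidean ball structuring element (radius 1 = 6-connected cross)."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return dx * dx + dy * dy + dz * dz <= r * r


def erode_mask(mask: RegionMask, radius_voxels: int = 1) -> RegionMask:
    """Binary erosion with a ball element; falls back to the original
    mask (with a warning) if erosion would empty it."""
    if radius_voxels < 0:
        raise ValueError("erosion radius must be >= 0")
    if radius_voxels == 0:
        return replace(mask, values=mask.values.copy())
    eroded = ndimage.binary_erosion(mask.values, structure=_ball(radius_voxels))
    if not eroded.any():
        warnings.warn(
            f"erosion with radius {radius_voxels} emptied region "
            f"{mask.region}; keeping the un-eroded mask",
            stacklevel=2,
        )
        return replace(mask, values=mask.values.copy())
    return replace(mask, values=eroded)


def crop_to_roi(
    vol: Volume3D, mask: RegionMask, margin_voxels: int = 2
) -> tuple[Volume3D, RegionMask, tuple[int, int, int]]:
    """Crop volume and mask to the mask's bounding box plus a margin.

    Returns the cropped pair and the 0-based offset of the crop within
    the original grid.
    """
    m = mask.values
    if not m.any():
        raise ValueError(f"empty mask for region {mask.region}")
    lo, hi = [], []
    for axis in range(3):
        proj = m.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        lo.append(max(int(idx[0]) - margin_voxels, 0))
        hi.append(min(int(idx[-1]) + margin_voxels + 1, m.shape[axis]))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return (
        replace(vol, values=vol.values[sl].copy()),
        replace(mask, values=m[sl].copy()),
        (lo[0], lo[1], lo[2]),
    )


def uncrop_labels(
    labels: np.ndarray,
    crop_offset: tuple[int, int, int],
    full_shape: tuple[int, int, int],
) -> np.ndarray:
    """Place a cropped integer label field back onto the original grid."""
    out = np.zeros(full_shape, dtype=labels.dtype)
    sl = tuple(
        slice(o, o + s) for o, s in zip(crop_offset, labels.shape)
    )
    out[sl] = labels
    return out


def local_entropy(
    vol: Volume3D,
    mask: RegionMask,
    window_radius: int = 2,
    n_bins: int = 32,
) -> Volume3D:
    """Local Shannon entropy (bits) of the quantized intensity histogram.

    At each in-mask voxel the intensities of the surrounding cubic window
    (restricted to in-mask voxels) are binned into ``n_bins`` equal-width
    bins over the in-mask intensity range, and the entropy of that
    histogram is returned.  Values lie in ``[0, log2(n_bins)]``; voxels
    outside the mask get 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    m = mask.values
    if not m.any():
        raise ValueError(f"empty mask for region {mask.region}")
    v = vol.values
    inside = v[m]
    vmin, vmax = float(inside.min()), float(inside.max())
    if vmax == vmin:
        return replace(vol, values=np.zeros_like(v, dtype=float))
    # quantize to bin indices 0..n_bins-1
    q = np.floor((v - vmin) / (vmax - vmin) * n_bins).astype(np.int64)
    np.clip(q, 0, n_bins - 1, out=q)
    size = 2 * window_radius + 1
    nwin = size**3

    def window_count(indicator: np.ndarray) -> np.ndarray:
        s = ndimage.uniform_filter(
            indicator.astype(np.float64), size=size, mode="constant", cval=0.0
        )
        return np.rint(s * nwin)

    total = window_count(m)
    entropy = np.zeros_like(v, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for b in range(n_bins):
            cnt = window_count(m & (q == b))
            p = np.where(total > 0, cnt / np.maximum(total, 1), 0.0)
            term = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
            entropy += term
    entropy[~m] = 0.0
    np.clip(entropy, 0.0, np.log2(n_bins), out=entropy)
    return replace(vol, values=entropy)


def fuse(
    norm_vol: Volume3D,
    entropy_map: Volume3D,
    mask: RegionMask | None = None,
    crop_offset: tuple[int, int, int] = (0, 0, 0),
    region: str = "GTVp",
) -> FusedImage:
    """Voxel-wise sum of the normalized image and its local entropy map."""
    if norm_vol.values.shape != entropy_map.values.shape:
        raise ValueError("normalized volume and entropy map shapes differ")
    fused = norm_vol.values + entropy_map.values
    if mask is not None:
        if mask.values.shape != fused.shape:
            raise ValueError("mask shape differs from volume shape")
        fused = np.where(mask.values, fused, 0.0)
        region = mask.region
    return FusedImage(
        values=fused,
        crop_offset=crop_offset,
        source_channel=norm_vol.channel,
        region=region,
    )


def preprocess_region(
    vol: Volume3D,
    mask: RegionMask,
    params: PreprocessParams | None = None,
) -> tuple[FusedImage, RegionMask]:
    """Run the full preprocessing chain for one (channel, region) pair.

    Returns the entropy-fused image on the cropped grid together with the
    cropped, eroded mask (the grid both live on is recorded in
    ``FusedImage.crop_offset``).
    """
    p = params or PreprocessParams()
    norm = normalize_intensity(vol, mask)
    eroded = erode_mask(mask, p.erosion_radius)
    norm_c, mask_c, offset = crop_to_roi(norm, eroded, p.crop_margin)
    ent = local_entropy(norm_c, mask_c, p.entropy_window_radius, p.entropy_bins)
    fused = fuse(norm_c, ent, mask=mask_c, crop_offset=offset)
    return fused, mask_c
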