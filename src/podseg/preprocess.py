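"""Intensity standardization, ROI cropping and label-preserving augmentation.

Multi-modal volumes carry M co-registered channels (default four, emulating
FLAIR / T1 / T1-CE / T2).  Standardization is the per-channel z-score
``z = (x - mu) / sigma`` with the population standard deviation; cropping
centers a fixed-size window on the foreground bounding box, padding with
zeros where the volume is smaller than the window; augmentation applies the
same seeded spatial transform to image (interpolated) and labels (nearest
neighbor), so no new labels can appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MultiModalVolume",
    "DEFAULT_MODALITIES",
    "zscore",
    "crop_roi",
    "augment",
]

DEFAULT_MODALITIES = ("FLAIR", "T1", "T1CE", "T2")


@dataclass
class MultiModalVolume:
    """Channels-first multi-modal image: ``M x (spatial...)`` plus an affine."""

    channels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality_names: tuple[str, ...] = DEFAULT_MODALITIES

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim not in (3, 4):
            raise ValueError(
                "channels must be M x H x W (2-D) or M x D x H x W (3-D), "
                f"got shape {self.channels.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4 x 4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if len(self.modality_names) != self.channels.shape[0]:
            self.modality_names = tuple(
                f"mod{i}" for i in range(self.channels.shape[0])
            )

    @property
    def n_modalities(self) -> int:
        return self.channels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.channels.shape[1:]


def zscore(
    vol: MultiModalVolume,
    per_modality: bool = True,
    foreground_only: bool = False,
) -> MultiModalVolume:
    """Standardize intensities: subtract the mean, divide by the (population) std.

    With ``foreground_only`` the statistics come from nonzero voxels only (a
    crude brain mask for zero-filled backgrounds); standardization is still
    applied everywhere.  A constant channel has sigma = 0 and is rejected with
    the offending modality named.
    """
    data = vol.channels
    out = np.empty_like(data, dtype=float)
    if per_modality:
        for i, name in enumerate(vol.modality_names):
            chan = data[i]
            domain = chan[chan != 0] if foreground_only else chan
            if domain.size == 0:
                raise ValueError(f"modality {name!r}: empty standardization domain")
            mu, sigma = float(domain.mean()), float(domain.std())
            if sigma == 0:
                raise ValueError(
                    f"modality {name!r} is constant (sigma = 0); cannot standardize"
                )
            out[i] = (chan - mu) / sigma
    else:
        domain = data[data != 0] if foreground_only else data
        mu, sigma = float(domain.mean()), float(domain.std())
        if sigma == 0:
            raise ValueError("volume is constant (sigma = 0); cannot standardize")
        out = (data - mu) / sigma
    return MultiModalVolume(out, vol.affine.copy(), vol.modality_names)


def _crop_axis(center: int, extent: int, target: int) -> tuple[slice, slice]:
    """Source slice into the volume and destination slice into the window."""
    start = center - target // 2
    src0, src1 = max(start, 0), min(start + target, extent)
    dst0 = src0 - start
    return slice(src0, src1), slice(dst0, dst0 + (src1 - src0))


def crop_roi(
    vol: MultiModalVolume,
    labels: np.ndarray,
    size: Sequence[int] = (160, 160, 160),
    center: Sequence[int] | None = None,
) -> tuple[MultiModalVolume, np.ndarray]:
    """Crop a fixed-size window centered on the labeled foreground.

    The window is centered on the center of the foreground bounding box
    (rounded down for even extents), clipped to the volume and zero-padded
    where the volume is smaller than the window, so the output always has
    exactly the requested size and all foreground is retained whenever it
    fits.  An explicit ``center`` overrides the bounding-box rule (required
    when the label map is empty).
    """
    labels = np.asarray(labels)
    spatial = vol.spatial_shape
    size = tuple(int(s) for s in size)[: len(spatial)]
    if len(size) != len(spatial):
        raise ValueError("size must match the number of spatial axes")
    if center is None:
        fg = np.argwhere(labels != 0)
        if fg.size == 0:
            raise ValueError(
                "label map has no foreground; pass an explicit crop center"
            )
        center = tuple(
            (int(fg[:, a].min()) + int(fg[:, a].max())) // 2
            for a in range(labels.ndim)
        )
    center = tuple(int(c) for c in center)

    out_img = np.zeros((vol.n_modalities, *size), dtype=float)
    out_lab = np.zeros(size, dtype=labels.dtype)
    src, dst = [], []
    for c, extent, target in zip(center, spatial, size):
        s, d = _crop_axis(c, extent, target)
        src.append(s)
        dst.append(d)
    out_img[(slice(None), *dst)] = vol.channels[(slice(None), *src)]
    out_lab[tuple(dst)] = labels[tuple(src)]

    # carry the affine: translate the origin to the window corner
    affine = vol.affine.copy()
    corner = np.zeros(3)
    starts = [c - t // 2 for c, t in zip(center, size)]
    corner[: len(starts)] = starts
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ corner
    return MultiModalVolume(out_img, affine, vol.modality_names), out_lab


def _rot90(img: np.ndarray, k: int, axes: tuple[int, int]) -> np.ndarray:
    return np.rot90(img, k=k, axes=axes)


def augment(
    vol: MultiModalVolume,
    labels: np.ndarray,
    seed: int,
    ops: Sequence[str] = ("rotate", "flip", "scale"),
    free_rotation: bool = False,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> tuple[MultiModalVolume, np.ndarray]:
    """Seeded spatial augmentation applied identically to image and labels.

    Default rotations are axis-aligned 90-degree multiples (exact, no
    resampling); ``free_rotation=True`` enables arbitrary-angle rotation with
    linear interpolation for the image and nearest-neighbor for the labels.
    Scaling resamples about the center and crops/pads back to the original
    shape.  The label set after augmentation is always a subset of the input
    label set, and the same seed reproduces the output bit for bit.
    """
    if any(f <= 0 for f in scale_range):
        raise ValueError("scale factors must be > 0")
    rng = np.random.default_rng(seed)
    img = vol.channels.copy()
    lab = np.asarray(labels).copy()
    ndim = lab.ndim
    spatial_axes = list(range(ndim))

    if "rotate" in ops:
        ax = tuple(rng.choice(spatial_axes, size=2, replace=False))
        if free_rotation:
            angle = float(rng.uniform(0, 360))
            img = np.stack(
                [
                    ndimage.rotate(
                        ch, angle, axes=ax, reshape=False, order=1, mode="constant"
                    )
                    for ch in img
                ]
            )
            lab = ndimage.rotate(
                lab, angle, axes=ax, reshape=False, order=0, mode="constant"
            )
        else:
            k = int(rng.integers(0, 4))
            img = np.stack([_rot90(ch, k, ax) for ch in img])
            lab = _rot90(lab, k, ax)

    if "flip" in ops:
        for axis in spatial_axes:
            if rng.random() < 0.5:
                img = np.flip(img, axis=axis + 1)
                lab = np.flip(lab, axis=axis)

    if "scale" in ops:
        factor = float(rng.uniform(*scale_range))
        if factor != 1.0:
            orig_shape = lab.shape
            img = np.stack(
                [ndimage.zoom(ch, factor, order=1, mode="constant") for ch in img]
            )
            lab = ndimage.zoom(lab, factor, order=0, mode="constant")
            vol_scaled = MultiModalVolume(img, vol.affine, vol.modality_names)
            center = tuple(s // 2 for s in lab.shape)
            vol_c, lab = crop_roi(vol_scaled, lab, orig_shape, center=center)
            img = vol_c.channels

    return (
        MultiModalVolume(np.ascontiguousarray(img), vol.affine.copy(), vol.modality_names),
        np.ascontiguousarray(lab),
    )
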