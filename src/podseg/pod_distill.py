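"""Pooled-output distillation (POD) embeddings and the local POD loss.

A feature map of shape ``H x W x C`` is embedded by concatenating its
width-averaged slices (one ``C``-vector per row) with its height-averaged
slices (one ``C``-vector per column).  *Local* POD repeats this on a grid of
``s x s`` sub-regions for every scale ``s`` in a configured list, preserving
short-range spatial statistics alongside the global ones.  The distillation
loss between a frozen old model and the model being trained is the squared
Euclidean distance between their local POD embeddings, averaged over the
tapped layers.

Embedding order (public contract)
---------------------------------
Within one POD embedding the width-pooled block comes first, then the
height-pooled block; each block is flattened spatial-index major, channel
minor.  Sub-regions are concatenated in row-major order, and scales in the
order they are listed.  For ``scales=[1]`` the local embedding equals the
plain POD embedding exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureMap",
    "PODEmbedding",
    "LocalPODEmbedding",
    "pod_embed",
    "local_pod_embed",
    "local_pod_embedding_length",
    "pod_loss",
    "DEFAULT_SCALES",
]

#: Default sub-region scales for local POD: global, 2x2 and 4x4 grids.
DEFAULT_SCALES: tuple[int, ...] = (1, 2, 4)


@dataclass(frozen=True)
class FeatureMap:
    """One layer's activations, shape ``H x W x C``, all values finite."""

    values: np.ndarray
    layer_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ValueError(
                f"feature map must be H x W x C, got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError(f"feature map axes must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature map contains non-finite values")
        if self.layer_index < 0:
            raise ValueError("layer_index must be >= 0")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PODEmbedding:
    """Flat POD embedding of length ``(H + W) * C``."""

    vector: np.ndarray
    source_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        h, w, c = self.source_shape
        if self.vector.shape != ((h + w) * c,):
            raise ValueError(
                f"embedding length {self.vector.shape} != {(h + w) * c}"
            )


@dataclass(frozen=True)
class LocalPODEmbedding:
    """Concatenated per-scale, per-region POD vectors.

    Length is ``C * sum_s s * (H + W)``: each of the ``s**2`` regions at scale
    ``s`` contributes about ``(H/s + W/s) * C`` values.
    """

    vector: np.ndarray
    scales: tuple[int, ...]
    source_shape: tuple[int, int, int]
    region_lengths: tuple[int, ...] = field(default=(), repr=False)


def _as_feature_array(x: FeatureMap | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureMap):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected H x W x C array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map contains non-finite values")
    return arr


def pod_embed(x: FeatureMap | np.ndarray) -> PODEmbedding:
    """Embed ``x`` (H x W x C) as ``[width-pooled rows || height-pooled cols]``.

    The width-pooled block holds, for each row ``h``, the mean over the width
    axis (an ``H x C`` array); the height-pooled block holds, for each column
    ``w``, the mean over the height axis (``W x C``).  Both are flattened
    spatial-major, channel-minor, and concatenated in that order.
    """
    arr = _as_feature_array(x)
    width_pooled = arr.mean(axis=1)  # H x C
    height_pooled = arr.mean(axis=0)  # W x C
    vec = np.concatenate([width_pooled.ravel(), height_pooled.ravel()])
    return PODEmbedding(vector=vec, source_shape=arr.shape)


def _region_bounds(n: int, s: int) -> list[tuple[int, int]]:
    # half-open floor boundaries; regions may differ by one row/column when
    # s does not divide n
    return [(i * n // s, (i + 1) * n // s) for i in range(s)]


def local_pod_embedding_length(
    shape: tuple[int, int, int], scales: Sequence[int]
) -> int:
    """Exact vector length: ``C * sum_s sum_regions (h_i + w_j)``."""
    h, w, c = shape
    total = 0
    for s in scales:
        hs = [b - a for a, b in _region_bounds(h, s)]
        ws = [b - a for a, b in _region_bounds(w, s)]
        total += c * sum(hi + wj for hi in hs for wj in ws)
    return total


def local_pod_embed(
    x: FeatureMap | np.ndarray, scales: Sequence[int] = DEFAULT_SCALES
) -> LocalPODEmbedding:
    """Multi-scale local POD: POD of every ``s x s`` tile, concatenated.

    For each scale ``s`` the spatial grid is split into ``s x s`` tiles with
    half-open boundaries ``floor(i*H/s) .. floor((i+1)*H/s)``; :func:`pod_embed`
    is applied to each tile and the per-tile vectors are concatenated in
    row-major tile order, then per-scale vectors in the order of ``scales``.
    """
    arr = _as_feature_array(x)
    h, w, _c = arr.shape
    scales = tuple(int(s) for s in scales)
    if len(scales) == 0:
        raise ValueError("scales must be a non-empty list of integers >= 1")
    pieces: list[np.ndarray] = []
    lengths: list[int] = []
    for s in scales:
        if s < 1:
            raise ValueError(f"scale {s} must be >= 1")
        if s > min(h, w):
            raise ValueError(
                f"scale {s} exceeds min spatial extent {min(h, w)}"
            )
        for h0, h1 in _region_bounds(h, s):
            for w0, w1 in _region_bounds(w, s):
                sub = arr[h0:h1, w0:w1, :]
                vec = pod_embed(sub).vector
                pieces.append(vec)
                lengths.append(vec.size)
    return LocalPODEmbedding(
        vector=np.concatenate(pieces),
        scales=scales,
        source_shape=arr.shape,
        region_lengths=tuple(lengths),
    )


def pod_loss(
    old_feats: Sequence[FeatureMap | np.ndarray],
    new_feats: Sequence[FeatureMap | np.ndarray],
    scales: Sequence[int] = DEFAULT_SCALES,
) -> float:
    """Distillation loss ``(1/L) * sum_l ||Psi(f_l_new) - Psi(f_l_old)||^2``.

    ``Psi`` is the local POD embedding with the given scales; the norm is the
    squared Euclidean norm of the flattened embedding difference; the sum runs
    over paired layers and is averaged by the number of layers ``L``.
    """
    if len(old_feats) != len(new_feats):
        raise ValueError(
            f"layer count mismatch: {len(old_feats)} old vs {len(new_feats)} new"
        )
    if len(old_feats) == 0:
        raise ValueError("need at least one layer pair")
    total = 0.0
    for layer, (fo, fn) in enumerate(zip(old_feats, new_feats)):
        ao, an = _as_feature_array(fo), _as_feature_array(fn)
        if ao.shape != an.shape:
            raise ValueError(
                f"layer {layer}: shape mismatch {ao.shape} vs {an.shape}"
            )
        diff = local_pod_embed(an, scales).vector - local_pod_embed(ao, scales).vector
        total += float(diff @ diff)
    return total / len(old_feats)
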