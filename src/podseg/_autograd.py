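"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the desk-scale segmentation network needs:
2-D convolution (strided, dilated, grouped-depthwise), ReLU, residual add,
channel concatenation, nearest-neighbor upsampling, a weighted masked
softmax cross-entropy head, and a local-POD distillation loss node whose
backward pass is the adjoint of the (linear) pooling embedding.

Arrays are channels-first ``N x C x H x W`` float32.  The graph is built
eagerly; ``backward`` runs a topological sweep.  Everything is deterministic.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "conv2d", "depthwise_conv2d", "relu", "add", "concat",
           "upsample_nearest", "softmax", "weighted_ce_loss", "local_pod_pair_loss",
           "add_losses"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse sweep from this (scalar) node."""
        if self.data.size != 1:
            raise ValueError("backward() must start from a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        # iterative post-order to avoid recursion limits on deep graphs
        work: list[tuple[Tensor, bool]] = [(self, False)]
        while work:
            n, processed = work.pop()
            if processed:
                topo.append(n)
                continue
            if id(n) in seen:
                continue
            seen.add(id(n))
            work.append((n, True))
            for p in n.parents:
                if p.requires_grad and id(p) not in seen:
                    work.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _im2col(
    xp: np.ndarray, kh: int, kw: int, oh: int, ow: int, stride: int, dil: int
) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[
                :, :,
                i * dil : i * dil + (oh - 1) * stride + 1 : stride,
                j * dil : j * dil + (ow - 1) * stride + 1 : stride,
            ]
    return cols


def _col2im(
    dcols: np.ndarray, xp_shape: tuple[int, ...], stride: int, dil: int
) -> np.ndarray:
    n, c, kh, kw, oh, ow = dcols.shape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[
                :, :,
                i * dil : i * dil + (oh - 1) * stride + 1 : stride,
                j * dil : j * dil + (ow - 1) * stride + 1 : stride,
            ] += dcols[:, :, i, j]
    return dxp


def conv2d(
    x: Tensor, w: Tensor, b: Tensor | None = None,
    stride: int = 1, padding: int = 0, dilation: int = 1,
) -> Tensor:
    """Standard 2-D convolution (cross-correlation), NCHW x (OC,C,KH,KW)."""
    n, c, h, wid = x.shape
    oc, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (h + 2 * padding - dil_extent(kh, dilation)) // stride + 1
    ow = (wid + 2 * padding - dil_extent(kw, dilation)) // stride + 1
    cols = _im2col(xp, kh, kw, oh, ow, stride, dilation)
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    w2 = w.data.reshape(oc, c * kh * kw)
    out = np.matmul(w2, cols2).reshape(n, oc, oh, ow)
    if b is not None:
        out += b.data.reshape(1, oc, 1, 1)

    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(n, oc, oh * ow)
        if w.requires_grad:
            dw = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols2 = np.matmul(w2.T, g2)
            dcols = dcols2.reshape(n, c, kh, kw, oh, ow)
            dxp = _col2im(dcols, xp.shape, stride, dilation)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor(out, parents, backward)


def dil_extent(k: int, dil: int) -> int:
    return dil * (k - 1) + 1


def depthwise_conv2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 1
) -> Tensor:
    """Depthwise 3x3 (or KxK) convolution: kernel shape (C, KH, KW), stride 1."""
    n, c, h, wid = x.shape
    cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"depthwise kernel channels {cw} != input channels {c}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = h + 2 * padding - kh + 1
    ow = wid + 2 * padding - kw + 1
    cols = _im2col(xp, kh, kw, oh, ow, 1, 1)  # N,C,KH,KW,OH,OW
    out = np.einsum("ncijhw,cij->nchw", cols, w.data, optimize=True)
    if b is not None:
        out += b.data.reshape(1, c, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g: np.ndarray) -> None:
        if w.requires_grad:
            w._accumulate(np.einsum("ncijhw,nchw->cij", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("nchw,cij->ncijhw", g, w.data, optimize=True)
            dxp = _col2im(dcols, xp.shape, 1, 1)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor(out, parents, backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization over channel groups (batch-size independent)."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    xg = x.data.reshape(n, groups, -1)
    mean = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mean) * inv_std).reshape(n, c, h, w)
    out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gamma.data.reshape(1, c, 1, 1)).reshape(n, groups, -1)
            xh = xhat.reshape(n, groups, -1)
            m1 = dxhat.mean(axis=2, keepdims=True)
            m2 = (dxhat * xh).mean(axis=2, keepdims=True)
            dx = (dxhat - m1 - xh * m2) * inv_std
            x._accumulate(dx.reshape(n, c, h, w))

    return Tensor(out, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add shape mismatch {a.shape} vs {b.shape}")

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(a.data + b.data, (a, b), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(
                g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            )

    return Tensor(out, (x,), backward)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_ce_loss(
    logits: Tensor, onehot: np.ndarray, pixel_weight: np.ndarray
) -> Tensor:
    """``-sum_{n,h,w} weight * log softmax(logits)[target]``.

    ``onehot`` is N x K x H x W with all-zero columns for ignored pixels;
    ``pixel_weight`` is N x H x W and must already be zero wherever the
    target is ignored.  The caller folds v / N_eff / batch into the weights.
    """
    p = softmax(logits.data, axis=1)
    labeled = onehot.sum(axis=1) > 0
    w = pixel_weight * labeled
    p_t = np.clip((p * onehot).sum(axis=1), 1e-12, None)
    loss = -(w * np.log(p_t)).sum()

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            dlogits = (p - onehot) * w[:, None, :, :]
            logits._accumulate(g * dlogits)

    return Tensor(np.float32(loss), (logits,), backward)


def _pod_blocks(shape: tuple[int, int], scales: Sequence[int]):
    """Yield (h0,h1,w0,w1) region bounds in embedding order for given scales."""
    h, w = shape
    for s in scales:
        hb = [(i * h // s, (i + 1) * h // s) for i in range(s)]
        wb = [(j * w // s, (j + 1) * w // s) for j in range(s)]
        for h0, h1 in hb:
            for w0, w1 in wb:
                yield h0, h1, w0, w1


def batched_local_pod_embed(feats: np.ndarray, scales: Sequence[int]) -> np.ndarray:
    """Local POD embedding of an N x C x H x W batch -> N x E.

    Per region: width-pooled block (spatial-major, channel-minor) then
    height-pooled block, matching :func:`podseg.pod_distill.local_pod_embed`.
    """
    n, c, h, w = feats.shape
    pieces = []
    for h0, h1, w0, w1 in _pod_blocks((h, w), scales):
        sub = feats[:, :, h0:h1, w0:w1]
        wp = sub.mean(axis=3).transpose(0, 2, 1).reshape(n, -1)  # N,(h*c)
        hp = sub.mean(axis=2).transpose(0, 2, 1).reshape(n, -1)  # N,(w*c)
        pieces.append(wp)
        pieces.append(hp)
    return np.concatenate(pieces, axis=1)


def local_pod_pair_loss(
    new_feat: Tensor, old_feat: np.ndarray, scales: Sequence[int]
) -> Tensor:
    """Mean over batch of ``||Psi(new) - Psi(old)||^2`` for one layer pair.

    The backward pass applies the adjoint of the region-mean embedding to
    ``2 (Psi(new) - Psi(old)) / N``.
    """
    n, c, h, w = new_feat.shape
    emb_new = batched_local_pod_embed(new_feat.data, scales)
    emb_old = batched_local_pod_embed(np.asarray(old_feat, np.float32), scales)
    diff = emb_new - emb_old
    loss = float((diff * diff).sum() / n)

    def backward(g: np.ndarray) -> None:
        if not new_feat.requires_grad:
            return
        dx = np.zeros_like(new_feat.data)
        coeff = (2.0 / n) * diff * g  # N x E
        offset = 0
        for h0, h1, w0, w1 in _pod_blocks((h, w), scales):
            hh, ww = h1 - h0, w1 - w0
            dwp = coeff[:, offset : offset + hh * c].reshape(n, hh, c)
            offset += hh * c
            dhp = coeff[:, offset : offset + ww * c].reshape(n, ww, c)
            offset += ww * c
            # adjoint of mean over width / height: spread uniformly
            dx[:, :, h0:h1, w0:w1] += dwp.transpose(0, 2, 1)[:, :, :, None] / ww
            dx[:, :, h0:h1, w0:w1] += dhp.transpose(0, 2, 1)[:, :, None, :] / hh
        new_feat._accumulate(dx)

    return Tensor(np.float32(loss), (new_feat,), backward)


def add_losses(terms: Sequence[tuple[Tensor, float]]) -> Tensor:
    """Weighted sum of scalar loss nodes."""
    total = sum(float(t.data) * w for t, w in terms)

    def backward(g: np.ndarray) -> None:
        for t, w in terms:
            if t.requires_grad:
                t._accumulate(g * np.float32(w))

    return Tensor(np.float32(total), tuple(t for t, _ in terms), backward)
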