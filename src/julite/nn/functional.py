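"""Functional ops: grouped 2-D convolution (im2col + GEMM), activations,
pooling and the cross-entropy objective."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _as_tensor


def hswish(x):
    """Hard-swish activation ``x * ReLU6(x + 3) / 6``.

    Accepts a plain ndarray/scalar (returns ndarray) or a graph
    :class:`Tensor` (returns Tensor, differentiable).
    """
    if isinstance(x, Tensor):
        return x.hswish()
    arr = np.asarray(x, dtype=float)
    return arr * np.clip(arr + 3.0, 0.0, 6.0) / 6.0


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def channel_mean(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, 1, H, W) mean over the channel dimension."""
    return x.mean(axis=1, keepdims=True)


def _conv_geometry(h, w, kh, kw, stride, padding):
    sh, sw = stride
    ph, pw = padding
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    return ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=(1, 1), padding=(0, 0), groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout.

    weight shape: (C_out, C_in // groups, K_h, K_w). Depthwise convolution is
    groups == C_in == C_out.
    """
    x = _as_tensor(x)
    n, c_in, h, w = x.shape
    c_out, c_ig, kh, kw = weight.shape
    if c_in != c_ig * groups:
        raise ValueError(
            f"input channels {c_in} incompatible with weight {weight.shape} and groups {groups}")
    if c_out % groups:
        raise ValueError("out_channels must be divisible by groups")
    sh, sw = stride
    ph, pw = padding
    ho, wo = _conv_geometry(h, w, kh, kw, stride, padding)
    c_og = c_out // groups

    hw = ho * wo
    ck = c_ig * kh * kw
    pointwise = kh == kw == 1 and sh == sw == 1 and ph == pw == 0
    # few groups: group-major columns (g, N*HW, CK) make each pass one large
    # batched GEMM; many groups (depthwise): sample-major avoids the costly
    # group-major transpose and keeps GEMM batches over (N, g)
    group_major = groups <= 4
    if pointwise:
        if group_major:
            cols = x.data.reshape(n, groups, c_ig, hw).transpose(1, 0, 3, 2) \
                .reshape(groups, n * hw, ck)
        else:
            cols = x.data.reshape(n, groups, c_ig, hw).transpose(0, 1, 3, 2)
    else:
        if ph or pw:
            xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        else:
            xp = x.data
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        win = win.reshape(n, groups, c_ig, ho, wo, kh, kw)
        if group_major:
            cols = win.transpose(1, 0, 3, 4, 2, 5, 6).reshape(groups, n * hw, ck)
        else:
            cols = win.transpose(0, 1, 3, 4, 2, 5, 6).reshape(n, groups, hw, ck)
    wm = weight.data.reshape(groups, c_og, ck)
    if group_major:
        out = np.matmul(cols, wm.transpose(0, 2, 1))      # (g, N*HW, C_og)
        out = out.reshape(groups, n, hw, c_og).transpose(1, 0, 3, 2) \
            .reshape(n, c_out, ho, wo)
    else:
        out = np.matmul(cols, wm.transpose(0, 2, 1))      # (N, g, HW, C_og)
        out = out.transpose(0, 1, 3, 2).reshape(n, c_out, ho, wo)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if group_major:
            go = g.reshape(n, groups, c_og, hw).transpose(1, 0, 3, 2) \
                .reshape(groups, n * hw, c_og)
            if weight.requires_grad:
                weight._accum_owned(np.matmul(go.transpose(0, 2, 1), cols)
                                    .reshape(weight.shape))
            dcols = np.matmul(go, wm) if x.requires_grad else None
        else:
            go = g.reshape(n, groups, c_og, hw)
            if weight.requires_grad:
                weight._accum_owned(
                    np.matmul(go, cols).sum(axis=0).reshape(weight.shape))
            dcols = (np.matmul(go.transpose(0, 1, 3, 2), wm)
                     if x.requires_grad else None)
        if bias is not None and bias.requires_grad:
            bias._accum_owned(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if group_major:
                dcols = dcols.reshape(groups, n, ho, wo, c_ig, kh, kw) \
                    .transpose(1, 0, 4, 2, 3, 5, 6)
            else:
                dcols = dcols.reshape(n, groups, ho, wo, c_ig, kh, kw) \
                    .transpose(0, 1, 4, 2, 3, 5, 6)
            dwin = dcols.reshape(n, c_in, ho, wo, kh, kw)
            if pointwise:
                x._accum_owned(dwin.reshape(n, c_in, h, w))
            else:
                dxp = np.zeros((n, c_in, h + 2 * ph, w + 2 * pw), dtype=x.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += dwin[:, :, :, :, i, j]
                x._accum_owned(dxp[:, :, ph:ph + h, pw:pw + w])

    return Tensor._make(out, parents, backward)


def batch_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float):
    """Fused training-mode batch normalization over axes (0, 2, 3).

    Returns (out, batch_mean, batch_var) with the statistics as plain
    per-channel arrays (biased variance, as used for normalization).
    """
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    xhat = x.data - mu
    var = np.mean(np.square(xhat), axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat *= inv  # in place: the centered copy becomes the normalized one
    gamma = weight.data[None, :, None, None]
    out = xhat * gamma
    out += bias.data[None, :, None, None]

    def backward(g):
        gx = g * xhat
        gx_sum = gx.sum(axis=axes, keepdims=True)
        g_sum = g.sum(axis=axes, keepdims=True)
        if weight.requires_grad:
            weight._accum_owned(gx_sum.reshape(-1))
        if bias.requires_grad:
            bias._accum_owned(g_sum.reshape(-1).copy())
        if x.requires_grad:
            dx = g - g_sum * (1.0 / n)
            dx -= xhat * (gx_sum * (1.0 / n))
            dx *= gamma * inv
            x._accum_owned(dx)

    out_t = Tensor._make(out, (x, weight, bias), backward)
    return out_t, mu.reshape(-1), var.reshape(-1), n


def _depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                      stride, padding) -> Tensor:
    """Depthwise convolution as K*K shifted fused multiply-adds (faster than
    batched GEMM with a length-K*K inner dimension)."""
    n, c, h, w = x.shape
    _, _, kh, kw = weight.shape
    sh, sw = stride
    ph, pw = padding
    ho, wo = _conv_geometry(h, w, kh, kw, stride, padding)
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x.data
    out = np.zeros((n, c, ho, wo), dtype=x.dtype)
    wd = weight.data
    for i in range(kh):
        for j in range(kw):
            out += wd[:, 0, i, j][None, :, None, None] \
                * xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
    if bias is not None:
        out += bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            gw = np.empty_like(wd)
            for i in range(kh):
                for j in range(kw):
                    gw[:, 0, i, j] = (
                        g * xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
                    ).sum(axis=(0, 2, 3))
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += \
                        wd[:, 0, i, j][None, :, None, None] * g
            x._accum(dxp[:, :, ph:ph + h, pw:pw + w])

    return Tensor._make(out, parents, backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """x (N, in) with weight (out, in) -> (N, out)."""
    out = x @ weight.T
    if bias is not None:
        out = out + bias
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    n, c = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant, for stability
    z = logits - shift
    log_probs = z - z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, c), dtype=logits.dtype)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / n)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x (testing utility)."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
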