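"""Independent brute-force re-implementations used as test oracles.

Everything here recomputes a block's forward pass from its parameter
arrays using a different code path than the package (scipy correlation or
explicit Python loops), so agreement is evidence of correctness rather
than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def conv2d_oracle(x, w, b=None, stride=1, dilation=1, groups=1):
    """Same-padded 2-d cross-correlation via scipy.ndimage, stride by
    output subsampling, dilation by kernel zero-insertion."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    if dilation > 1:
        wd = np.zeros((O, Cg, (kh - 1) * dilation + 1, (kw - 1) * dilation + 1))
        wd[:, :, ::dilation, ::dilation] = w
        w, kh, kw = wd, wd.shape[2], wd.shape[3]
    out = np.zeros((B, O, H, W))
    cpg, opg = C // groups, O // groups
    for bi in range(B):
        for o in range(O):
            g = o // opg
            for ci in range(cpg):
                out[bi, o] += ndimage.correlate(
                    x[bi, g * cpg + ci], w[o, ci], mode="constant", cval=0.0)
    if stride > 1:
        out = out[:, :, ::stride, ::stride]
    if b is not None:
        out = out + np.asarray(b, dtype=np.float64).reshape(1, O, 1, 1)
    return out


def eca_oracle(x, weight):
    """GAP, then an explicit per-channel dot product over the zero-padded
    window, sigmoid, broadcast multiply."""
    x = np.asarray(x, dtype=np.float64)
    k = len(weight)
    pad = (k - 1) // 2
    B, C, H, W = x.shape
    gap = x.mean(axis=(2, 3))
    padded = np.pad(gap, ((0, 0), (pad, pad)))
    gates = np.empty((B, C))
    for bi in range(B):
        for c in range(C):
            gates[bi, c] = sigmoid(np.dot(padded[bi, c:c + k], weight))
    return x * gates[:, :, None, None]


def cbam_oracle(module, x):
    """CBAM forward recomputed from the module's parameter arrays."""
    x = np.asarray(x, dtype=np.float64)

    def channel_gate(t):
        f_avg = t.mean(axis=(2, 3))
        f_max = t.max(axis=(2, 3))
        fc1, fc2 = module.channel_att.mlp.mods[0], module.channel_att.mlp.mods[2]

        def mlp(v):
            h = np.maximum(v @ fc1.weight.data.astype(np.float64)
                           + fc1.bias.data, 0.0)
            return h @ fc2.weight.data.astype(np.float64) + fc2.bias.data

        return sigmoid(mlp(f_avg) + mlp(f_max))

    def spatial_gate(t):
        pooled = np.stack([t.mean(axis=1), t.max(axis=1)], axis=1)
        conv = module.spatial_att.conv
        return sigmoid(conv2d_oracle(pooled, conv.weight.data, conv.bias.data))

    def apply_channel(t):
        return t * channel_gate(t)[:, :, None, None]

    def apply_spatial(t):
        return t * spatial_gate(t)

    if module.spatial_first:
        return apply_channel(apply_spatial(x))
    return apply_spatial(apply_channel(x))


def batchnorm_oracle(bn, x, training):
    x = np.asarray(x, dtype=np.float64)
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
    else:
        mean, var = bn.running_mean, bn.running_var
    xhat = (x - mean.reshape(1, -1, 1, 1)) / np.sqrt(
        var.reshape(1, -1, 1, 1) + bn.eps)
    return bn.weight.data.reshape(1, -1, 1, 1) * xhat \
        + bn.bias.data.reshape(1, -1, 1, 1)


def aspp_oracle(module, x, training=False):
    """ASPP forward recomputed branch by branch via scipy correlation."""
    outs = []
    for branch in module.branches.mods:
        conv, bn = branch.mods[0], branch.mods[1]
        y = conv2d_oracle(x, conv.weight.data, dilation=conv.dilation)
        outs.append(np.maximum(batchnorm_oracle(bn, y, training), 0.0))
    merged = np.concatenate(outs, axis=1)
    fconv, fbn = module.fuse.mods[0], module.fuse.mods[1]
    fused = conv2d_oracle(merged, fconv.weight.data)
    return np.maximum(batchnorm_oracle(fbn, fused, training), 0.0)


def dsc_oracle(module, x):
    """Depthwise-separable conv as the rank-1 standard kernel, via scipy."""
    kernel = module.as_standard_kernel()
    b = None
    if module.pointwise.bias is not None:
        b = module.pointwise.bias.data
    return conv2d_oracle(x, kernel, b, stride=module.depthwise.stride)


def hausdorff_oracle(a, b):
    """O(|A||B|) double loop over both directed distances."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    best = 0.0
    for p in a:
        d = min(float(np.hypot(*(p - q))) for q in b)
        best = max(best, d)
    for q in b:
        d = min(float(np.hypot(*(q - p))) for p in a)
        best = max(best, d)
    return best
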