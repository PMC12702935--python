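"""Depthwise-separable convolution, its analytic cost model, and counters.

A depthwise-separable convolution (DSC conv) factors a standard Dk x Dk
convolution M->N into a per-channel spatial stage (one Dk x Dk kernel per
input channel, groups = M) and a 1x1 cross-channel stage (M -> N).  For a
square stride-1 map of side Df the multiply-accumulate counts are

    standard:  Dk^2 * M * N * Df^2
    separable: Dk^2 * M * Df^2  +  M * N * Df^2

whose quotient is the classic 1/N + 1/Dk^2 — independent of M and Df, and
below 1 whenever Dk >= 2 and N >= 2.  The same structure holds for the
parameter counts (drop the Df^2 factor).

``count_parameters`` / ``count_macs`` walk any :class:`~iap_transunet.nn.Module`
tree and are used by the "inspect" and "ablate" pipelines for Table-style
parameter/MAC reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor

__all__ = [
    "ConvSpec", "conv_cost_standard", "conv_cost_dsc", "cost_ratio",
    "DepthwiseSeparableConv2d", "count_parameters", "count_macs", "layer_table",
]


@dataclass(frozen=True)
class ConvSpec:
    """(Dk, M, N, Df): kernel size, in/out channels, square map side.

    The cost formulas assume stride 1 and "same" padding, i.e. input and
    output maps share the side Df.
    """
    Dk: int
    M: int
    N: int
    Df: int

    def __post_init__(self):
        for name in ("Dk", "M", "N", "Df"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.Dk % 2 == 0:
            raise ValueError(f"Dk must be odd, got {self.Dk}")


def conv_cost_standard(spec: ConvSpec) -> int:
    """MACs of a standard Dk x Dk convolution M -> N on a Df x Df map."""
    return spec.Dk * spec.Dk * spec.M * spec.N * spec.Df * spec.Df


def conv_cost_dsc(spec: ConvSpec) -> int:
    """MACs of the separable factorisation: depthwise + pointwise stages."""
    depthwise = spec.Dk * spec.Dk * spec.M * spec.Df * spec.Df
    pointwise = spec.M * spec.N * spec.Df * spec.Df
    return depthwise + pointwise


def cost_ratio(spec: ConvSpec) -> float:
    """conv_cost_dsc / conv_cost_standard = 1/N + 1/Dk^2 in closed form."""
    return 1.0 / spec.N + 1.0 / (spec.Dk * spec.Dk)


class DepthwiseSeparableConv2d(Module):
    """Depthwise (groups=M, optionally coarser) then pointwise 1x1 conv.

    Equivalent to a standard convolution whose kernel is the rank-1 product
    K[n, m] = P[n, m] * D[m] when ``groups == in_channels``.  ``groups``
    exposes the depthwise stage's group count (1 = ordinary convolution,
    in_channels = full depthwise) for the group-number ablation.
    Biases default off on both stages (the block is normally followed by a
    normalisation layer).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3, *,
                 stride: int = 1, groups: int | None = None, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        groups = in_channels if groups is None else groups
        self.depthwise = Conv2d(in_channels, in_channels, kernel_size,
                                stride=stride, padding="same", groups=groups,
                                bias=False, rng=rng)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))

    def as_standard_kernel(self) -> np.ndarray:
        """Materialise the equivalent standard kernel (full-depthwise only)."""
        D = self.depthwise.weight.data          # (M, 1, k, k)
        if D.shape[0] != self.depthwise.groups:
            raise ValueError("rank-1 expansion requires a full depthwise stage")
        P = self.pointwise.weight.data[:, :, 0, 0]  # (N, M)
        return P[:, :, None, None] * D[None, :, 0, :, :]


# -- counters -------------------------------------------------------------

def count_parameters(block: Module) -> int:
    """Total element count of all learnable arrays in a module tree."""
    return int(sum(p.size for p in block.parameters()))


def _conv_macs(conv: Conv2d, out_h: int, out_w: int) -> int:
    k = conv.kernel_size
    return (k * k * (conv.in_channels // conv.groups) * conv.out_channels
            * out_h * out_w)


def count_macs(model: Module, input_shape: tuple[int, ...]) -> int:
    """Multiply-accumulate count of all convolutions and linear maps for one
    forward pass at ``input_shape`` (C, H, W); measured by tracing shapes."""
    return sum(row["macs"] for row in layer_table(model, input_shape))


def layer_table(model: Module, input_shape: tuple[int, ...]) -> list[dict]:
    """Per-layer (name, type, params, macs) report at a given input size.

    Runs one forward pass with shape hooks; layers that carry no learnable
    arrays (activations, resampling) are omitted.
    """
    records: list[dict] = []
    name_of = {id(m): n for n, m in model.named_modules()}
    originals: list[tuple[Module, object]] = []

    def wrap(mod: Module):
        fwd = mod.forward

        def hooked(*args, **kwargs):
            out = fwd(*args, **kwargs)
            if isinstance(out, Tensor):
                records.append({
                    "name": name_of.get(id(mod), "?"), "type": "Conv2d",
                    "params": count_parameters(mod),
                    "macs": _conv_macs(mod, out.shape[2], out.shape[3])})
            return out
        mod.forward = hooked
        originals.append((mod, fwd))

    from .nn import Linear, LayerNorm  # local import to avoid cycle at module load

    def wrap_other(mod: Module, typename: str, macs_fn):
        fwd = mod.forward

        def hooked(*args, **kwargs):
            out = fwd(*args, **kwargs)
            records.append({"name": name_of.get(id(mod), "?"), "type": typename,
                            "params": count_parameters(mod),
                            "macs": macs_fn(out)})
            return out
        mod.forward = hooked
        originals.append((mod, fwd))

    for _, mod in model.named_modules():
        if isinstance(mod, Conv2d):
            wrap(mod)
        elif isinstance(mod, Linear):
            wrap_other(mod, "Linear", lambda out, m=mod: int(
                np.prod(out.shape[:-1])) * m.in_features * m.out_features)
        elif isinstance(mod, (BatchNorm2d, LayerNorm)):
            wrap_other(mod, type(mod).__name__, lambda out: 0)
        elif type(mod).__name__ == "EcaAttention":
            wrap_other(mod, "EcaAttention", lambda out, m=mod: int(
                out.shape[1]) * m.kernel_size)

    was_training = model.training
    model.eval()
    try:
        x = Tensor(np.zeros((1, *input_shape), np.float32))
        model(x)
    finally:
        for mod, fwd in originals:
            mod.forward = fwd
        model.train(was_training)
    # a shared submodule (e.g. the CBAM perceptron) may run more than once
    # per pass: keep one row per layer, counting params once and MACs per call
    merged: dict[str, dict] = {}
    for row in records:
        if row["name"] in merged:
            merged[row["name"]]["macs"] += row["macs"]
        else:
            merged[row["name"]] = dict(row)
    return list(merged.values())
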