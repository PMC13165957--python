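"""Closed-form cost accounting for partial convolution (PConv).

A partial convolution applies a k x k kernel to only ``c_p`` of the
``c`` input channels (producing ``c_p`` outputs) and passes the
remaining channels through untouched. Counting multiply-accumulates of
the convolution proper (bias and the identity pass-through cost zero):

    FLOPs(standard) = h * w * k^2 * c^2
    FLOPs(partial)  = h * w * k^2 * c_p^2

so the speed-up ratio is (c / c_p)^2 = 1 / r^2 with separation ratio
r = c_p / c — independent of the spatial size and kernel. At the usual
r = 1/4 the partial convolution costs 1/16 of a standard one.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PConvSpec:
    """Channel and geometry description of one convolution layer."""

    channels_total: int
    channels_active: int
    kernel: int = 3
    spatial: tuple[int, int] = (1, 1)

    def __post_init__(self):
        if self.channels_active <= 0:
            raise ValueError("channels_active must be positive")
        if self.channels_active > self.channels_total:
            raise ValueError("channels_active cannot exceed channels_total")
        if self.kernel <= 0 or min(self.spatial) <= 0:
            raise ValueError("kernel and spatial dims must be positive")

    @property
    def separation_ratio(self) -> float:
        return self.channels_active / self.channels_total


def standard_conv_flops(spec: PConvSpec) -> float:
    h, w = spec.spatial
    return float(h * w * spec.kernel**2 * spec.channels_total**2)


def pconv_flops(spec: PConvSpec) -> float:
    h, w = spec.spatial
    return float(h * w * spec.kernel**2 * spec.channels_active**2)


def pconv_flop_ratio(spec: PConvSpec) -> float:
    """Speed-up of PConv over a standard convolution: (c / c_p)^2."""
    return standard_conv_flops(spec) / pconv_flops(spec)


def speedup_for_ratio(r: float) -> float:
    """Speed-up as a function of the separation ratio r = c_p / c."""
    if not 0 < r <= 1:
        raise ValueError("separation ratio must lie in (0, 1]")
    return 1.0 / r**2
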