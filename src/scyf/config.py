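"""Codec configuration and named presets.

``CodecConfig`` gathers every user-tunable knob of the compressor:

block_size (BS)
    Length of a range block in samples.  Must be a power of two so that
    recursive halving always yields integer block lengths, and small enough
    that ``BS / 2**max_divisions >= 2``.
jump_step (JS)
    Distance in samples between the starts of two adjacent overlapping
    domain blocks.  ``JS = 1`` gives the densest (and slowest) pool.
frms_limit
    Split threshold on the fractal RMS residual, expressed in the amplitude
    units of the stored samples (ADC counts for integer records).  A range
    block whose best match exceeds this residual is halved and re-encoded.
max_divisions
    Maximum depth of the per-range-block binary division tree.
smooth / smooth_span
    Optional post-reconstruction local-quadratic (LOESS-style) smoothing
    and its odd window length in samples.  Off by default.
domain_halved
    Store the domain at half rate (pairwise sample means); it is re-expanded
    by linear interpolation before matching.
extension
    Mirror-pad the signal by this many samples on each side before
    compression (helps short records; the padding is cropped on decode).
scale_bits / scale_range, shift_bits
    Uniform quantizer widths for the affine scale and shift coefficients.
    The shift range is taken per-record from the DC-removed amplitude span
    and carried in the stream header.
lossless_coeffs
    Debug switch: carry full-precision coefficients instead of quantizer
    codes (64 bits each in the stream).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

from .errors import ConfigurationError

__all__ = ["CodecConfig", "PRESETS", "preset"]


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class CodecConfig:
    block_size: int = 256
    jump_step: int = 1
    frms_limit: float = 12.0
    max_divisions: int = 2
    smooth: bool = False
    smooth_span: int = 7
    domain_halved: bool = False
    extension: int = 0
    scale_bits: int = 8
    scale_range: Tuple[float, float] = (-2.0, 2.0)
    shift_bits: int = 11
    lossless_coeffs: bool = False

    def __post_init__(self) -> None:
        if not _is_power_of_two(self.block_size):
            raise ConfigurationError(
                f"block_size must be a power of two, got {self.block_size}"
            )
        if self.max_divisions < 0:
            raise ConfigurationError("max_divisions must be >= 0")
        if self.block_size // (1 << self.max_divisions) < 2:
            raise ConfigurationError(
                "block_size / 2**max_divisions must be >= 2 "
                f"(got BS={self.block_size}, divisions={self.max_divisions})"
            )
        if self.jump_step < 1:
            raise ConfigurationError("jump_step must be >= 1")
        if not self.frms_limit > 0:
            raise ConfigurationError("frms_limit must be > 0")
        if self.extension < 0:
            raise ConfigurationError("extension must be >= 0")
        if self.scale_bits < 1 or self.shift_bits < 1:
            raise ConfigurationError("quantizer bit widths must be >= 1")
        lo, hi = self.scale_range
        if not lo < hi:
            raise ConfigurationError("scale_range must satisfy min < max")
        if self.smooth_span < 3 or self.smooth_span % 2 == 0:
            raise ConfigurationError("smooth_span must be odd and >= 3")

    def leaf_sizes(self) -> Tuple[int, ...]:
        """Permitted leaf block lengths, largest first: BS, BS/2, ..."""
        return tuple(self.block_size >> k for k in range(self.max_divisions + 1))

    def with_(self, **kw) -> "CodecConfig":
        return replace(self, **kw)


#: Per-database settings: (BS, JS, FRMS limit, divisions).
PRESETS = {
    "cse": CodecConfig(block_size=256, jump_step=1, frms_limit=12.0, max_divisions=2),
    "mitadb": CodecConfig(block_size=128, jump_step=1, frms_limit=5.0, max_divisions=3),
    "upt": CodecConfig(block_size=256, jump_step=1, frms_limit=12.0, max_divisions=2),
    "butqdb": CodecConfig(block_size=256, jump_step=1, frms_limit=12.0, max_divisions=2),
}


def preset(name: str, **overrides) -> CodecConfig:
    """Return a named preset, optionally overriding individual fields."""
    try:
        base = PRESETS[name.lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return base.with_(**overrides) if overrides else base
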