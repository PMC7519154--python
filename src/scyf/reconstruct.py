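"""Single-pass decoding of a compressed ECG.

Unlike classical iterated-function-system fractal decoding, the domain
cycle is stored verbatim in the stream, so every leaf can be evaluated
directly: reconstruction is one deterministic pass, never a fixed-point
iteration.  Optional LOESS-style smoothing (tricube-weighted local
quadratic regression) can be applied to the joined signal to soften the
seams between adjacent range blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .codec import (
    CompressedECG,
    DomainPool,
    MatchLeaf,
    _expand_domain,
    dequantize_affine,
    pairwise_swap,
)
from .config import CodecConfig
from .errors import ConfigurationError, CorruptStreamError, InternalError

__all__ = ["ReconstructionResult", "decode_leaf", "reconstruct", "loess_smooth"]


@dataclass
class ReconstructionResult:
    """Decoded signal plus per-sample leaf provenance for diagnostics."""

    signal: np.ndarray        # length = header n_samples
    leaf_size: np.ndarray     # leaf block length that produced each sample
    leaf_db_index: np.ndarray  # domain-block index that produced each sample


def decode_leaf(
    leaf: MatchLeaf,
    pool: DomainPool,
    shift_range,
    config: CodecConfig,
) -> np.ndarray:
    """Evaluate one leaf: fetch its domain block, apply the transform bit,
    then the dequantized affine coefficients."""
    if not 0 <= leaf.db_index < pool.count(leaf.size):
        raise CorruptStreamError(
            f"domain block index {leaf.db_index} out of range at size {leaf.size}"
        )
    d = pool.block(leaf.size, leaf.db_index)
    if leaf.transform:
        d = pairwise_swap(d)
    s_q, o_q = dequantize_affine(
        (leaf.scale_code, leaf.shift_code), shift_range, config
    )
    return s_q * d + o_q


def reconstruct(c: CompressedECG, smooth: Optional[bool] = None) -> ReconstructionResult:
    """Rebuild the time-domain signal from a :class:`CompressedECG`.

    The domain pool is re-derived deterministically from the header, each
    division tree is decoded depth-first and the leaves concatenated in
    temporal order; padding and mirror extension are cropped, the DC value
    restored, and smoothing applied if the header requests it (``smooth``
    overrides the header flag when given).
    """
    cfg = c.config
    domain_full = _expand_domain(
        np.asarray(c.domain_payload, dtype=np.float64) - c.dc_value,
        c.domain_end - c.domain_start,
        cfg.domain_halved,
    )
    pool = DomainPool(domain_full, cfg)

    n_pad = c.n_padded
    bs = cfg.block_size
    if len(c.trees) != n_pad // bs:
        raise CorruptStreamError(
            f"stream carries {len(c.trees)} trees but header implies {n_pad // bs}"
        )

    out = np.empty(n_pad)
    sizes = np.empty(n_pad, dtype=np.int64)
    dbs = np.empty(n_pad, dtype=np.int64)
    pos = 0
    for tree in c.trees:
        for leaf in tree.iter_leaves():
            seg = decode_leaf(leaf, pool, c.shift_range, cfg)
            out[pos : pos + leaf.size] = seg
            sizes[pos : pos + leaf.size] = leaf.size
            dbs[pos : pos + leaf.size] = leaf.db_index
            pos += leaf.size
        if pos % bs:
            raise CorruptStreamError("division tree does not tile its range block")
    if pos != n_pad:
        raise InternalError("decoded sample count mismatch")

    e = cfg.extension
    signal = out[e : e + c.n_samples] + c.dc_value
    sizes = sizes[e : e + c.n_samples]
    dbs = dbs[e : e + c.n_samples]

    do_smooth = cfg.smooth if smooth is None else smooth
    if do_smooth:
        signal = loess_smooth(signal, cfg.smooth_span)
    return ReconstructionResult(signal=signal, leaf_size=sizes, leaf_db_index=dbs)


def loess_smooth(x: np.ndarray, span: int) -> np.ndarray:
    """Local quadratic regression smoother with tricube weights.

    Each sample is replaced by the value at its own position of a weighted
    least-squares 2nd-degree polynomial fitted over a centered window of
    ``span`` samples (shrunk near the edges).  Polynomials up to degree 2
    are reproduced exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if span % 2 == 0 or span < 3:
        raise ConfigurationError("smoothing span must be odd and >= 3")
    if span > n:
        raise ConfigurationError(f"smoothing span {span} exceeds signal length {n}")
    h = span // 2
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        t = idx[lo:hi] - i
        # tricube weights; h+1 in the denominator keeps edge points positive
        w = (1.0 - (np.abs(t) / (h + 1.0)) ** 3) ** 3
        sw = np.sqrt(w)
        A = np.vander(t.astype(np.float64), 3, increasing=True)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], x[lo:hi] * sw, rcond=None)
        out[i] = coef[0]  # value at t = 0
    return out
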