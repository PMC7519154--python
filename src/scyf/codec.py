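"""Fractal compression of a single-lead ECG segment.

The encoder exploits the quasiperiodicity of the ECG: one representative
cycle (P-wave onset to next P-wave onset) is kept verbatim as the *domain*,
and every *range block* (a non-overlapping BS-sample block of the signal)
is described as an affine map of some overlapping *domain block* cut from
that cycle.  A range block whose best fractal RMS residual (FRMS) exceeds
the configured limit is halved and each half encoded independently, down to
a preset maximum division depth; at the deepest level the best available
match is stored regardless of the limit.

Per candidate the encoder fits the least-squares affine pair
``(s, o) = argmin sum (s*d + o - r)^2``, quantizes both coefficients with
the uniform quantizers declared in the header, and ranks candidates by the
residual achieved with the *dequantized* coefficients, so the stored code
is the one that is actually best after coding.  Two block transforms are
searched: identity and a pairwise swap of adjacent samples (one bit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import CodecConfig
from .errors import (
    ConfigurationError,
    InternalError,
    InvalidInputError,
    MissingAnnotationError,
)

__all__ = [
    "Domain",
    "DomainPool",
    "MatchLeaf",
    "RangeNode",
    "CompressedECG",
    "subtract_dc",
    "select_domain",
    "build_domain_pool",
    "pairwise_swap",
    "fit_affine",
    "quantize_affine",
    "dequantize_affine",
    "match_block",
    "encode_range",
    "compress",
]

Code = Union[int, float]  # quantizer code, or raw float in lossless mode


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Domain:
    """The stored single ECG cycle (DC-removed), ``[start, end)`` in the
    (possibly extended) source signal; ``halved`` marks pairwise-averaged
    storage."""

    samples: np.ndarray
    start: int
    end: int
    halved: bool = False

    @property
    def full_length(self) -> int:
        return self.end - self.start


class DomainPool:
    """Overlapping domain blocks at every permitted leaf size.

    Blocks of size ``L`` start at offsets ``0, JS, 2*JS, ...`` into the
    full-length (re-expanded if halved) domain; there are
    ``floor((Ld - L) / JS) + 1`` of them.
    """

    def __init__(self, domain_full: np.ndarray, config: CodecConfig):
        self._full = np.ascontiguousarray(domain_full, dtype=np.float64)
        self._js = config.jump_step
        self._sizes = config.leaf_sizes()
        ld = len(self._full)
        if ld < config.block_size:
            raise ConfigurationError(
                f"domain length {ld} is shorter than block_size {config.block_size}"
            )
        self._counts: Dict[int, int] = {
            L: (ld - L) // self._js + 1 for L in self._sizes
        }

    @property
    def domain_full(self) -> np.ndarray:
        return self._full

    @property
    def sizes(self) -> Tuple[int, ...]:
        return self._sizes

    def count(self, size: int) -> int:
        try:
            return self._counts[size]
        except KeyError:
            raise InternalError(f"size {size} is not a permitted leaf size") from None

    def offsets(self, size: int) -> np.ndarray:
        return np.arange(self.count(size)) * self._js

    def block(self, size: int, index: int) -> np.ndarray:
        if not 0 <= index < self.count(size):
            raise InternalError(
                f"domain block index {index} out of range at size {size}"
            )
        off = index * self._js
        return self._full[off : off + size]

    def blocks(self, size: int) -> np.ndarray:
        """All domain blocks of ``size`` as a (count, size) read-only view."""
        n = self.count(size)
        windows = np.lib.stride_tricks.sliding_window_view(self._full, size)
        return windows[:: self._js][:n]


@dataclass(frozen=True)
class MatchLeaf:
    """Best affine match of one range block: pool index, quantized scale and
    shift codes, transform bit (0 none / 1 swap) and the achieved FRMS."""

    size: int
    db_index: int
    scale_code: Code
    shift_code: Code
    transform: int
    frms: float


@dataclass
class RangeNode:
    """Node of the per-range-block binary division tree."""

    depth: int
    leaf: Optional[MatchLeaf] = None
    children: Optional[Tuple["RangeNode", "RangeNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def iter_leaves(self) -> Iterator[MatchLeaf]:
        """Leaves in temporal (left-to-right) order."""
        if self.is_leaf:
            yield self.leaf
        else:
            left, right = self.children
            yield from left.iter_leaves()
            yield from right.iter_leaves()

    def max_depth(self) -> int:
        if self.is_leaf:
            return self.depth
        return max(c.max_depth() for c in self.children)


@dataclass
class CompressedECG:
    """Everything needed to rebuild the signal: header, the raw domain
    payload (original amplitude units, halved if so configured) and one
    division tree per range block."""

    fs: float
    n_samples: int
    source_bits: int
    dc_value: float
    config: CodecConfig
    shift_range: Tuple[float, float]
    domain_payload: np.ndarray
    domain_start: int
    domain_end: int
    trees: List[RangeNode] = field(default_factory=list)

    @property
    def n_padded(self) -> int:
        bs = self.config.block_size
        n_ext = self.n_samples + 2 * self.config.extension
        return -(-n_ext // bs) * bs

    def iter_leaves(self) -> Iterator[MatchLeaf]:
        for tree in self.trees:
            yield from tree.iter_leaves()


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def subtract_dc(x: Sequence[float]) -> Tuple[np.ndarray, float]:
    """Remove the DC component (mean, including any offset) from ``x``."""
    arr = np.asarray(x, dtype=np.float64)
    if arr.size == 0:
        raise InvalidInputError("cannot subtract DC from an empty signal")
    dc = float(arr.mean())
    return arr - dc, dc


def pairwise_swap(block: np.ndarray) -> np.ndarray:
    """Swap each two adjacent samples: the codec's single affine block
    transform (an involution)."""
    block = np.asarray(block)
    if block.shape[-1] % 2:
        raise InvalidInputError("pairwise_swap requires an even-length block")
    out = np.empty_like(block)
    out[..., 0::2] = block[..., 1::2]
    out[..., 1::2] = block[..., 0::2]
    return out


def _pairwise_mean(x: np.ndarray) -> np.ndarray:
    # odd tail: last sample is kept as-is
    n = len(x)
    half = x[: n - (n % 2)].reshape(-1, 2).mean(axis=1)
    if n % 2:
        half = np.concatenate([half, x[-1:]])
    return half


def _expand_domain(samples: np.ndarray, full_length: int, halved: bool) -> np.ndarray:
    """Full-rate view of the domain; halved storage is re-expanded by linear
    interpolation (the first-order inverse of pairwise averaging)."""
    if not halved:
        if len(samples) != full_length:
            raise InternalError("un-halved domain length mismatch")
        return np.asarray(samples, dtype=np.float64)
    centers = 2.0 * np.arange(len(samples)) + 0.5
    if full_length % 2:
        centers[-1] = full_length - 1.0
    return np.interp(np.arange(full_length, dtype=np.float64), centers, samples)


def select_domain(
    x0: np.ndarray,
    config: CodecConfig,
    cycle_bounds: Optional[Tuple[int, int]] = None,
    p_onsets: Optional[Sequence[int]] = None,
) -> Domain:
    """Pick the single cycle stored as the fractal domain.

    With explicit ``cycle_bounds`` the half-open window ``[start, end)`` is
    used verbatim.  Otherwise the cycle (consecutive P-onset pair) whose
    length is closest to the median length of the first five cycles is
    chosen, earliest on ties — a stand-in for the manual "most
    representative cycle" choice.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    if cycle_bounds is not None:
        start, end = int(cycle_bounds[0]), int(cycle_bounds[1])
        if not (0 <= start < end <= len(x0)):
            raise InvalidInputError(f"cycle bounds {cycle_bounds} out of range")
    elif p_onsets is not None and len(p_onsets) >= 2:
        onsets = [int(v) for v in p_onsets]
        lengths = np.diff(onsets)[:5]
        median = float(np.median(lengths))
        idx = int(np.argmin(np.abs(lengths - median)))  # argmin = earliest tie
        start, end = onsets[idx], onsets[idx + 1]
    else:
        raise MissingAnnotationError(
            "select_domain needs cycle_bounds or at least two p_onsets"
        )
    if end - start < config.block_size:
        raise ConfigurationError(
            f"domain cycle length {end - start} is shorter than "
            f"block_size {config.block_size}"
        )
    samples = x0[start:end]
    if config.domain_halved:
        samples = _pairwise_mean(samples)
    return Domain(samples=samples, start=start, end=end, halved=config.domain_halved)


def build_domain_pool(domain: Domain, config: CodecConfig) -> DomainPool:
    """Overlapping domain blocks at every leaf size, stepped by jump_step."""
    full = _expand_domain(domain.samples, domain.full_length, domain.halved)
    return DomainPool(full, config)


def fit_affine(d: np.ndarray, r: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares affine fit of domain block ``d`` onto range block ``r``.

    Returns ``(s, o, frms)`` minimizing ``sum (s*d + o - r)**2`` with
    ``frms = sqrt(mean residual**2)`` — the fractal RMS similarity metric.
    A constant ``d`` makes the system rank-deficient; the minimum-norm
    solution ``s = 0, o = mean(r)`` is returned.
    """
    d = np.asarray(d, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if d.shape != r.shape or d.ndim != 1:
        raise InvalidInputError("fit_affine needs two 1-D arrays of equal length")
    n = len(d)
    if n < 2:
        raise InvalidInputError("fit_affine needs at least two samples")
    sd, sr = d.sum(), r.sum()
    denom = n * (d * d).sum() - sd * sd
    if denom <= 0.0:
        s, o = 0.0, sr / n
    else:
        s = (n * (d * r).sum() - sd * sr) / denom
        o = (sr - s * sd) / n
    resid = s * d + o - r
    frms = math.sqrt(float(resid @ resid) / n)
    return float(s), float(o), frms


def _fit_affine_many(D: np.ndarray, r: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized fit of every row of ``D`` onto ``r``."""
    n = D.shape[1]
    sd = D.sum(axis=1)
    sr = r.sum()
    denom = n * (D * D).sum(axis=1) - sd * sd
    sdr = D @ r
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (n * sdr - sd * sr) / denom
    s = np.where(denom > 0.0, s, 0.0)
    o = (sr - s * sd) / n
    return s, o


# ---------------------------------------------------------------------------
# coefficient quantization
# ---------------------------------------------------------------------------

def _quant_uniform(v, lo: float, hi: float, bits: int):
    levels = 1 << bits
    width = (hi - lo) / levels
    if width <= 0.0:
        return np.zeros_like(np.asarray(v), dtype=np.int64) if np.ndim(v) else 0
    code = np.floor((np.asarray(v, dtype=np.float64) - lo) / width)
    code = np.clip(code, 0, levels - 1).astype(np.int64)
    return code if np.ndim(v) else int(code)


def _dequant_uniform(code, lo: float, hi: float, bits: int):
    levels = 1 << bits
    width = (hi - lo) / levels
    if width <= 0.0:
        return np.full_like(np.asarray(code, dtype=np.float64), lo) if np.ndim(code) else lo
    out = lo + (np.asarray(code, dtype=np.float64) + 0.5) * width
    return out if np.ndim(code) else float(out)


def quantize_affine(
    s: float, o: float, shift_range: Tuple[float, float], config: CodecConfig
) -> Tuple[Code, Code]:
    """Map (scale, shift) to uniform mid-rise quantizer codes.  Values
    outside the declared ranges are clamped into the end bins.  In
    lossless mode the full-precision values pass through as the codes."""
    if config.lossless_coeffs:
        return float(s), float(o)
    slo, shi = config.scale_range
    olo, ohi = shift_range
    return (
        _quant_uniform(s, slo, shi, config.scale_bits),
        _quant_uniform(o, olo, ohi, config.shift_bits),
    )


def dequantize_affine(
    codes: Tuple[Code, Code], shift_range: Tuple[float, float], config: CodecConfig
) -> Tuple[float, float]:
    """Inverse of :func:`quantize_affine`: codes map to bin centers."""
    sc, oc = codes
    if config.lossless_coeffs:
        return float(sc), float(oc)
    slo, shi = config.scale_range
    olo, ohi = shift_range
    return (
        _dequant_uniform(sc, slo, shi, config.scale_bits),
        _dequant_uniform(oc, olo, ohi, config.shift_bits),
    )


# ---------------------------------------------------------------------------
# matching and recursive encoding
# ---------------------------------------------------------------------------

def match_block(
    r: np.ndarray,
    pool: DomainPool,
    shift_range: Tuple[float, float],
    config: CodecConfig,
) -> MatchLeaf:
    """Exhaustively search the pool (both transforms) for the domain block
    whose affine map best reproduces ``r``.

    Candidates are scored by the FRMS achieved with *dequantized*
    coefficients; ties break to the lower domain-block index, then to the
    identity transform.
    """
    r = np.asarray(r, dtype=np.float64)
    size = len(r)
    D = pool.blocks(size)
    if D.shape[0] == 0:
        raise InternalError(f"empty domain pool at size {size}")

    best = None  # (frms, db_index, transform, scale_code, shift_code)
    for transform in (0, 1):
        Dt = D if transform == 0 else pairwise_swap(D)
        s, o = _fit_affine_many(Dt, r)
        if config.lossless_coeffs:
            sq, oq = s, o
            scodes, ocodes = s, o
        else:
            slo, shi = config.scale_range
            olo, ohi = shift_range
            scodes = _quant_uniform(s, slo, shi, config.scale_bits)
            ocodes = _quant_uniform(o, olo, ohi, config.shift_bits)
            sq = _dequant_uniform(scodes, slo, shi, config.scale_bits)
            oq = _dequant_uniform(ocodes, olo, ohi, config.shift_bits)
        resid = sq[:, None] * Dt + oq[:, None] - r
        frms = np.sqrt((resid * resid).mean(axis=1))
        k = int(np.argmin(frms))  # argmin returns the earliest minimum
        cand = (float(frms[k]), k, transform, scodes[k], ocodes[k])
        if best is None or cand[:3] < best[:3]:
            best = cand

    frms, k, transform, sc, oc = best
    if config.lossless_coeffs:
        sc, oc = float(sc), float(oc)
    else:
        sc, oc = int(sc), int(oc)
    return MatchLeaf(
        size=size, db_index=k, scale_code=sc, shift_code=oc,
        transform=transform, frms=frms,
    )


def encode_range(
    r: np.ndarray,
    pool: DomainPool,
    shift_range: Tuple[float, float],
    config: CodecConfig,
    depth: int = 0,
) -> RangeNode:
    """Encode one range block: keep the best match as a leaf if its FRMS
    meets the limit (or the maximum division depth is reached), otherwise
    split into two halves encoded independently."""
    leaf = match_block(r, pool, shift_range, config)
    if leaf.frms <= config.frms_limit or depth >= config.max_divisions:
        return RangeNode(depth=depth, leaf=leaf)
    half = len(r) // 2
    left = encode_range(r[:half], pool, shift_range, config, depth + 1)
    right = encode_range(r[half:], pool, shift_range, config, depth + 1)
    return RangeNode(depth=depth, children=(left, right))


def _mirror_extend(x: np.ndarray, e: int) -> np.ndarray:
    if e == 0:
        return x
    if e >= len(x):
        raise ConfigurationError("extension must be shorter than the signal")
    return np.concatenate([x[e:0:-1], x, x[-2 : -e - 2 : -1]])


def compress(
    x: Sequence[float],
    fs: float,
    source_bits: int,
    config: CodecConfig,
    cycle_bounds: Optional[Tuple[int, int]] = None,
    p_onsets: Optional[Sequence[int]] = None,
) -> CompressedECG:
    """Run the full compression pipeline on a raw ECG segment.

    Steps: optional mirror extension, DC removal, domain selection, domain
    pool construction, then recursive encoding of consecutive
    non-overlapping range blocks (tail zero-padded to a block multiple).
    ``cycle_bounds``/``p_onsets`` are indices into the *original* signal.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite samples")
    if len(x) < config.block_size:
        raise ConfigurationError(
            f"signal length {len(x)} is shorter than block_size {config.block_size}"
        )
    e = config.extension
    x_ext = _mirror_extend(x, e)
    x0, dc = subtract_dc(x_ext)

    if cycle_bounds is not None:
        cycle_bounds = (cycle_bounds[0] + e, cycle_bounds[1] + e)
    if p_onsets is not None:
        p_onsets = [int(v) + e for v in p_onsets]
    sel = select_domain(x0, config, cycle_bounds, p_onsets)

    # The stored payload keeps original amplitude units; the matching domain
    # is derived from it exactly as the decoder will, so encoder and decoder
    # pools are bit-identical.
    payload = x_ext[sel.start : sel.end]
    if config.domain_halved:
        payload = _pairwise_mean(payload)
    domain = Domain(
        samples=payload - dc, start=sel.start, end=sel.end, halved=config.domain_halved
    )
    pool = build_domain_pool(domain, config)

    shift_range = (float(x0.min()), float(x0.max()))
    bs = config.block_size
    n_pad = -(-len(x0) // bs) * bs
    x0p = np.zeros(n_pad)
    x0p[: len(x0)] = x0

    trees = [
        encode_range(x0p[i : i + bs], pool, shift_range, config)
        for i in range(0, n_pad, bs)
    ]
    return CompressedECG(
        fs=float(fs),
        n_samples=len(x),
        source_bits=int(source_bits),
        dc_value=dc,
        config=config,
        shift_range=shift_range,
        domain_payload=payload,
        domain_start=sel.start,
        domain_end=sel.end,
        trees=trees,
    )
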