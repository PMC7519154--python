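"""Bit-exact serialization of a compressed ECG to the ``.scyf`` container.

Layout: a fixed-width little-endian header (magic ``SCYF``, version byte,
signal provenance, codec configuration echo, quantizer ranges, domain
window), then the domain payload, then the per-tree body bits, zero-padded
to a byte boundary.  Body bits are packed most-significant-bit first.

Per tree node: one split bit while the node is above the maximum division
depth (at maximum depth a leaf is implied and the bit is omitted); a leaf
is ``[db_index][transform][scale_code][shift_code]`` where the index width
is ``ceil(log2(pool count at that size))`` bits, re-derived from the
header, so the body is self-describing.

The domain payload is stored as ``source_bits``-wide two's-complement
integers whenever every sample is an integer in range (the usual case for
ADC-count records); otherwise as raw IEEE-754 doubles, signalled by a
header flag.  Either way the round trip is exact.
"""

from __future__ import annotations

import json
import struct
from typing import List

import numpy as np

from .codec import CompressedECG, MatchLeaf, RangeNode
from .config import CodecConfig
from .errors import CorruptStreamError, EncodingError, FormatError, VersionError

__all__ = ["serialize", "deserialize", "bit_cost", "inspect"]

MAGIC = b"SCYF"
VERSION = 1

_HEADER_FMT = "<4sBdIBdHHBBHHdBddBddIII"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)

_FLAG_HALVED = 1
_FLAG_LOSSLESS = 2
_FLAG_FLOAT_PAYLOAD = 4
_FLAG_SMOOTH = 8


class _BitWriter:
    """MSB-first bit packer."""

    def __init__(self) -> None:
        self._bytes = bytearray()
        self._acc = 0
        self._nbits = 0

    def write(self, value: int, nbits: int) -> None:
        if nbits == 0:
            if value:
                raise EncodingError("zero-width field must carry value 0")
            return
        if value < 0 or value >= (1 << nbits):
            raise EncodingError(f"value {value} does not fit in {nbits} bits")
        self._acc = (self._acc << nbits) | value
        self._nbits += nbits
        while self._nbits >= 8:
            self._nbits -= 8
            self._bytes.append((self._acc >> self._nbits) & 0xFF)
        self._acc &= (1 << self._nbits) - 1

    def write_float64(self, value: float) -> None:
        (u,) = struct.unpack(">Q", struct.pack(">d", value))
        self.write(u, 64)

    def getvalue(self) -> bytes:
        if self._nbits:  # zero-pad to a byte boundary
            pad = 8 - self._nbits
            self._acc <<= pad
            self._bytes.append(self._acc & 0xFF)
            self._acc, self._nbits = 0, 0
        return bytes(self._bytes)


class _BitReader:
    """MSB-first bit unpacker; raises on exhaustion."""

    def __init__(self, data: bytes) -> None:
        self._data = data
        self._pos = 0  # bit position

    def read(self, nbits: int) -> int:
        if nbits == 0:
            return 0
        end = self._pos + nbits
        if end > 8 * len(self._data):
            raise CorruptStreamError("stream truncated mid-body")
        value = 0
        pos = self._pos
        while nbits:
            byte = self._data[pos >> 3]
            avail = 8 - (pos & 7)
            take = min(avail, nbits)
            shift = avail - take
            value = (value << take) | ((byte >> shift) & ((1 << take) - 1))
            pos += take
            nbits -= take
        self._pos = pos
        return value

    def read_float64(self) -> float:
        (v,) = struct.unpack(">d", struct.pack(">Q", self.read(64)))
        return v


def _index_bits(count: int) -> int:
    return (count - 1).bit_length()


def _pool_counts(domain_length: int, config: CodecConfig) -> dict:
    return {
        L: (domain_length - L) // config.jump_step + 1 for L in config.leaf_sizes()
    }


def _check_range(name: str, value: int, nbits: int) -> int:
    if not 0 <= value < (1 << nbits):
        raise EncodingError(f"{name}={value} exceeds its {nbits}-bit field")
    return value


def _payload_is_integral(payload: np.ndarray, source_bits: int) -> bool:
    lo, hi = -(1 << (source_bits - 1)), (1 << (source_bits - 1)) - 1
    return bool(
        np.all(payload == np.round(payload))
        and payload.min() >= lo
        and payload.max() <= hi
    )


def serialize(c: CompressedECG) -> bytes:
    """Deterministic byte encoding of a compressed ECG."""
    cfg = c.config
    payload = np.asarray(c.domain_payload, dtype=np.float64)
    float_payload = not _payload_is_integral(payload, c.source_bits)

    flags = 0
    if cfg.domain_halved:
        flags |= _FLAG_HALVED
    if cfg.lossless_coeffs:
        flags |= _FLAG_LOSSLESS
    if float_payload:
        flags |= _FLAG_FLOAT_PAYLOAD
    if cfg.smooth:
        flags |= _FLAG_SMOOTH

    header = struct.pack(
        _HEADER_FMT,
        MAGIC,
        VERSION,
        c.fs,
        _check_range("n_samples", c.n_samples, 32),
        _check_range("source_bits", c.source_bits, 8),
        c.dc_value,
        _check_range("block_size", cfg.block_size, 16),
        _check_range("jump_step", cfg.jump_step, 16),
        _check_range("max_divisions", cfg.max_divisions, 8),
        flags,
        _check_range("extension", cfg.extension, 16),
        _check_range("smooth_span", cfg.smooth_span, 16),
        cfg.frms_limit,
        _check_range("scale_bits", cfg.scale_bits, 8),
        cfg.scale_range[0],
        cfg.scale_range[1],
        _check_range("shift_bits", cfg.shift_bits, 8),
        c.shift_range[0],
        c.shift_range[1],
        _check_range("domain_start", c.domain_start, 32),
        _check_range("domain_end", c.domain_end, 32),
        _check_range("payload_len", len(payload), 32),
    )

    w = _BitWriter()
    if float_payload:
        for v in payload:
            w.write_float64(float(v))
    else:
        b = c.source_bits
        mask = (1 << b) - 1
        for v in payload:
            w.write(int(round(v)) & mask, b)  # two's complement

    counts = _pool_counts(c.domain_end - c.domain_start, cfg)

    def write_node(node: RangeNode, size: int, depth: int) -> None:
        if depth < cfg.max_divisions:
            w.write(0 if node.is_leaf else 1, 1)
        elif not node.is_leaf:
            raise EncodingError("split node below the maximum division depth")
        if node.is_leaf:
            leaf = node.leaf
            nbits = _index_bits(counts[size])
            if leaf.db_index >= counts[size]:
                raise EncodingError("leaf db_index exceeds pool count")
            w.write(leaf.db_index, nbits)
            w.write(leaf.transform & 1, 1)
            if cfg.lossless_coeffs:
                w.write_float64(float(leaf.scale_code))
                w.write_float64(float(leaf.shift_code))
            else:
                w.write(_check_range("scale_code", leaf.scale_code, cfg.scale_bits),
                        cfg.scale_bits)
                w.write(_check_range("shift_code", leaf.shift_code, cfg.shift_bits),
                        cfg.shift_bits)
        else:
            left, right = node.children
            write_node(left, size // 2, depth + 1)
            write_node(right, size // 2, depth + 1)

    for tree in c.trees:
        write_node(tree, cfg.block_size, 0)

    return header + w.getvalue()


def deserialize(data: bytes) -> CompressedECG:
    """Exact inverse of :func:`serialize`; the body is decoded using pool
    counts re-derived from the header, with no external state."""
    if len(data) < 5 or data[:4] != MAGIC:
        raise FormatError("not a SCYF container (bad magic)")
    if data[4] != VERSION:
        raise VersionError(f"unsupported container version {data[4]}")
    if len(data) < _HEADER_SIZE:
        raise CorruptStreamError("stream truncated inside the header")
    (
        _magic, _version, fs, n_samples, source_bits, dc,
        block_size, jump_step, max_divisions, flags, extension, smooth_span,
        frms_limit, scale_bits, scale_min, scale_max,
        shift_bits, shift_min, shift_max,
        domain_start, domain_end, payload_len,
    ) = struct.unpack_from(_HEADER_FMT, data)

    cfg = CodecConfig(
        block_size=block_size,
        jump_step=jump_step,
        frms_limit=frms_limit,
        max_divisions=max_divisions,
        smooth=bool(flags & _FLAG_SMOOTH),
        smooth_span=smooth_span,
        domain_halved=bool(flags & _FLAG_HALVED),
        extension=extension,
        scale_bits=scale_bits,
        scale_range=(scale_min, scale_max),
        shift_bits=shift_bits,
        lossless_coeffs=bool(flags & _FLAG_LOSSLESS),
    )

    r = _BitReader(data[_HEADER_SIZE:])
    if flags & _FLAG_FLOAT_PAYLOAD:
        payload = np.array([r.read_float64() for _ in range(payload_len)])
    else:
        sign = 1 << (source_bits - 1)
        full = 1 << source_bits
        raw = [r.read(source_bits) for _ in range(payload_len)]
        payload = np.array([v - full if v & sign else v for v in raw], dtype=np.float64)

    counts = _pool_counts(domain_end - domain_start, cfg)

    def read_node(size: int, depth: int) -> RangeNode:
        split = bool(r.read(1)) if depth < max_divisions else False
        if split:
            left = read_node(size // 2, depth + 1)
            right = read_node(size // 2, depth + 1)
            return RangeNode(depth=depth, children=(left, right))
        db_index = r.read(_index_bits(counts[size]))
        transform = r.read(1)
        if cfg.lossless_coeffs:
            scale_code: float = r.read_float64()
            shift_code: float = r.read_float64()
        else:
            scale_code = r.read(scale_bits)
            shift_code = r.read(shift_bits)
        leaf = MatchLeaf(
            size=size, db_index=db_index, scale_code=scale_code,
            shift_code=shift_code, transform=transform, frms=float("nan"),
        )
        return RangeNode(depth=depth, leaf=leaf)

    n_ext = n_samples + 2 * extension
    n_trees = -(-n_ext // block_size)
    trees: List[RangeNode] = [read_node(block_size, 0) for _ in range(n_trees)]

    return CompressedECG(
        fs=fs,
        n_samples=n_samples,
        source_bits=source_bits,
        dc_value=dc,
        config=cfg,
        shift_range=(shift_min, shift_max),
        domain_payload=payload,
        domain_start=domain_start,
        domain_end=domain_end,
        trees=trees,
    )


def bit_cost(c: CompressedECG) -> int:
    """Exact size of the serialized stream in bits (header + domain payload
    + body + byte padding)."""
    return 8 * len(serialize(c))


def inspect(c: CompressedECG) -> dict:
    """JSON-friendly summary of a compressed ECG: header fields plus
    per-tree leaf counts and depths (for debugging)."""
    cfg = c.config
    return {
        "fs": c.fs,
        "n_samples": c.n_samples,
        "source_bits": c.source_bits,
        "dc_value": c.dc_value,
        "block_size": cfg.block_size,
        "jump_step": cfg.jump_step,
        "frms_limit": cfg.frms_limit,
        "max_divisions": cfg.max_divisions,
        "domain_halved": cfg.domain_halved,
        "extension": cfg.extension,
        "smooth": cfg.smooth,
        "lossless_coeffs": cfg.lossless_coeffs,
        "domain_window": [c.domain_start, c.domain_end],
        "domain_payload_len": int(len(c.domain_payload)),
        "shift_range": list(c.shift_range),
        "n_trees": len(c.trees),
        "leaves_per_tree": [sum(1 for _ in t.iter_leaves()) for t in c.trees],
        "max_depth_per_tree": [t.max_depth() for t in c.trees],
        "total_bits": bit_cost(c),
    }


def inspect_json(c: CompressedECG) -> str:
    return json.dumps(inspect(c), indent=2)
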