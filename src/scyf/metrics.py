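"""Compression efficiency and reconstruction fidelity measures.

Efficiency: ``avL`` (average value length, stream bits per original
sample) and ``CF`` (compression factor, original bits over compressed
bits).  Distortion: ``PRD``/``PRDN`` (percentage RMS difference without /
with mean removal in the denominator — PRDN is the offset-invariant,
honest variant), ``MSE``, ``SNR`` (mean-removed signal energy over error
energy, in dB, so that ``SNR = -20 log10(PRDN/100)`` holds exactly),
``MAX`` (largest absolute sample error), ``STDERR`` (population standard
deviation of the error) and the combined quality score ``QS = CF / PRDN``.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "QualityReport",
    "avl",
    "cf",
    "prd",
    "prdn",
    "mse",
    "snr",
    "max_err",
    "stderr",
    "qs",
    "quality_report",
]


def _as_pair(x, xr):
    x = np.asarray(x, dtype=np.float64)
    xr = np.asarray(xr, dtype=np.float64)
    if x.shape != xr.shape or x.ndim != 1:
        raise InvalidInputError("signals must be 1-D arrays of equal length")
    if len(x) < 2:
        raise InvalidInputError("metrics need at least two samples")
    return x, xr


def avl(total_bits: float, n: int) -> float:
    """Average value length: stream bits per original sample (bps)."""
    if n < 1:
        raise InvalidInputError("sample count must be >= 1")
    return total_bits / n


def cf(original_bits: float, compressed_bits: float) -> float:
    """Compression factor (a.k.a. compression ratio)."""
    if compressed_bits <= 0:
        raise InvalidInputError("compressed size must be positive")
    return original_bits / compressed_bits


def prd(x, xr) -> float:
    """Percentage RMS difference, no mean removal (inflatable by DC)."""
    x, xr = _as_pair(x, xr)
    denom = float(x @ x)
    if denom == 0.0:
        raise InvalidInputError("PRD undefined for an all-zero signal")
    e = x - xr
    return 100.0 * math.sqrt(float(e @ e) / denom)


def prdn(x, xr) -> float:
    """Normalized percentage RMS difference (mean-removed denominator)."""
    x, xr = _as_pair(x, xr)
    x0 = x - x.mean()
    denom = float(x0 @ x0)
    if denom == 0.0:
        raise InvalidInputError("PRDN undefined for a constant signal")
    e = x - xr
    return 100.0 * math.sqrt(float(e @ e) / denom)


def mse(x, xr) -> float:
    x, xr = _as_pair(x, xr)
    e = x - xr
    return float(e @ e) / len(e)


def snr(x, xr) -> float:
    """Signal-to-noise ratio in dB, mean-removed signal energy over error
    energy; +inf for a perfect reconstruction."""
    x, xr = _as_pair(x, xr)
    x0 = x - x.mean()
    e = x - xr
    err = float(e @ e)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(float(x0 @ x0) / err)


def max_err(x, xr) -> float:
    x, xr = _as_pair(x, xr)
    return float(np.abs(x - xr).max())


def stderr(x, xr) -> float:
    """Population (1/n) standard deviation of the error signal."""
    x, xr = _as_pair(x, xr)
    return float(np.std(x - xr))


def qs(cf_value: float, prdn_value: float) -> float:
    """Quality score: compression factor per percent of distortion."""
    if prdn_value == 0.0:
        return math.inf
    return cf_value / prdn_value


@dataclass
class QualityReport:
    """The full metric battery for one (original, reconstructed, stream
    size) triple."""

    n: int
    source_bits: int
    total_bits: int
    avl: float
    cf: float
    prd: float
    prdn: float
    mse: float
    snr: float
    max_err: float
    stderr: float
    qs: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        d = {k: ("Infinity" if v == math.inf else v) for k, v in self.to_dict().items()}
        return json.dumps(d, **kw)

    def to_csv_row(self, header: bool = False) -> str:
        buf = _io.StringIO()
        writer = csv.writer(buf)
        d = self.to_dict()
        if header:
            writer.writerow(d.keys())
        writer.writerow(d.values())
        return buf.getvalue()


def quality_report(x, xr, total_bits: int, source_bits: int) -> QualityReport:
    """Compute every efficiency and distortion metric at once."""
    x, xr = _as_pair(x, xr)
    n = len(x)
    avl_v = avl(total_bits, n)
    cf_v = cf(source_bits * n, total_bits)
    prdn_v = prdn(x, xr)
    return QualityReport(
        n=n,
        source_bits=source_bits,
        total_bits=int(total_bits),
        avl=avl_v,
        cf=cf_v,
        prd=prd(x, xr),
        prdn=prdn_v,
        mse=mse(x, xr),
        snr=snr(x, xr),
        max_err=max_err(x, xr),
        stderr=stderr(x, xr),
        qs=qs(cf_v, prdn_v),
    )
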