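"""Reading and writing single-lead ECG records.

This build reads and writes plain-text CSV (one sample per line, optional
header line, decimal point, selectable column) with the sampling frequency
and source bit resolution supplied by the caller, plus an optional JSON
sidecar carrying those and the P-onset annotations.  WFDB binary records
are recognised but not read by this build.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, UnsupportedFormatError

__all__ = ["EcgRecord", "read_record", "write_csv", "read_sidecar", "write_sidecar"]


@dataclass
class EcgRecord:
    samples: np.ndarray
    fs: float
    source_bits: int
    units: str = "adu"
    record_id: str = ""
    lead: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ConfigurationError("sampling frequency must be > 0")
        if not 8 <= self.source_bits <= 32:
            raise ConfigurationError("source_bits must be in 8..32")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("record contains non-finite samples")


def read_record(
    path,
    format: str = "csv",
    fs: Optional[float] = None,
    source_bits: Optional[int] = None,
    column: int = 0,
    record_id: str = "",
    lead: str = "",
) -> EcgRecord:
    """Load one lead from a CSV file.

    ``fs`` and ``source_bits`` are required for CSV (they are not carried
    by the format); ``column`` selects the lead in multi-column files.
    """
    path = Path(path)
    if format == "wfdb":
        raise UnsupportedFormatError(
            "WFDB reading is not included in this build; export the lead "
            "to CSV (one sample per line) and pass --fs/--bits"
        )
    if format != "csv":
        raise UnsupportedFormatError(f"unknown format {format!r}")
    if fs is None or source_bits is None:
        raise ConfigurationError("CSV input requires fs and source_bits")

    rows: List[List[str]] = []
    first = True
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(";", ",").split(",")
            if first:
                first = False
                try:
                    [float(f) for f in fields]
                except ValueError:
                    continue  # header line
            rows.append(fields)
    if not rows:
        raise InvalidInputError(f"no samples found in {path}")
    ncol = len(rows[0])
    if not 0 <= column < ncol:
        raise InvalidInputError(f"column {column} not present (file has {ncol})")
    try:
        samples = np.array([float(r[column]) for r in rows])
    except ValueError as exc:
        raise InvalidInputError(f"non-numeric sample value: {exc}") from None
    return EcgRecord(
        samples=samples,
        fs=fs,
        source_bits=source_bits,
        record_id=record_id or path.stem,
        lead=lead or str(column),
    )


def write_csv(path, samples: Sequence[float]) -> None:
    """One sample per line, full double precision (round-trips exactly)."""
    np.savetxt(path, np.asarray(samples, dtype=np.float64), fmt="%.17g")


def write_sidecar(path, payload: dict) -> None:
    """JSON sidecar (provenance, spec, onsets) next to a CSV output."""
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
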