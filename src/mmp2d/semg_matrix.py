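"""One-dimensional SEMG records and their two-dimensional (column-per-segment) form.

A surface-EMG record is a sequence of integer samples (nominally 12-bit,
zero-centered at load time).  For two-dimensional compression the record is
split into consecutive segments of ``segment_length`` samples and each segment
becomes one matrix column; the trailing shortfall is padded.  The original
sample count is kept so the inverse mapping is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SemgRecord",
    "SemgMatrix",
    "segment_to_matrix",
    "matrix_to_record",
    "square_segment_length",
    "read_raw",
    "write_raw",
    "read_text",
    "write_text",
    "write_pgm",
]

#: pad value for the trailing partial segment (signals are zero-centered,
#: so zeros inject the least energy into the last column)
PAD_VALUE = 0


@dataclass
class SemgRecord:
    """An integer-sampled SEMG record.

    Parameters
    ----------
    samples
        Signed integer samples, zero-centered (the acquisition offset has
        already been subtracted).
    sampling_rate_hz
        Acquisition rate in Hz.
    bit_depth
        Quantizer resolution in bits (default 12).
    offset
        Integer subtracted at load time so that samples are zero-centered
        (e.g. 2048 for an unsigned 12-bit acquisition).  It is re-applied on
        export to unsigned formats and travels in the coded-file header.
    """

    samples: np.ndarray
    sampling_rate_hz: float = 2000.0
    bit_depth: int = 12
    offset: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("empty signal")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit depth must be positive")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class SemgMatrix:
    """A K×L integer matrix holding one record segment per column."""

    values: np.ndarray
    original_sample_count: int
    pad_value: int = PAD_VALUE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("matrix must be two-dimensional")
        k, l = self.values.shape
        if self.original_sample_count > k * l:
            raise ValueError("original_sample_count exceeds matrix capacity")

    @property
    def segment_length(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_segments(self) -> int:
        return int(self.values.shape[1])


def square_segment_length(n_samples: int) -> int:
    """Segment length K giving an (as square as padding allows) K×L matrix.

    Returns ``ceil(sqrt(n_samples))`` so that L ∈ {K−1, K}.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    return math.isqrt(n_samples - 1) + 1


def segment_to_matrix(record: SemgRecord, segment_length: int) -> SemgMatrix:
    """Rearrange a record into a column-per-segment matrix.

    Column ``c``, row ``r`` holds sample ``c*segment_length + r``; the trailing
    shortfall of the last column is filled with :data:`PAD_VALUE`.
    """
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    x = record.samples
    n = x.size
    if n < 1:
        raise ValueError("empty signal")
    k = segment_length
    l = -(-n // k)
    padded = np.full(k * l, PAD_VALUE, dtype=np.int64)
    padded[:n] = x
    values = padded.reshape(l, k).T
    meta = {
        "sampling_rate_hz": record.sampling_rate_hz,
        "bit_depth": record.bit_depth,
        "offset": record.offset,
    }
    return SemgMatrix(values=values, original_sample_count=n, meta=meta)


def matrix_to_record(matrix: SemgMatrix, meta: dict | None = None) -> SemgRecord:
    """Concatenate columns and truncate to the original sample count."""
    n = matrix.original_sample_count
    flat = matrix.values.T.reshape(-1)
    if n > flat.size:
        raise ValueError("original_sample_count exceeds matrix capacity")
    m = dict(matrix.meta)
    if meta:
        m.update(meta)
    return SemgRecord(
        samples=flat[:n].copy(),
        sampling_rate_hz=float(m.get("sampling_rate_hz", 2000.0)),
        bit_depth=int(m.get("bit_depth", 12)),
        offset=int(m.get("offset", 0)),
    )


# ---------------------------------------------------------------------------
# Raw-signal file dialects
# ---------------------------------------------------------------------------

def read_raw(path, sampling_rate_hz: float = 2000.0, bit_depth: int = 12,
             offset: int = 0) -> SemgRecord:
    """Read a little-endian signed 16-bit raw file; ``offset`` is subtracted."""
    data = np.fromfile(str(path), dtype="<i2").astype(np.int64)
    if data.size == 0:
        raise ValueError("empty signal")
    return SemgRecord(data - offset, sampling_rate_hz, bit_depth, offset)


def write_raw(path, record: SemgRecord) -> None:
    """Write the record as little-endian signed int16 (offset re-applied)."""
    out = record.samples + record.offset
    lo, hi = np.iinfo(np.int16).min, np.iinfo(np.int16).max
    if out.min() < lo or out.max() > hi:
        raise ValueError("samples do not fit in int16")
    out.astype("<i2").tofile(str(path))


def read_text(path, sampling_rate_hz: float = 2000.0, bit_depth: int = 12,
              offset: int = 0) -> SemgRecord:
    """Read the one-integer-per-line text dialect."""
    data = np.loadtxt(str(path), dtype=np.int64, ndmin=1)
    if data.size == 0:
        raise ValueError("empty signal")
    return SemgRecord(data - offset, sampling_rate_hz, bit_depth, offset)


def write_text(path, record: SemgRecord) -> None:
    out = record.samples + record.offset
    Path(path).write_text("\n".join(str(int(v)) for v in out) + "\n")


def write_pgm(path, matrix: SemgMatrix, offset: int | None = None) -> None:
    """Export the matrix as a 16-bit binary PGM (P5, maxval 65535).

    The amplitude offset is re-applied so values are nonnegative, as expected
    by external image codecs; out-of-range values are clipped.  PGM stores
    16-bit samples most-significant byte first.
    """
    if offset is None:
        offset = int(matrix.meta.get("offset", 0))
        if offset == 0:
            bit_depth = int(matrix.meta.get("bit_depth", 12))
            offset = 1 << (bit_depth - 1)
    vals = np.clip(matrix.values + offset, 0, 65535).astype(">u2")
    k, l = vals.shape
    with open(str(path), "wb") as fh:
        fh.write(f"P5\n{l} {k}\n65535\n".encode("ascii"))
        fh.write(vals.tobytes())
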