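"""End-to-end compression pipeline: matrix formation, preprocessing, codec.

The encoder runs in three stages — matrix formation, preprocessing and image
compression — and the decoder undoes them in reverse order.  With PDS a
square segment length is fixed first and the column permutation joins the
header; with SbS the segment length itself is adapted to the signal so the
first two stages collapse into one; with no preprocessing the square matrix
goes straight to the codec.
"""

from __future__ import annotations

import numpy as np

from . import entropy, mmp_core
from .preprocess import (
    PreprocessPlan,
    SegmentOrdering,
    pds_restore,
    pds_sort,
    sbs_select_length,
)
from .semg_matrix import (
    SemgMatrix,
    SemgRecord,
    matrix_to_record,
    segment_to_matrix,
    square_segment_length,
)

__all__ = ["make_plan", "apply_plan", "compress_record", "decompress"]


def make_plan(record: SemgRecord, method: str = "none",
              segment_length: int | None = None) -> PreprocessPlan:
    """Choose the segment length (and ordering slot) for a record."""
    if method not in ("none", "pds", "sbs"):
        raise ValueError(f"unknown preprocessing method {method!r}")
    if method == "sbs":
        k = sbs_select_length(record) if segment_length is None else segment_length
    else:
        k = square_segment_length(len(record)) if segment_length is None \
            else segment_length
    return PreprocessPlan(method=method, segment_length=k)


def apply_plan(record: SemgRecord, plan: PreprocessPlan) -> SemgMatrix:
    """Matrix formation + preprocessing; fills in the PDS ordering."""
    matrix = segment_to_matrix(record, plan.segment_length)
    if plan.method == "pds":
        matrix, ordering = pds_sort(matrix)
        plan.ordering = ordering
    return matrix


def compress_record(record: SemgRecord, lam: float, method: str = "none",
                    segment_length: int | None = None,
                    config: mmp_core.MmpConfig | None = None
                    ) -> tuple[entropy.CodedHeader, bytes]:
    """Full encoder: preprocess, MMP-code, and assemble the header."""
    config = config or mmp_core.MmpConfig()
    plan = make_plan(record, method, segment_length)
    matrix = apply_plan(record, plan)
    _, _, payload, x_max = mmp_core.encode_matrix(matrix.values, lam, config)
    header = entropy.CodedHeader(
        n_samples=len(record),
        offset=record.offset,
        x_max=x_max,
        segment_length=plan.segment_length,
        preprocess=plan.method,
        lam=float(lam),
        n_rows=matrix.segment_length,
        n_cols=matrix.n_segments,
        sampling_rate_hz=record.sampling_rate_hz,
        bit_depth=record.bit_depth,
        dict_cap=config.dict_cap,
        additive_symmetric=config.additive_symmetric,
        permutation=None if plan.ordering is None else plan.ordering.permutation,
    )
    return header, payload


def decompress(header: entropy.CodedHeader, payload: bytes) -> SemgRecord:
    """Full decoder: MMP-decode, undo preprocessing, rebuild the record."""
    config = mmp_core.MmpConfig(dict_cap=header.dict_cap,
                                additive_symmetric=header.additive_symmetric)
    values = mmp_core.decode_matrix(payload, header.n_rows, header.n_cols,
                                    header.x_max, header.lam, config)
    matrix = SemgMatrix(values=values,
                        original_sample_count=header.n_samples,
                        meta={"sampling_rate_hz": header.sampling_rate_hz,
                              "bit_depth": header.bit_depth,
                              "offset": header.offset})
    if header.preprocess == "pds":
        matrix = pds_restore(matrix, SegmentOrdering(header.permutation))
    return matrix_to_record(matrix)


def compress_to_file(path, record: SemgRecord, lam: float,
                     method: str = "none", segment_length: int | None = None,
                     config: mmp_core.MmpConfig | None = None
                     ) -> entropy.CodedHeader:
    header, payload = compress_record(record, lam, method, segment_length, config)
    entropy.write_container(path, header, payload)
    return header


def decompress_file(path) -> SemgRecord:
    header, payload = entropy.read_container(path)
    return decompress(header, payload)
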