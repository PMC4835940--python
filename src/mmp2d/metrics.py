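"""Distortion/rate metrics and rate-distortion sweeps.

Reconstruction quality is the percent root-mean-square difference

    PRD = 100 * sqrt( Σ (x[i] − x̂[i])² / Σ x²[i] )

computed on the restored one-dimensional signal (after un-preprocessing),
with no mean removal.  Compression is the compression factor

    CF = 100 * (B_o − B_c) / B_o,      B_o = bit_depth * n  (12 n nominally)

where B_c is the container size in bits, byte padding and side information
included.  The bitrate is steered indirectly through the Lagrangian
multiplier λ, so a sweep runs the full pipeline once per grid point.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import entropy, pipeline
from .mmp_core import MmpConfig
from .semg_matrix import SemgRecord

__all__ = ["RdPoint", "prd", "cf", "rd_sweep", "sweep_to_csv",
           "DEFAULT_LAMBDA_GRID", "plot_rd"]

#: default λ grid for sweeps; spans every redundancy-threshold branch
DEFAULT_LAMBDA_GRID = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)


@dataclass
class RdPoint:
    """One operating point of the rate-distortion trade-off."""

    lam: float
    cf_percent: float
    prd_percent: float
    bits: int


def prd(x: np.ndarray, xhat: np.ndarray) -> float:
    """Percent root-mean-square difference between original and decoded."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape or x.ndim != 1:
        raise ValueError("signals must be equal-length 1-D vectors")
    energy = float(np.dot(x, x))
    if energy == 0.0:
        raise ValueError("zero-energy original signal")
    d = x - xhat
    return 100.0 * float(np.sqrt(np.dot(d, d) / energy))


def cf(b_original: int, b_compressed: int) -> float:
    """Compression factor in percent; negative means expansion."""
    if b_original <= 0:
        raise ValueError("original size must be positive")
    return 100.0 * (b_original - b_compressed) / b_original


def _container_bits(header: entropy.CodedHeader, payload: bytes) -> int:
    buf = tempfile.NamedTemporaryFile(suffix=".mmp2d", delete=False)
    try:
        buf.close()
        entropy.write_container(buf.name, header, payload)
        return os.path.getsize(buf.name) * 8
    finally:
        os.unlink(buf.name)


def rd_sweep(record: SemgRecord, method: str = "none",
             lambdas=DEFAULT_LAMBDA_GRID,
             segment_length: int | None = None,
             config: MmpConfig | None = None) -> list[RdPoint]:
    """Run the full pipeline once per λ and measure (CF, PRD).

    B_c is the complete container size in bits (header, permutation and
    payload); results are sorted by CF.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("empty lambda grid")
    n = len(record)
    b_o = record.bit_depth * n
    points = []
    for lam in lambdas:
        header, payload = pipeline.compress_record(
            record, lam, method, segment_length, config)
        bits = _container_bits(header, payload)
        decoded = pipeline.decompress(header, payload)
        points.append(RdPoint(
            lam=float(lam),
            cf_percent=cf(b_o, bits),
            prd_percent=prd(record.samples, decoded.samples),
            bits=bits,
        ))
    points.sort(key=lambda p: p.cf_percent)
    return points


def find_lambda_for_cf(record: SemgRecord, target_cf: float,
                       method: str = "none",
                       config: MmpConfig | None = None,
                       lo: float = 0.0, hi: float = 512.0,
                       iters: int = 10) -> tuple[float, RdPoint]:
    """Bisection on λ toward a target compression factor."""
    best = None
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pt = rd_sweep(record, method, [mid], config=config)[0]
        if best is None or abs(pt.cf_percent - target_cf) < abs(
                best[1].cf_percent - target_cf):
            best = (mid, pt)
        if pt.cf_percent < target_cf:
            lo = mid
        else:
            hi = mid
    return best


def sweep_to_csv(points: list[RdPoint], path=None) -> pd.DataFrame:
    """Tabulate sweep results (λ, bits, CF %, PRD %); optionally save CSV."""
    df = pd.DataFrame(
        [(p.lam, p.bits, p.cf_percent, p.prd_percent) for p in points],
        columns=["lambda", "bits", "cf_percent", "prd_percent"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def plot_rd(points: list[RdPoint], path, label: str = "MMP-2D") -> None:
    """Save a PRD×CF curve (matplotlib imported on demand)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pts = sorted(points, key=lambda p: p.cf_percent)
    ax.plot([p.cf_percent for p in pts], [p.prd_percent for p in pts],
            marker="o", label=label)
    ax.set_xlabel("CF (%)")
    ax.set_ylabel("PRD (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
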