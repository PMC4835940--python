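"""Hierarchical intra prediction for SEMG images.

The predictor mirrors the HEVC intra toolbox: 33 angular modes (ids 2–34, the
standard displacement table, 1/32-sample linear interpolation), a planar mode
(id 0, average of one horizontal and one vertical linear interpolation) and a
most-frequent-value mode (id 1, the modal reference sample replicated — the
MMP lineage's replacement for the DC mode).  Predictions are built from two
reference vectors of previously reconstructed samples:

* the *vertical* vector (corner, left column, below-left) serves the
  horizontal-ish angular modes 2–17;
* the *horizontal* vector (corner, above row, above-right) serves the
  vertical-ish angular modes 18–34.

Mode availability is gated by block scale: no prediction at scales 1–3, planar
only at the square scales 4, 9, 16 and 25.  Reference smoothing is not applied
(SEMG images are noise-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLANAR",
    "MFV",
    "NO_PRED",
    "ANGULAR_MODES",
    "PLANAR_SCALES",
    "ReferenceVectors",
    "allowed_modes",
    "build_reference_vectors",
    "predict_block",
    "residual",
    "intra_pred_angle",
]

PLANAR = 0
MFV = 1
#: explicit "code the raw block, no prediction" mode (bitstream grammar needs
#: the mode slot to be decodable; see docs/methods.md)
NO_PRED = 35

ANGULAR_MODES = tuple(range(2, 35))
#: scales where the planar mode is available (the square dims 2x2..16x16)
PLANAR_SCALES = frozenset({4, 9, 16, 25})

# HEVC intra displacement table, indexed by mode id 2..34 (units: 1/32 sample
# per row/column). Modes 2..17 are horizontal-family, 18..34 vertical-family.
_ANGLES = {
    2: 32, 3: 26, 4: 21, 5: 17, 6: 13, 7: 9, 8: 5, 9: 2, 10: 0,
    11: -2, 12: -5, 13: -9, 14: -13, 15: -17, 16: -21, 17: -26,
    18: -32, 19: -26, 20: -21, 21: -17, 22: -13, 23: -9, 24: -5, 25: -2,
    26: 0, 27: 2, 28: 5, 29: 9, 30: 13, 31: 17, 32: 21, 33: 26, 34: 32,
}


def intra_pred_angle(mode: int) -> int:
    """Displacement (1/32-sample units) of an angular mode."""
    return _ANGLES[mode]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x).astype(np.int64)


def allowed_modes(scale: int) -> frozenset[int]:
    """Prediction modes usable at a dictionary scale.

    Scales 1–3: empty (blocks too small for prediction to pay off).
    Scales ≥ 4: MFV plus all 33 angular modes; planar additionally at the
    square scales 4, 9, 16, 25.
    """
    if not 1 <= scale <= 25:
        raise ValueError(f"scale {scale} outside [1, 25]")
    if scale <= 3:
        return frozenset()
    modes = {MFV, *ANGULAR_MODES}
    if scale in PLANAR_SCALES:
        modes.add(PLANAR)
    return frozenset(modes)


@dataclass
class ReferenceVectors:
    """Reconstructed-sample references for one block.

    ``vertical[0]`` and ``horizontal[0]`` are both the top-left corner sample;
    ``vertical[1:]`` runs down the left edge into the below-left region and
    ``horizontal[1:]`` runs across the top edge into the above-right region.
    Each has length ``2*max(M, N) + 1``.
    """

    vertical: np.ndarray
    horizontal: np.ndarray


def build_reference_vectors(reconstruction: np.ndarray, mask: np.ndarray,
                            origin: tuple[int, int], dims: tuple[int, int]
                            ) -> ReferenceVectors:
    """Assemble the two reference vectors for the block at ``origin``.

    ``mask`` marks already-reconstructed samples.  Unavailable references are
    substituted HEVC-style: scanning from the below-left end through the corner
    to the above-right end, leading gaps take the first available sample and
    later gaps propagate the previous value; if nothing is available the
    references are all zero (the data is zero-centered).
    """
    r0, c0 = origin
    m, n = dims
    h, w = reconstruction.shape
    ext = 2 * max(m, n)

    def sample(r: int, c: int) -> tuple[int, bool]:
        if 0 <= r < h and 0 <= c < w and mask[r, c]:
            return int(reconstruction[r, c]), True
        return 0, False

    # scan order: below-left end -> up the left edge -> corner -> across the
    # top edge -> above-right end
    seq_vals = np.zeros(2 * ext + 1, dtype=np.int64)
    seq_ok = np.zeros(2 * ext + 1, dtype=bool)
    for i in range(ext):  # left edge, bottom-most first
        r = r0 + (ext - 1 - i)
        seq_vals[i], seq_ok[i] = sample(r, c0 - 1)
    seq_vals[ext], seq_ok[ext] = sample(r0 - 1, c0 - 1)  # corner
    for i in range(ext):  # top edge, left-most first
        seq_vals[ext + 1 + i], seq_ok[ext + 1 + i] = sample(r0 - 1, c0 + i)

    if seq_ok.any():
        first = int(np.flatnonzero(seq_ok)[0])
        seq_vals[:first] = seq_vals[first]
        for i in range(first + 1, seq_vals.size):
            if not seq_ok[i]:
                seq_vals[i] = seq_vals[i - 1]
    # else: all zeros already

    vertical = np.empty(ext + 1, dtype=np.int64)
    vertical[0] = seq_vals[ext]          # corner
    vertical[1:] = seq_vals[:ext][::-1]  # down the left edge
    horizontal = seq_vals[ext:].copy()   # corner then across the top
    return ReferenceVectors(vertical=vertical, horizontal=horizontal)


def _predict_angular(refs: ReferenceVectors, mode: int, m: int, n: int
                     ) -> np.ndarray:
    angle = _ANGLES[mode]
    vertical_family = mode >= 18
    if vertical_family:
        main, side = refs.horizontal, refs.vertical
        rows, cols = m, n
    else:  # horizontal family: transpose of the vertical procedure
        main, side = refs.vertical, refs.horizontal
        rows, cols = n, m

    # ref at logical index k >= 0 is main[k] (k = 0 is the corner); negative
    # logical indices are projected onto the side vector via the inverse angle
    lo = (rows * angle) >> 5 if angle < 0 else 0
    ref = np.zeros(2 * max(m, n) + 1 - lo, dtype=np.int64)
    ref[-lo:] = main
    if lo < 0:
        inv = round(8192 / abs(angle))  # HEVC invAngle magnitude
        for x in range(-1, lo - 1, -1):
            # the projection can point past the stored side samples for
            # entries the interpolation never reads; clamp to the last one
            j = min((-x * inv + 128) >> 8, side.size - 1)
            ref[x - lo] = side[j]

    out = np.empty((rows, cols), dtype=np.int64)
    for y in range(rows):
        pos = (y + 1) * angle
        idx, frac = pos >> 5, pos & 31
        base = np.arange(cols) + idx + 1 - lo
        if frac == 0:
            out[y] = ref[base]
        else:
            vals = ((32 - frac) * ref[base] + frac * ref[base + 1]) / 32.0
            out[y] = _round_half_away(vals)
    return out if vertical_family else out.T


def _predict_planar(refs: ReferenceVectors, m: int, n: int) -> np.ndarray:
    top = refs.horizontal[1: n + 1].astype(np.float64)
    left = refs.vertical[1: m + 1].astype(np.float64)
    top_right = float(refs.horizontal[n + 1]) if refs.horizontal.size > n + 1 \
        else float(refs.horizontal[n])
    bottom_left = float(refs.vertical[m + 1]) if refs.vertical.size > m + 1 \
        else float(refs.vertical[m])
    xs = np.arange(n, dtype=np.float64)
    ys = np.arange(m, dtype=np.float64)
    hor = ((n - 1 - xs)[None, :] * left[:, None] + (xs + 1)[None, :] * top_right) / n
    ver = ((m - 1 - ys)[:, None] * top[None, :] + (ys + 1)[:, None] * bottom_left) / m
    return _round_half_away(0.5 * (hor + ver))


def _predict_mfv(refs: ReferenceVectors, m: int, n: int) -> np.ndarray:
    # corner counted once: vertical holds it at index 0
    pool = np.concatenate([refs.vertical, refs.horizontal[1:]])
    vals, counts = np.unique(pool, return_counts=True)
    mode_val = int(vals[np.argmax(counts)])  # ties: smallest value (unique is sorted)
    return np.full((m, n), mode_val, dtype=np.int64)


def predict_block(refs: ReferenceVectors, mode: int, dims: tuple[int, int]
                  ) -> np.ndarray:
    """Predict an M×N integer block from the reference vectors.

    A pure function of (refs, mode, dims) — the decoder reproduces it exactly.
    ``NO_PRED`` yields the all-zero prediction (raw coding).
    """
    m, n = dims
    if mode == NO_PRED:
        return np.zeros((m, n), dtype=np.int64)
    if mode == PLANAR:
        return _predict_planar(refs, m, n)
    if mode == MFV:
        return _predict_mfv(refs, m, n)
    if mode in _ANGLES:
        return _predict_angular(refs, mode, m, n)
    raise ValueError(f"unknown prediction mode {mode}")


def residual(block: np.ndarray, prediction: np.ndarray) -> np.ndarray:
    """Elementwise block − prediction (may be negative)."""
    block = np.asarray(block, dtype=np.int64)
    prediction = np.asarray(prediction, dtype=np.int64)
    if block.shape != prediction.shape:
        raise ValueError("dimension mismatch between block and prediction")
    return block - prediction
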