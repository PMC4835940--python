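"""Symbol serialization, adaptive arithmetic coding and the container format.

The segmentation tree of every coded 16×16 block is flattened to a symbol
string by a pre-order walk using five flags (0 leaf, 1/2 residue splits,
3/4 hierarchical-prediction splits); a leaf is followed by its dictionary
index (partition id, then index within the partition) and a node that starts a
predicted region carries a prediction-mode symbol right after its first flag.

Symbols are entropy-coded by a 32-bit integer adaptive arithmetic coder with
per-context frequency tables (one flag table per scale, one mode table per
scale, one partition table per scale and one index table per (scale,
partition)).  All counts start at 1, increment by 1 and are halved (keeping a
floor of 1) when the total reaches 2^14.  The layer is exactly lossless; the
only loss in the codec is the dictionary approximation itself.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Symbol",
    "FrequencyTable",
    "ArithmeticEncoder",
    "ArithmeticDecoder",
    "arith_encode",
    "arith_decode",
    "serialize_tree",
    "deserialize_tree",
    "CodedHeader",
    "write_container",
    "read_container",
    "MAGIC",
    "VERSION",
]

MAGIC = b"MMP2DSEMG"
VERSION = 1

_RESCALE_TOTAL = 1 << 14
_CODE_BITS = 32
_TOP = (1 << _CODE_BITS) - 1
_HALF = 1 << (_CODE_BITS - 1)
_QUARTER = 1 << (_CODE_BITS - 2)
_THREE_QUARTERS = _HALF + _QUARTER


# ---------------------------------------------------------------------------
# Adaptive model
# ---------------------------------------------------------------------------

class FrequencyTable:
    """Adaptive symbol-frequency table (counts >= 1, growable alphabet)."""

    __slots__ = ("counts", "total")

    def __init__(self, n_symbols: int):
        if n_symbols < 1:
            raise ValueError("alphabet must hold at least one symbol")
        self.counts = np.ones(n_symbols, dtype=np.int64)
        self.total = n_symbols

    def __len__(self) -> int:
        return int(self.counts.size)

    def span(self, symbol: int) -> tuple[int, int, int]:
        """(cumulative low, cumulative high, total) for ``symbol``."""
        lo = int(self.counts[:symbol].sum())
        return lo, lo + int(self.counts[symbol]), self.total

    def locate(self, value: int) -> int:
        """Symbol whose cumulative interval contains ``value``."""
        cum = np.cumsum(self.counts)
        if value >= cum[-1]:
            raise ValueError("cumulative value outside table range")
        return int(np.searchsorted(cum, value, side="right"))

    def update(self, symbol: int) -> None:
        self.counts[symbol] += 1
        self.total += 1
        if self.total >= _RESCALE_TOTAL:
            self.counts = (self.counts + 1) >> 1
            self.total = int(self.counts.sum())

    def add_symbol(self) -> None:
        """Grow the alphabet by one symbol with count 1."""
        self.counts = np.append(self.counts, 1)
        self.total += 1

    def code_lengths(self) -> np.ndarray:
        """-log2 probability of each symbol under the current counts."""
        return -np.log2(self.counts / self.total)


# ---------------------------------------------------------------------------
# 32-bit integer arithmetic coder (Witten-Neal-Cleary style)
# ---------------------------------------------------------------------------

class ArithmeticEncoder:
    def __init__(self):
        self.low = 0
        self.high = _TOP
        self.pending = 0
        self._bits: list[int] = []

    def _emit(self, bit: int) -> None:
        self._bits.append(bit)
        if self.pending:
            self._bits.extend([bit ^ 1] * self.pending)
            self.pending = 0

    def encode(self, cum_lo: int, cum_hi: int, total: int) -> None:
        span = self.high - self.low + 1
        self.high = self.low + span * cum_hi // total - 1
        self.low = self.low + span * cum_lo // total
        while True:
            if self.high < _HALF:
                self._emit(0)
            elif self.low >= _HALF:
                self._emit(1)
                self.low -= _HALF
                self.high -= _HALF
            elif self.low >= _QUARTER and self.high < _THREE_QUARTERS:
                self.pending += 1
                self.low -= _QUARTER
                self.high -= _QUARTER
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1

    def encode_symbol(self, table: FrequencyTable, symbol: int,
                      update: bool = True) -> None:
        self.encode(*table.span(symbol))
        if update:
            table.update(symbol)

    def finish(self) -> bytes:
        """Flush and return the payload, bit-padded to a byte boundary."""
        self.pending += 1
        self._emit(0 if self.low < _QUARTER else 1)
        bits = np.asarray(self._bits, dtype=np.uint8)
        return np.packbits(bits).tobytes()

    @property
    def n_bits(self) -> int:
        return len(self._bits)


class ArithmeticDecoder:
    def __init__(self, payload: bytes):
        bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8))
        self._bits = bits
        self._pos = 0
        self.low = 0
        self.high = _TOP
        self.value = 0
        for _ in range(_CODE_BITS):
            self.value = (self.value << 1) | self._next_bit()

    def _next_bit(self) -> int:
        if self._pos < self._bits.size:
            b = int(self._bits[self._pos])
            self._pos += 1
            return b
        # past the end of the payload: feed zeros (encoder flush guarantees
        # unambiguous termination of the coded symbol sequence)
        self._pos += 1
        return 0

    def decode(self, cum_lo: int, cum_hi: int, total: int) -> None:
        span = self.high - self.low + 1
        self.high = self.low + span * cum_hi // total - 1
        self.low = self.low + span * cum_lo // total
        while True:
            if self.high < _HALF:
                pass
            elif self.low >= _HALF:
                self.low -= _HALF
                self.high -= _HALF
                self.value -= _HALF
            elif self.low >= _QUARTER and self.high < _THREE_QUARTERS:
                self.low -= _QUARTER
                self.high -= _QUARTER
                self.value -= _QUARTER
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1
            self.value = (self.value << 1) | self._next_bit()

    def decode_symbol(self, table: FrequencyTable, update: bool = True) -> int:
        span = self.high - self.low + 1
        target = ((self.value - self.low + 1) * table.total - 1) // span
        symbol = table.locate(target)
        self.decode(*table.span(symbol))
        if update:
            table.update(symbol)
        return symbol


def arith_encode(symbols, table: FrequencyTable) -> bytes:
    """Adaptively encode a flat symbol sequence with one shared table."""
    enc = ArithmeticEncoder()
    for s in symbols:
        enc.encode_symbol(table, int(s))
    return enc.finish()


def arith_decode(payload: bytes, table: FrequencyTable, n_symbols: int) -> list[int]:
    """Inverse of :func:`arith_encode` (table must start in the same state)."""
    dec = ArithmeticDecoder(payload)
    return [dec.decode_symbol(table) for _ in range(n_symbols)]


# ---------------------------------------------------------------------------
# Tree <-> symbol string
# ---------------------------------------------------------------------------

#: symbols are tuples: ("flag", scale, f) | ("mode", scale, m)
#: | ("index", scale, partition, index_within_partition)
Symbol = tuple

_FLAG_OF_KIND = {
    "leaf": 0,
    "vsplit": 1,
    "hsplit": 2,
    "pred_vsplit": 3,
    "pred_hsplit": 4,
}
_KIND_OF_FLAG = {v: k for k, v in _FLAG_OF_KIND.items()}


def serialize_tree(tree) -> list[Symbol]:
    """Flatten a segmentation tree to its symbol string (pre-order).

    For every node the flag comes first; a node that carries a prediction mode
    emits it immediately after its flag; a leaf then emits its dictionary
    index; split nodes emit the left/upper child subtree before the
    right/lower one.
    """
    from .mmp_core import scale_index  # local import; no module cycle at load

    out: list[Symbol] = []

    def walk(node) -> None:
        m, n = node.dims
        s = scale_index(m, n)
        flag = _FLAG_OF_KIND[node.kind]
        out.append(("flag", s, flag))
        if node.kind in ("pred_vsplit", "pred_hsplit"):
            walk(node.children[0])
            walk(node.children[1])
            return
        if node.mode is not None:
            out.append(("mode", s, node.mode))
        if node.kind == "leaf":
            part, idx = node.index
            out.append(("index", s, part, idx))
        else:
            walk(node.children[0])
            walk(node.children[1])

    walk(tree)
    return out


def deserialize_tree(symbols, dims: tuple[int, int], predicted: bool = True):
    """Rebuild a segmentation tree from its symbol string.

    ``predicted`` tells whether the root sits in the original (prediction)
    domain — where every non-split node at a scale with prediction modes
    carries a mode symbol — or inside a residue tree (no modes).
    """
    from .mmp_core import TreeNode, scale_index, MIN_PRED_SPLIT_SCALE
    from .prediction import allowed_modes

    it = iter(symbols)

    def next_symbol(kind: str) -> Symbol:
        try:
            sym = next(it)
        except StopIteration:
            raise ValueError("unexpected end of symbols") from None
        if sym[0] != kind:
            raise ValueError(f"expected {kind} symbol, got {sym[0]}")
        return sym

    def parse(dims: tuple[int, int], predicted: bool):
        m, n = dims
        s = scale_index(m, n)
        sym = next_symbol("flag")
        flag = sym[2]
        kind = _KIND_OF_FLAG[flag]
        if kind in ("pred_vsplit", "pred_hsplit"):
            if not predicted:
                raise ValueError("prediction split inside a residue tree")
            if s < MIN_PRED_SPLIT_SCALE:
                raise ValueError(
                    f"prediction split at scale {s} < {MIN_PRED_SPLIT_SCALE}")
            cd = (m, n // 2) if kind == "pred_vsplit" else (m // 2, n)
            if 0 in cd:
                raise ValueError("split below unit block size")
            return TreeNode(kind=kind, dims=dims,
                            children=(parse(cd, True), parse(cd, True)))
        mode = None
        if predicted and allowed_modes(s):
            mode = next_symbol("mode")[2]
        if kind == "leaf":
            isym = next_symbol("index")
            return TreeNode(kind="leaf", dims=dims, mode=mode,
                            index=(isym[2], isym[3]))
        cd = (m, n // 2) if kind == "vsplit" else (m // 2, n)
        if 0 in cd:
            raise ValueError("split below unit block size")
        return TreeNode(kind=kind, dims=dims, mode=mode,
                        children=(parse(cd, False), parse(cd, False)))

    tree = parse(tuple(dims), predicted)
    try:
        extra = next(it)
    except StopIteration:
        return tree
    raise ValueError(f"trailing symbols after tree: {extra!r}")


# ---------------------------------------------------------------------------
# Container format
# ---------------------------------------------------------------------------

@dataclass
class CodedHeader:
    """Side information needed to configure the decoder.

    Matches the compression architecture: sample count, amplitude offset,
    dictionary amplitude bound, segment length, preprocessing id (and PDS
    permutation when applicable), the Lagrangian multiplier and the matrix
    dimensions, plus record metadata and the dictionary-update settings the
    decoder must mirror.
    """

    n_samples: int
    offset: int
    x_max: int
    segment_length: int
    preprocess: str  # "none" | "pds" | "sbs"
    lam: float
    n_rows: int
    n_cols: int
    sampling_rate_hz: float = 2000.0
    bit_depth: int = 12
    dict_cap: int = 50000
    additive_symmetric: bool = False
    permutation: np.ndarray | None = None


_PREPROCESS_IDS = {"none": 0, "pds": 1, "sbs": 2}
_PREPROCESS_NAMES = {v: k for k, v in _PREPROCESS_IDS.items()}


def _encode_permutation(perm: np.ndarray) -> bytes:
    """Arithmetic-code a permutation over the 0..L-1 alphabet, byte-aligned."""
    table = FrequencyTable(int(perm.size))
    return arith_encode(perm.tolist(), table)


def _decode_permutation(blob: bytes, length: int) -> np.ndarray:
    table = FrequencyTable(length)
    return np.asarray(arith_decode(blob, table, length), dtype=np.int64)


def write_container(path, header: CodedHeader, payload: bytes) -> None:
    """Write a .mmp2d file: magic, version, fixed header, permutation, payload."""
    if header.preprocess not in _PREPROCESS_IDS:
        raise ValueError(f"unknown preprocessing {header.preprocess!r}")
    perm_blob = b""
    perm_len = 0
    if header.preprocess == "pds":
        if header.permutation is None:
            raise ValueError("PDS header requires a permutation")
        perm = np.asarray(header.permutation, dtype=np.int64)
        perm_len = int(perm.size)
        perm_blob = _encode_permutation(perm)
    fixed = struct.pack(
        "<QiIIBdIIdBIBII",
        header.n_samples,
        header.offset,
        header.x_max,
        header.segment_length,
        _PREPROCESS_IDS[header.preprocess],
        header.lam,
        header.n_rows,
        header.n_cols,
        header.sampling_rate_hz,
        header.bit_depth,
        header.dict_cap,
        1 if header.additive_symmetric else 0,
        perm_len,
        len(perm_blob),
    )
    with open(str(path), "wb") as fh:
        fh.write(MAGIC)
        fh.write(bytes([VERSION]))
        fh.write(fixed)
        fh.write(perm_blob)
        fh.write(struct.pack("<Q", len(payload)))
        fh.write(payload)


def read_container(path) -> tuple[CodedHeader, bytes]:
    with open(str(path), "rb") as fh:
        blob = fh.read()
    if blob[: len(MAGIC)] != MAGIC:
        raise ValueError("not an mmp2d container (bad magic)")
    pos = len(MAGIC)
    if len(blob) < pos + 1 or blob[pos] != VERSION:
        raise ValueError("unsupported container version")
    pos += 1
    fixed_fmt = "<QiIIBdIIdBIBII"
    fixed_size = struct.calcsize(fixed_fmt)
    if len(blob) < pos + fixed_size:
        raise ValueError("truncated container header")
    (n_samples, offset, x_max, segment_length, pp_id, lam, n_rows, n_cols,
     fs, bit_depth, dict_cap, addsym, perm_len, perm_bytes) = struct.unpack(
        fixed_fmt, blob[pos: pos + fixed_size])
    pos += fixed_size
    if pp_id not in _PREPROCESS_NAMES:
        raise ValueError(f"unknown preprocessing id {pp_id}")
    if len(blob) < pos + perm_bytes + 8:
        raise ValueError("truncated container")
    permutation = None
    if perm_len:
        permutation = _decode_permutation(blob[pos: pos + perm_bytes], perm_len)
    pos += perm_bytes
    (payload_len,) = struct.unpack("<Q", blob[pos: pos + 8])
    pos += 8
    payload = blob[pos: pos + payload_len]
    if len(payload) != payload_len:
        raise ValueError("truncated payload")
    header = CodedHeader(
        n_samples=n_samples,
        offset=offset,
        x_max=x_max,
        segment_length=segment_length,
        preprocess=_PREPROCESS_NAMES[pp_id],
        lam=lam,
        n_rows=n_rows,
        n_cols=n_cols,
        sampling_rate_hz=fs,
        bit_depth=bit_depth,
        dict_cap=dict_cap,
        additive_symmetric=bool(addsym),
        permutation=permutation,
    )
    return header, payload
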