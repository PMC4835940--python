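"""The modified two-dimensional multiscale-parser (MMP) engine.

An SEMG matrix is padded to 16×16 tiles which are coded in raster order.
Each tile is approximated by recursively segmenting it (vertical = left/right,
horizontal = top/bottom halves) and matching the pieces against an adaptive
multiscale dictionary; the segmentation/prediction tree is chosen to minimize
the Lagrangian cost J = D + λR, where D is the sum of squared differences and
R the rate in bits under the current adaptive models.  Intra prediction
(33 angular modes, planar, MFV) can be applied hierarchically: flags 3/4 split
a block in the prediction domain and every predicted region codes its residue
with an ordinary MMP subtree.

Block dimensions are 2^m × 2^n with m, n ∈ {0..4}; the 25 (M, N) pairs map
bijectively onto dictionary scales 1..25.  After a residue split is coded, the
concatenation of the children's reconstructions becomes a new dictionary
pattern, scale-transformed to every scale, subject to a redundancy-distance
threshold d(λ) and a per-scale entry cap; encoder and decoder perform the
identical updates, keeping their dictionaries and probability models in
lockstep after every block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import entropy
from .prediction import (
    NO_PRED,
    allowed_modes,
    build_reference_vectors,
    predict_block,
)

__all__ = [
    "VALID_SIDES",
    "BLOCK",
    "N_SCALES",
    "MIN_PRED_SPLIT_SCALE",
    "ScaleSpec",
    "TreeNode",
    "MmpConfig",
    "CostModel",
    "MultiscaleDictionary",
    "scale_index",
    "dims_of_scale",
    "all_scales",
    "init_dictionary",
    "initial_levels",
    "level_step",
    "redundancy_threshold",
    "scale_transform",
    "best_match",
    "update_dictionary",
    "optimize_block",
    "encode_matrix",
    "decode_matrix",
    "Mmp2dEncoder",
    "Mmp2dDecoder",
]

VALID_SIDES = (1, 2, 4, 8, 16)
BLOCK = 16          # top-level tile side
N_SCALES = 25
#: hierarchical-prediction flags (3/4) are legal at scales 25 down to 9
MIN_PRED_SPLIT_SCALE = 9


# ---------------------------------------------------------------------------
# Scales
# ---------------------------------------------------------------------------

def scale_index(m: int, n: int) -> int:
    """Dictionary scale of an M×N block (bijection onto 1..25).

    Three cases depending on the aspect ratio::

        M = N:  (log2 M + 1)(log2 N + 1)
        M > N:  (log2 M + 1)(log2 N + 1) + (log2 M - 1) log2(M/N)
        M < N:  (log2 M + 1)(log2 N + 1) + (log2 N - 1) log2(N/M) + 1
    """
    if m not in VALID_SIDES or n not in VALID_SIDES:
        raise ValueError(f"invalid block dimensions {m}x{n}")
    lm, ln = m.bit_length() - 1, n.bit_length() - 1
    base = (lm + 1) * (ln + 1)
    if m == n:
        return base
    if m > n:
        return base + (lm - 1) * (lm - ln)
    return base + (ln - 1) * (ln - lm) + 1


_DIMS_OF_SCALE = {scale_index(m, n): (m, n)
                  for m in VALID_SIDES for n in VALID_SIDES}
assert len(_DIMS_OF_SCALE) == N_SCALES


def dims_of_scale(scale: int) -> tuple[int, int]:
    """(M, N) block dimensions of a dictionary scale."""
    try:
        return _DIMS_OF_SCALE[scale]
    except KeyError:
        raise ValueError(f"scale {scale} outside [1, {N_SCALES}]") from None


def all_scales() -> list[int]:
    return sorted(_DIMS_OF_SCALE)


@dataclass(frozen=True)
class ScaleSpec:
    """A dictionary scale and the block dimensions it addresses."""

    scale: int
    dims: tuple[int, int]

    @classmethod
    def from_dims(cls, m: int, n: int) -> "ScaleSpec":
        return cls(scale_index(m, n), (m, n))


# ---------------------------------------------------------------------------
# Initial dictionary and redundancy control
# ---------------------------------------------------------------------------

def level_step(value: int) -> int:
    """Step p to the next initial-dictionary level, by magnitude band.

    Residue samples cluster around zero, so levels are densest there:
    p = 1 for |v| ≤ 10, 4 for 10 < |v| ≤ 22, 8 for 22 < |v| ≤ 86, 13 above.
    """
    a = abs(value)
    if a <= 10:
        return 1
    if a <= 22:
        return 4
    if a <= 86:
        return 8
    return 13


def initial_levels(x_max: int) -> np.ndarray:
    """Homogeneous-block amplitude levels: one pass from −x_max, step p(|v|)."""
    if x_max < 1:
        raise ValueError("x_max must be >= 1")
    levels = []
    v = -x_max
    while v <= x_max:
        levels.append(v)
        v += level_step(v)
    return np.asarray(levels, dtype=np.int64)


def redundancy_threshold(lam: float) -> float:
    """Minimum dictionary distance d(λ) for inserting a new pattern."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam <= 4:
        return 20.0
    if lam <= 22:
        return 40.0
    if lam <= 50:
        return 60.0
    return 80.0


# ---------------------------------------------------------------------------
# Scale transformation (separable resampling)
# ---------------------------------------------------------------------------

def _resample_matrix(src: int, dst: int) -> np.ndarray:
    """1-D resampling weights W (dst×src): expansion by linearly weighted
    sample repetition, contraction by box averaging; rows sum to 1."""
    if src == dst:
        return np.eye(src)
    w = np.zeros((dst, src))
    if dst > src:
        for j in range(dst):
            pos = (j + 0.5) * src / dst - 0.5
            i0 = int(np.floor(pos))
            frac = pos - i0
            i0c = min(max(i0, 0), src - 1)
            i1c = min(max(i0 + 1, 0), src - 1)
            w[j, i0c] += 1.0 - frac
            w[j, i1c] += frac
    else:
        f = src // dst
        for j in range(dst):
            w[j, j * f:(j + 1) * f] = 1.0 / f
    return w


_RESAMPLE = {(s, d): _resample_matrix(s, d)
             for s in VALID_SIDES for d in VALID_SIDES}


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x).astype(np.int64)


def scale_transform(pattern: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    """Separable rescaling of a pattern to new dims (rows then columns)."""
    pattern = np.asarray(pattern, dtype=np.int64)
    sm, sn = pattern.shape
    dm, dn = dims
    if sm not in VALID_SIDES or sn not in VALID_SIDES \
            or dm not in VALID_SIDES or dn not in VALID_SIDES:
        raise ValueError("dimensions must be in {1,2,4,8,16}")
    out = _RESAMPLE[(sm, dm)] @ pattern.astype(np.float64) @ _RESAMPLE[(sn, dn)].T
    return _round_half_away(out)


# ---------------------------------------------------------------------------
# Multiscale dictionary
# ---------------------------------------------------------------------------

class _ScaleStore:
    """Append-only pattern store for one scale (flat float64 + int64 views)."""

    def __init__(self, dims: tuple[int, int], capacity_hint: int = 64):
        self.dims = dims
        self.k = dims[0] * dims[1]
        cap = max(capacity_hint, 8)
        self.pat_f = np.empty((cap, self.k), dtype=np.float64)
        self.pat_i = np.empty((cap, self.k), dtype=np.int64)
        self.norms = np.empty(cap, dtype=np.float64)
        self.partition = np.empty(cap, dtype=np.int64)
        self.within = np.empty(cap, dtype=np.int64)
        self.lookup: dict[tuple[int, int], int] = {}
        self.n = 0

    def _grow(self) -> None:
        cap = self.pat_f.shape[0] * 2
        for name in ("pat_f", "pat_i", "norms", "partition", "within"):
            arr = getattr(self, name)
            new = np.empty((cap,) + arr.shape[1:], dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def append(self, pattern: np.ndarray, partition: int, within: int) -> None:
        if self.n == self.pat_f.shape[0]:
            self._grow()
        flat = pattern.reshape(-1)
        self.pat_i[self.n] = flat
        self.pat_f[self.n] = flat
        self.norms[self.n] = float(flat @ flat)
        self.partition[self.n] = partition
        self.within[self.n] = within
        self.lookup[(partition, within)] = self.n
        self.n += 1

    def pattern(self, entry: int) -> np.ndarray:
        return self.pat_i[entry].reshape(self.dims)


class MultiscaleDictionary:
    """25 per-scale pattern lists with origin-scale partitions.

    Scale 1 initially holds every integer in [−x_max, x_max]; every other
    scale holds homogeneous blocks at the nonuniform levels of
    :func:`initial_levels`.  Initial entries live in partition 0; adaptive
    entries go to the partition named after the scale of the block that gave
    rise to them.
    """

    def __init__(self, x_max: int, cap: int = 50000):
        if x_max < 1:
            raise ValueError("x_max must be >= 1")
        self.x_max = int(x_max)
        self.cap = int(cap)
        self.scales: dict[int, _ScaleStore] = {}
        # per scale, entry count of each partition id 0..25
        self.part_sizes: dict[int, np.ndarray] = {}
        levels = initial_levels(self.x_max)
        full = np.arange(-self.x_max, self.x_max + 1, dtype=np.int64)
        for s in all_scales():
            dims = dims_of_scale(s)
            vals = full if s == 1 else levels
            store = _ScaleStore(dims, capacity_hint=vals.size + 16)
            for i, v in enumerate(vals):
                store.append(np.full(dims, v, dtype=np.int64), 0, i)
            self.scales[s] = store
            sizes = np.zeros(26, dtype=np.int64)
            sizes[0] = vals.size
            self.part_sizes[s] = sizes

    def n_entries(self, scale: int) -> int:
        return self.scales[scale].n

    def entry_pattern(self, scale: int, partition: int, within: int) -> np.ndarray:
        store = self.scales[scale]
        try:
            e = store.lookup[(partition, within)]
        except KeyError:
            raise KeyError(
                f"no entry ({partition}, {within}) at scale {scale}") from None
        return store.pattern(e)

    def fingerprint(self) -> tuple:
        """Hashable digest of the full dictionary state (sync checks)."""
        return tuple(
            (s, st.n, st.pat_i[: st.n].tobytes())
            for s, st in sorted(self.scales.items()))


def init_dictionary(x_max: int, cap: int = 50000) -> MultiscaleDictionary:
    """Build the initial multiscale dictionary for amplitude bound x_max."""
    return MultiscaleDictionary(x_max, cap)


def _try_insert(dictionary: MultiscaleDictionary, pattern: np.ndarray,
                origin_scale: int, d: float,
                models: "ContextModels | None") -> list[int]:
    """Insert the pattern (scale-transformed) at every scale whose redundancy
    distance allows it; returns the scales that accepted it."""
    accepted = []
    for s in all_scales():
        store = dictionary.scales[s]
        if store.n >= dictionary.cap:
            continue
        cand = scale_transform(pattern, store.dims).reshape(-1)
        cf = cand.astype(np.float64)
        ex = store.pat_f[: store.n]
        # mean squared difference per sample vs every existing entry
        dist = (cf @ cf - 2.0 * (ex @ cf) + store.norms[: store.n]) / store.k
        if float(dist.min()) <= d:
            continue
        part = origin_scale
        within = int(dictionary.part_sizes[s][part])
        store.append(cand.reshape(store.dims), part, within)
        dictionary.part_sizes[s][part] += 1
        if models is not None:
            models.index_symbol_added(s, part)
        accepted.append(s)
    return accepted


def update_dictionary(dictionary: MultiscaleDictionary, new_pattern: np.ndarray,
                      origin_scale: int, d: float,
                      models: "ContextModels | None" = None,
                      additive_symmetric: bool = False) -> list[int]:
    """Dictionary update after coding a segmented block.

    ``new_pattern`` is the concatenation of the two children's reconstructions;
    it is rescaled to every scale and appended to the ``origin_scale``
    partition wherever its mean-squared distance to all existing entries
    exceeds ``d`` and the per-scale cap is not reached.  With
    ``additive_symmetric`` the negated pattern is offered as well.
    """
    new_pattern = np.asarray(new_pattern, dtype=np.int64)
    accepted = _try_insert(dictionary, new_pattern, origin_scale, d, models)
    if additive_symmetric:
        accepted += _try_insert(dictionary, -new_pattern, origin_scale, d, models)
    return accepted


# ---------------------------------------------------------------------------
# Segmentation tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of a segmentation tree.

    ``kind`` ∈ {leaf, vsplit, hsplit, pred_vsplit, pred_hsplit}; a leaf holds
    a dictionary ``index`` (partition, index-within-partition); a node that
    starts a predicted region carries ``mode``; split nodes hold two children
    (left/upper first).
    """

    kind: str
    dims: tuple[int, int]
    mode: int | None = None
    index: tuple[int, int] | None = None
    children: tuple = ()

    def leaves(self):
        if self.kind == "leaf":
            yield self
        else:
            for ch in self.children:
                yield from ch.leaves()


def _child_dims(kind: str, dims: tuple[int, int]) -> tuple[int, int]:
    m, n = dims
    if kind in ("vsplit", "pred_vsplit"):
        return (m, n // 2)
    return (m // 2, n)


# ---------------------------------------------------------------------------
# Configuration and context models
# ---------------------------------------------------------------------------

@dataclass
class MmpConfig:
    """Codec options.

    dict_cap and additive_symmetric change the bitstream (they travel in the
    container header); mode_search_width and pred_split_depth only bound the
    encoder's search (rough SSE prescreen of prediction modes with full RD on
    the shortlist; None = exhaustive).
    """

    dict_cap: int = 50000
    additive_symmetric: bool = False
    mode_search_width: int | None = 4
    pred_split_depth: int = 1


@dataclass
class CostModel:
    """Lagrangian weighting: J = D + lam * R (R in bits)."""

    lam: float = 0.0
    rates: "object | None" = None


def _legal_flags(scale: int) -> list[int]:
    m, n = dims_of_scale(scale)
    flags = [0]
    if n >= 2:
        flags.append(1)
    if m >= 2:
        flags.append(2)
    if scale >= MIN_PRED_SPLIT_SCALE:
        if n >= 2:
            flags.append(3)
        if m >= 2:
            flags.append(4)
    return flags


def _mode_alphabet(scale: int) -> list[int]:
    modes = sorted(allowed_modes(scale))
    return modes + [NO_PRED] if modes else []


class ContextModels:
    """All adaptive frequency tables, mirrored on both codec sides."""

    def __init__(self, dictionary: MultiscaleDictionary):
        self.flag_alpha = {s: _legal_flags(s) for s in all_scales()}
        self.flag_pos = {s: {f: i for i, f in enumerate(a)}
                         for s, a in self.flag_alpha.items()}
        self.flag = {s: entropy.FrequencyTable(len(a))
                     for s, a in self.flag_alpha.items()}
        self.mode_alpha = {s: _mode_alphabet(s) for s in all_scales()}
        self.mode_pos = {s: {m: i for i, m in enumerate(a)}
                         for s, a in self.mode_alpha.items()}
        self.mode = {s: entropy.FrequencyTable(len(a))
                     for s, a in self.mode_alpha.items() if a}
        self.part = {s: entropy.FrequencyTable(26) for s in all_scales()}
        self.index: dict[tuple[int, int], entropy.FrequencyTable] = {}
        for s in all_scales():
            sizes = dictionary.part_sizes[s]
            for p in range(26):
                if sizes[p] > 0:
                    self.index[(s, p)] = entropy.FrequencyTable(int(sizes[p]))

    def index_symbol_added(self, scale: int, partition: int) -> None:
        key = (scale, partition)
        if key in self.index:
            self.index[key].add_symbol()
        else:
            self.index[key] = entropy.FrequencyTable(1)

    def fingerprint(self) -> tuple:
        out = []
        for s in all_scales():
            out.append(("flag", s, self.flag[s].counts.tobytes()))
            if s in self.mode:
                out.append(("mode", s, self.mode[s].counts.tobytes()))
            out.append(("part", s, self.part[s].counts.tobytes()))
        for key in sorted(self.index):
            out.append(("index", key, self.index[key].counts.tobytes()))
        return tuple(out)


class _Rates:
    """Per-scale code lengths frozen at the start of a block's optimization."""

    def __init__(self, models: ContextModels, dictionary: MultiscaleDictionary):
        self._models = models
        self._dict = dictionary
        self._flag: dict[int, np.ndarray] = {}
        self._mode: dict[int, np.ndarray] = {}
        self._entry: dict[int, np.ndarray] = {}

    def flag_bits(self, scale: int, flag: int) -> float:
        if scale not in self._flag:
            self._flag[scale] = self._models.flag[scale].code_lengths()
        return float(self._flag[scale][self._models.flag_pos[scale][flag]])

    def mode_bits(self, scale: int, mode: int) -> float:
        if scale not in self._mode:
            self._mode[scale] = self._models.mode[scale].code_lengths()
        return float(self._mode[scale][self._models.mode_pos[scale][mode]])

    def entry_bits(self, scale: int) -> np.ndarray:
        """Bits for (partition, index) of every entry, in storage order."""
        if scale not in self._entry:
            store = self._dict.scales[scale]
            part_len = self._models.part[scale].code_lengths()
            out = np.empty(store.n, dtype=np.float64)
            parts = store.partition[: store.n]
            within = store.within[: store.n]
            for p in np.unique(parts):
                tab = self._models.index[(scale, int(p))]
                lens = tab.code_lengths()
                sel = parts == p
                out[sel] = part_len[int(p)] + lens[within[sel]]
            self._entry[scale] = out
        return self._entry[scale]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def best_match(block: np.ndarray, dictionary: MultiscaleDictionary,
               cost: CostModel | None = None,
               entry_rates: np.ndarray | None = None
               ) -> tuple[tuple[int, int, int], float]:
    """Best dictionary approximation of a block under J = D + λR.

    Returns ``((scale, partition, within), J)``.  D is the sum of squared
    differences; R is the index code length in bits (zero when no cost model
    or rates are given).  Ties go to the lowest partition, then lowest index.
    """
    block = np.asarray(block, dtype=np.int64)
    s = scale_index(*block.shape)
    store = dictionary.scales[s]
    if store.n == 0:
        raise ValueError(f"empty dictionary scale {s}")
    b = block.reshape(-1).astype(np.float64)
    ex = store.pat_f[: store.n]
    dist = b @ b - 2.0 * (ex @ b) + store.norms[: store.n]
    lam = cost.lam if cost is not None else 0.0
    if lam > 0 and entry_rates is not None:
        j = dist + lam * entry_rates
    else:
        j = dist
    jmin = float(j.min())
    ties = np.flatnonzero(j == jmin)
    if ties.size > 1:
        rank = store.partition[ties] * (1 << 32) + store.within[ties]
        e = int(ties[int(np.argmin(rank))])
    else:
        e = int(ties[0])
    return (s, int(store.partition[e]), int(store.within[e])), float(j[e])


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

class _ResidueDP:
    """Bottom-up Lagrangian optimization of one residue region.

    Pure function of the target values under the frozen dictionary and rate
    snapshot, so results are cached by region position for reuse across
    prediction-split candidates.
    """

    def __init__(self, dictionary: MultiscaleDictionary, lam: float,
                 rates: _Rates | None):
        self.dict = dictionary
        self.lam = lam
        self.rates = rates

    def optimize(self, target: np.ndarray) -> tuple[float, TreeNode]:
        t = np.asarray(target, dtype=np.int64)
        m0, n0 = t.shape
        lam = self.lam
        dims_list = sorted(
            {(m0 >> a, n0 >> b)
             for a in range(m0.bit_length()) for b in range(n0.bit_length())
             if (m0 >> a) >= 1 and (n0 >> b) >= 1},
            key=lambda d: (d[0] * d[1], d[0]))
        best_j: dict[tuple[int, int], np.ndarray] = {}
        choice: dict[tuple[int, int], np.ndarray] = {}
        entry: dict[tuple[int, int], np.ndarray] = {}
        for (m, n) in dims_list:
            s = scale_index(m, n)
            store = self.dict.scales[s]
            gr, gc = m0 // m, n0 // n
            blocks = (t.reshape(gr, m, gc, n).transpose(0, 2, 1, 3)
                      .reshape(gr * gc, m * n).astype(np.float64))
            ex = store.pat_f[: store.n]
            dist = (np.einsum("ij,ij->i", blocks, blocks)[:, None]
                    - 2.0 * (blocks @ ex.T) + store.norms[: store.n][None, :])
            if lam > 0:
                j_mat = dist + lam * self.rates.entry_bits(s)[None, :]
            else:
                j_mat = dist
            jmin = j_mat.min(axis=1)
            ent = j_mat.argmin(axis=1)
            # resolve exact ties toward the lowest (partition, within)
            n_ties = (j_mat == jmin[:, None]).sum(axis=1)
            if np.any(n_ties > 1):
                rank = (store.partition[: store.n] * (1 << 32)
                        + store.within[: store.n])
                for r in np.flatnonzero(n_ties > 1):
                    cand = np.flatnonzero(j_mat[r] == jmin[r])
                    ent[r] = cand[int(np.argmin(rank[cand]))]
            j_leaf = jmin.reshape(gr, gc)
            if lam > 0:
                j_leaf = j_leaf + lam * self.rates.flag_bits(s, 0)
            jb = j_leaf.copy()
            ch = np.zeros((gr, gc), dtype=np.int8)
            if n >= 2:
                jc = best_j[(m, n // 2)]
                jv = jc[:, 0::2] + jc[:, 1::2]
                if lam > 0:
                    jv = jv + lam * self.rates.flag_bits(s, 1)
                better = jv < jb
                jb = np.where(better, jv, jb)
                ch[better] = 1
            if m >= 2:
                jc = best_j[(m // 2, n)]
                jh = jc[0::2, :] + jc[1::2, :]
                if lam > 0:
                    jh = jh + lam * self.rates.flag_bits(s, 2)
                better = jh < jb
                jb = np.where(better, jh, jb)
                ch[better] = 2
            best_j[(m, n)] = jb
            choice[(m, n)] = ch
            entry[(m, n)] = ent.reshape(gr, gc)

        store_of = {d: self.dict.scales[scale_index(*d)] for d in dims_list}

        def build(m: int, n: int, i: int, j: int) -> TreeNode:
            c = int(choice[(m, n)][i, j])
            if c == 0:
                st = store_of[(m, n)]
                e = int(entry[(m, n)][i, j])
                return TreeNode("leaf", (m, n),
                                index=(int(st.partition[e]), int(st.within[e])))
            if c == 1:
                return TreeNode("vsplit", (m, n), children=(
                    build(m, n // 2, i, 2 * j), build(m, n // 2, i, 2 * j + 1)))
            return TreeNode("hsplit", (m, n), children=(
                build(m // 2, n, 2 * i, j), build(m // 2, n, 2 * i + 1, j)))

        return float(best_j[(m0, n0)][0, 0]), build(m0, n0, 0, 0)


class _CodecState:
    """Dictionary + context models + update policy shared by both sides."""

    def __init__(self, x_max: int, lam: float, config: MmpConfig):
        self.x_max = x_max
        self.lam = lam
        self.config = config
        self.dict = MultiscaleDictionary(x_max, config.dict_cap)
        self.models = ContextModels(self.dict)
        self.d_thresh = redundancy_threshold(lam)

    def dictionary_update(self, pattern: np.ndarray, origin_scale: int) -> None:
        update_dictionary(self.dict, pattern, origin_scale, self.d_thresh,
                          models=self.models,
                          additive_symmetric=self.config.additive_symmetric)

    def render_residue(self, node: TreeNode) -> np.ndarray:
        """Reconstruction of a residue subtree (no side effects)."""
        if node.kind == "leaf":
            return self.dict.entry_pattern(scale_index(*node.dims), *node.index)
        a = self.render_residue(node.children[0])
        b = self.render_residue(node.children[1])
        axis = 1 if node.kind == "vsplit" else 0
        return np.concatenate([a, b], axis=axis)


class Mmp2dEncoder:
    """Rate-distortion optimized encoder for one padded SEMG matrix."""

    def __init__(self, lam: float, config: MmpConfig | None = None,
                 x_max: int | None = None):
        self.lam = float(lam)
        self.config = config or MmpConfig()
        self._forced_x_max = x_max

    # -- optimization ------------------------------------------------------

    def _optimize_pred_node(self, image: np.ndarray, r: int, c: int,
                            dims: tuple[int, int], recon: np.ndarray,
                            mask: np.ndarray, depth: int
                            ) -> tuple[float, TreeNode]:
        state, lam = self._state, self.lam
        m, n = dims
        s = scale_index(m, n)
        x = image[r:r + m, c:c + n]

        key = (r, c, m, n)
        if key in self._direct_cache:
            j_dp, tree_dp = self._direct_cache[key]
        else:
            j_dp, tree_dp = self._dp.optimize(x)
            self._direct_cache[key] = (j_dp, tree_dp)
        j_best = j_dp + (lam * self._rates.mode_bits(s, NO_PRED) if lam > 0 else 0.0)
        tree_best = dataclasses.replace(tree_dp, mode=NO_PRED)

        if not (lam == 0 and j_best == 0.0):
            refs = build_reference_vectors(recon, mask, (r, c), dims)
            modes = sorted(allowed_modes(s))
            preds, sses = {}, {}
            for mode in modes:
                p = predict_block(refs, mode, dims)
                d = (x - p).astype(np.float64)
                preds[mode], sses[mode] = p, float(np.einsum("ij,ij->", d, d))
            width = self.config.mode_search_width
            if width is not None and len(modes) > width:
                modes = sorted(modes, key=lambda mm: (sses[mm], mm))[:width]
                modes.sort()
            for mode in modes:
                j_r, tree_r = self._dp.optimize(x - preds[mode])
                j = j_r + (lam * self._rates.mode_bits(s, mode) if lam > 0 else 0.0)
                if j < j_best:
                    j_best = j
                    tree_best = dataclasses.replace(tree_r, mode=mode)

            if s >= MIN_PRED_SPLIT_SCALE and depth < self.config.pred_split_depth:
                for kind, flag in (("pred_vsplit", 3), ("pred_hsplit", 4)):
                    cm, cn = _child_dims(kind, dims)
                    if cm < 1 or cn < 1 or (cm, cn) == dims:
                        continue
                    r2, c2 = (r, c + cn) if kind == "pred_vsplit" else (r + cm, c)
                    j1, t1 = self._optimize_pred_node(
                        image, r, c, (cm, cn), recon, mask, depth + 1)
                    recon2, mask2 = recon.copy(), mask.copy()
                    self._render_pred(t1, r, c, recon2, mask2)
                    j2, t2 = self._optimize_pred_node(
                        image, r2, c2, (cm, cn), recon2, mask2, depth + 1)
                    j = j1 + j2 + (lam * self._rates.flag_bits(s, flag)
                                   if lam > 0 else 0.0)
                    if j < j_best:
                        j_best = j
                        tree_best = TreeNode(kind, dims, children=(t1, t2))
        return j_best, tree_best

    def _render_pred(self, node: TreeNode, r: int, c: int,
                     recon: np.ndarray, mask: np.ndarray) -> None:
        """Write a committed subtree's reconstruction into recon/mask."""
        m, n = node.dims
        if node.kind in ("pred_vsplit", "pred_hsplit"):
            cm, cn = _child_dims(node.kind, node.dims)
            r2, c2 = (r, c + cn) if node.kind == "pred_vsplit" else (r + cm, c)
            self._render_pred(node.children[0], r, c, recon, mask)
            self._render_pred(node.children[1], r2, c2, recon, mask)
            return
        if node.mode is not None and node.mode != NO_PRED:
            refs = build_reference_vectors(recon, mask, (r, c), node.dims)
            p = predict_block(refs, node.mode, node.dims)
        else:
            p = np.zeros((m, n), dtype=np.int64)
        recon[r:r + m, c:c + n] = p + self._state.render_residue(node)
        mask[r:r + m, c:c + n] = True

    # -- emission ----------------------------------------------------------

    def _emit_flag(self, scale: int, flag: int) -> None:
        mdl = self._state.models
        self._enc.encode_symbol(mdl.flag[scale], mdl.flag_pos[scale][flag])

    def _emit_mode(self, scale: int, mode: int) -> None:
        mdl = self._state.models
        self._enc.encode_symbol(mdl.mode[scale], mdl.mode_pos[scale][mode])

    def _emit_index(self, scale: int, part: int, within: int) -> None:
        mdl = self._state.models
        self._enc.encode_symbol(mdl.part[scale], part)
        self._enc.encode_symbol(mdl.index[(scale, part)], within)

    def _emit_residue(self, node: TreeNode, skip_flag: bool) -> np.ndarray:
        s = scale_index(*node.dims)
        if not skip_flag:
            self._emit_flag(s, entropy._FLAG_OF_KIND[node.kind])
        if node.kind == "leaf":
            self._emit_index(s, *node.index)
            return self._state.dict.entry_pattern(s, *node.index)
        a = self._emit_residue(node.children[0], False)
        b = self._emit_residue(node.children[1], False)
        axis = 1 if node.kind == "vsplit" else 0
        rec = np.concatenate([a, b], axis=axis)
        self._state.dictionary_update(rec, s)
        return rec

    def _emit_pred_node(self, node: TreeNode, r: int, c: int,
                        recon: np.ndarray, mask: np.ndarray) -> None:
        m, n = node.dims
        s = scale_index(m, n)
        if node.kind in ("pred_vsplit", "pred_hsplit"):
            self._emit_flag(s, entropy._FLAG_OF_KIND[node.kind])
            cm, cn = _child_dims(node.kind, node.dims)
            r2, c2 = (r, c + cn) if node.kind == "pred_vsplit" else (r + cm, c)
            self._emit_pred_node(node.children[0], r, c, recon, mask)
            self._emit_pred_node(node.children[1], r2, c2, recon, mask)
            return
        self._emit_flag(s, entropy._FLAG_OF_KIND[node.kind])
        self._emit_mode(s, node.mode)
        if node.mode != NO_PRED:
            refs = build_reference_vectors(recon, mask, (r, c), node.dims)
            p = predict_block(refs, node.mode, node.dims)
        else:
            p = np.zeros((m, n), dtype=np.int64)
        if node.kind == "leaf":
            self._emit_index(s, *node.index)
            rhat = self._state.dict.entry_pattern(s, *node.index)
        else:
            a = self._emit_residue(node.children[0], False)
            b = self._emit_residue(node.children[1], False)
            axis = 1 if node.kind == "vsplit" else 0
            rhat = np.concatenate([a, b], axis=axis)
            self._state.dictionary_update(rhat, s)
        recon[r:r + m, c:c + n] = p + rhat
        mask[r:r + m, c:c + n] = True

    # -- public ------------------------------------------------------------

    def encode(self, values: np.ndarray
               ) -> tuple[list[TreeNode], np.ndarray, bytes, int]:
        """Encode a K×L integer matrix.

        Returns (trees, padded reconstruction, payload bytes, x_max).
        """
        values = np.asarray(values, dtype=np.int64)
        k, l = values.shape
        pr = -(-k // BLOCK) * BLOCK
        pc = -(-l // BLOCK) * BLOCK
        image = np.zeros((pr, pc), dtype=np.int64)
        image[:k, :l] = values
        x_max = self._forced_x_max
        if x_max is None:
            x_max = max(1, int(np.abs(image).max()))
        self._state = _CodecState(x_max, self.lam, self.config)
        self._enc = entropy.ArithmeticEncoder()
        recon = np.zeros_like(image)
        mask = np.zeros(image.shape, dtype=bool)
        trees: list[TreeNode] = []
        for br in range(0, pr, BLOCK):
            for bc in range(0, pc, BLOCK):
                self._rates = _Rates(self._state.models, self._state.dict) \
                    if self.lam > 0 else None
                self._dp = _ResidueDP(self._state.dict, self.lam, self._rates)
                self._direct_cache = {}
                _, tree = self._optimize_pred_node(
                    image, br, bc, (BLOCK, BLOCK), recon, mask, 0)
                self._emit_pred_node(tree, br, bc, recon, mask)
                trees.append(tree)
        payload = self._enc.finish()
        self.recon_padded = recon
        self.state = self._state
        return trees, recon, payload, x_max


class Mmp2dDecoder:
    """Bitstream parser mirroring the encoder's reconstruction path."""

    def __init__(self, x_max: int, lam: float, config: MmpConfig | None = None):
        self.config = config or MmpConfig()
        self.state = _CodecState(x_max, lam, self.config)

    def _parse_flag(self, scale: int) -> int:
        mdl = self.state.models
        return mdl.flag_alpha[scale][self._dec.decode_symbol(mdl.flag[scale])]

    def _parse_mode(self, scale: int) -> int:
        mdl = self.state.models
        return mdl.mode_alpha[scale][self._dec.decode_symbol(mdl.mode[scale])]

    def _parse_index(self, scale: int) -> tuple[int, int]:
        mdl = self.state.models
        part = self._dec.decode_symbol(mdl.part[scale])
        key = (scale, part)
        if key not in mdl.index:
            raise ValueError(f"corrupt stream: empty partition {key}")
        within = self._dec.decode_symbol(mdl.index[key])
        return part, within

    def _parse_residue(self, dims: tuple[int, int], flag: int | None
                       ) -> tuple[np.ndarray, TreeNode]:
        m, n = dims
        s = scale_index(m, n)
        if flag is None:
            flag = self._parse_flag(s)
        kind = entropy._KIND_OF_FLAG[flag]
        if kind == "leaf":
            part, within = self._parse_index(s)
            node = TreeNode("leaf", dims, index=(part, within))
            return self.state.dict.entry_pattern(s, part, within), node
        if kind not in ("vsplit", "hsplit"):
            raise ValueError("corrupt stream: prediction flag in residue tree")
        cd = _child_dims(kind, dims)
        a, na = self._parse_residue(cd, None)
        b, nb = self._parse_residue(cd, None)
        axis = 1 if kind == "vsplit" else 0
        rec = np.concatenate([a, b], axis=axis)
        self.state.dictionary_update(rec, s)
        return rec, TreeNode(kind, dims, children=(na, nb))

    def _parse_pred_node(self, r: int, c: int, dims: tuple[int, int],
                         recon: np.ndarray, mask: np.ndarray) -> TreeNode:
        m, n = dims
        s = scale_index(m, n)
        flag = self._parse_flag(s)
        kind = entropy._KIND_OF_FLAG[flag]
        if kind in ("pred_vsplit", "pred_hsplit"):
            cm, cn = _child_dims(kind, dims)
            r2, c2 = (r, c + cn) if kind == "pred_vsplit" else (r + cm, c)
            a = self._parse_pred_node(r, c, (cm, cn), recon, mask)
            b = self._parse_pred_node(r2, c2, (cm, cn), recon, mask)
            return TreeNode(kind, dims, children=(a, b))
        mode = self._parse_mode(s)
        if mode != NO_PRED:
            refs = build_reference_vectors(recon, mask, (r, c), dims)
            p = predict_block(refs, mode, dims)
        else:
            p = np.zeros(dims, dtype=np.int64)
        rhat, node = self._parse_residue(dims, flag)
        node = dataclasses.replace(node, mode=mode)
        recon[r:r + m, c:c + n] = p + rhat
        mask[r:r + m, c:c + n] = True
        return node

    def decode(self, payload: bytes, n_rows: int, n_cols: int
               ) -> tuple[np.ndarray, list[TreeNode]]:
        """Decode a payload into the K×L matrix (true, unpadded dims)."""
        pr = -(-n_rows // BLOCK) * BLOCK
        pc = -(-n_cols // BLOCK) * BLOCK
        self._dec = entropy.ArithmeticDecoder(payload)
        recon = np.zeros((pr, pc), dtype=np.int64)
        mask = np.zeros(recon.shape, dtype=bool)
        trees = []
        br = bc = 0
        try:
            for br in range(0, pr, BLOCK):
                for bc in range(0, pc, BLOCK):
                    trees.append(self._parse_pred_node(
                        br, bc, (BLOCK, BLOCK), recon, mask))
        except (ValueError, IndexError, KeyError) as exc:
            raise ValueError(
                f"corrupt stream near block ({br // BLOCK}, {bc // BLOCK}): {exc}"
            ) from exc
        self.recon_padded = recon
        return recon[:n_rows, :n_cols], trees


# ---------------------------------------------------------------------------
# Module-level convenience wrappers
# ---------------------------------------------------------------------------

def optimize_block(block: np.ndarray, lam: float,
                   config: MmpConfig | None = None) -> TreeNode:
    """Optimize a single 16×16 block with a fresh dictionary/model state."""
    block = np.asarray(block, dtype=np.int64)
    if block.shape != (BLOCK, BLOCK):
        raise ValueError("optimize_block expects a 16x16 block")
    enc = Mmp2dEncoder(lam, config)
    trees, _, _, _ = enc.encode(block)
    return trees[0]


def encode_matrix(values: np.ndarray, lam: float,
                  config: MmpConfig | None = None
                  ) -> tuple[list[TreeNode], np.ndarray, bytes, int]:
    """Encode a K×L matrix; returns (trees, padded recon, payload, x_max)."""
    return Mmp2dEncoder(lam, config).encode(values)


def decode_matrix(payload: bytes, n_rows: int, n_cols: int, x_max: int,
                  lam: float, config: MmpConfig | None = None) -> np.ndarray:
    """Decode a payload produced by :func:`encode_matrix`."""
    dec = Mmp2dDecoder(x_max, lam, config)
    values, _ = dec.decode(payload, n_rows, n_cols)
    return values
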