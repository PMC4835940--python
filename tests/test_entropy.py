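"""Arithmetic coding layer, tree symbol strings, and the container format."""

import math

import numpy as np
import pytest

from mmp2d.entropy import (
    ArithmeticDecoder,
    ArithmeticEncoder,
    CodedHeader,
    FrequencyTable,
    arith_decode,
    arith_encode,
    deserialize_tree,
    read_container,
    serialize_tree,
    write_container,
)
from mmp2d.mmp_core import TreeNode


class TestArithmeticCoder:
    def test_empty_stream_roundtrip(self):
        blob = arith_encode([], FrequencyTable(5))
        assert arith_decode(blob, FrequencyTable(5), 0) == []

    def test_uniform_source_near_entropy(self, rng):
        syms = rng.integers(0, 5, 10_000).tolist()
        blob = arith_encode(syms, FrequencyTable(5))
        assert arith_decode(blob, FrequencyTable(5), len(syms)) == syms
        mean_bits = len(blob) * 8 / len(syms)
        # adaptive coding of a uniform 5-ary source: within 2% of H + 1 bit
        assert mean_bits <= 1.02 * (math.log2(5) + 1.0)

    def test_skewed_source_below_one_bit(self, rng):
        syms = rng.choice(5, 20_000,
                          p=[0.9, 0.025, 0.025, 0.025, 0.025]).tolist()
        blob = arith_encode(syms, FrequencyTable(5))
        assert arith_decode(blob, FrequencyTable(5), len(syms)) == syms
        assert len(blob) * 8 / len(syms) < 1.0

    def test_growing_alphabet_stays_synchronized(self, rng):
        enc_tab = FrequencyTable(2)
        enc = ArithmeticEncoder()
        syms = []
        for i in range(500):
            s = int(rng.integers(0, len(enc_tab)))
            syms.append(s)
            enc.encode_symbol(enc_tab, s)
            if i % 7 == 0:
                enc_tab.add_symbol()
        blob = enc.finish()
        dec_tab = FrequencyTable(2)
        dec = ArithmeticDecoder(blob)
        for i, expected in enumerate(syms):
            assert dec.decode_symbol(dec_tab) == expected
            if i % 7 == 0:
                dec_tab.add_symbol()

    def test_single_symbol_alphabet_costs_nothing(self):
        enc = ArithmeticEncoder()
        tab = FrequencyTable(1)
        for _ in range(1000):
            enc.encode_symbol(tab, 0)
        assert enc.n_bits == 0


def _leaf(dims, part=0, idx=0, mode=None):
    return TreeNode("leaf", dims, mode=mode, index=(part, idx))


class TestTreeSymbols:
    def test_fig_style_predicted_tree_string(self):
        # vertical prediction split; left half predicted with M1 and coded as
        # one element i0; right half predicted with M2, residue horizontally
        # segmented into i1 and a further split (i2, i3)
        tree = TreeNode("pred_vsplit", (16, 16), children=(
            _leaf((16, 8), 0, 0, mode=27),
            TreeNode("hsplit", (16, 8), mode=30, children=(
                _leaf((8, 8), 0, 1),
                TreeNode("hsplit", (8, 8), children=(
                    _leaf((4, 8), 0, 2), _leaf((4, 8), 0, 3)))))))
        syms = serialize_tree(tree)
        compact = []
        for s in syms:
            if s[0] == "flag":
                compact.append(str(s[2]))
            elif s[0] == "mode":
                compact.append(f"M{s[2]}")
            else:
                compact.append(f"i{s[3]}")
        assert compact == ["3", "0", "M27", "i0", "2", "M30", "0", "i1",
                           "2", "0", "i2", "0", "i3"]
        back = deserialize_tree(syms, (16, 16), predicted=True)
        assert serialize_tree(back) == syms

    def test_single_unpredicted_leaf(self):
        tree = _leaf((4, 4), 2, 9)
        syms = serialize_tree(tree)
        assert [s[0] for s in syms] == ["flag", "index"]
        back = deserialize_tree(syms, (4, 4), predicted=False)
        assert back.index == (2, 9)

    def test_vertical_residue_split_of_two_leaves(self):
        tree = TreeNode("vsplit", (4, 4),
                        children=(_leaf((4, 2), 0, 0), _leaf((4, 2), 0, 1)))
        syms = serialize_tree(tree)
        flags = [s[2] for s in syms if s[0] == "flag"]
        assert flags == [1, 0, 0]
        back = deserialize_tree(syms, (4, 4), predicted=False)
        assert serialize_tree(back) == syms

    def test_random_trees_roundtrip(self, rng):
        from mmp2d.prediction import NO_PRED, allowed_modes
        from mmp2d.mmp_core import MIN_PRED_SPLIT_SCALE, scale_index

        def random_tree(dims, predicted, depth=0):
            m, n = dims
            s = scale_index(m, n)
            choices = ["leaf"]
            if n >= 2:
                choices.append("vsplit")
            if m >= 2:
                choices.append("hsplit")
            if predicted and s >= MIN_PRED_SPLIT_SCALE and depth < 3:
                choices += ["pred_vsplit", "pred_hsplit"]
            kind = choices[rng.integers(0, len(choices))]
            if kind in ("pred_vsplit", "pred_hsplit"):
                cd = (m, n // 2) if kind == "pred_vsplit" else (m // 2, n)
                return TreeNode(kind, dims, children=(
                    random_tree(cd, True, depth + 1),
                    random_tree(cd, True, depth + 1)))
            mode = None
            if predicted and allowed_modes(s):
                pool = sorted(allowed_modes(s)) + [NO_PRED]
                mode = pool[rng.integers(0, len(pool))]
            if kind == "leaf":
                return TreeNode("leaf", dims, mode=mode,
                                index=(int(rng.integers(0, 26)),
                                       int(rng.integers(0, 100))))
            cd = (m, n // 2) if kind == "vsplit" else (m // 2, n)
            return TreeNode(kind, dims, mode=mode, children=(
                random_tree(cd, False), random_tree(cd, False)))

        for _ in range(1000):
            t = random_tree((16, 16), True)
            syms = serialize_tree(t)
            back = deserialize_tree(syms, (16, 16), predicted=True)
            assert serialize_tree(back) == syms

    def test_truncated_stream_rejected(self):
        tree = TreeNode("vsplit", (4, 4),
                        children=(_leaf((4, 2)), _leaf((4, 2))))
        syms = serialize_tree(tree)[:-1]
        with pytest.raises(ValueError, match="unexpected end"):
            deserialize_tree(syms, (4, 4), predicted=False)

    def test_prediction_split_below_scale_nine_rejected(self):
        syms = [("flag", 8, 3),
                ("flag", 7, 0), ("mode", 7, 1), ("index", 7, 0, 0),
                ("flag", 7, 0), ("mode", 7, 1), ("index", 7, 0, 0)]
        with pytest.raises(ValueError, match="scale"):
            deserialize_tree(syms, (2, 4), predicted=True)

    def test_flag_alphabet_is_closed(self, rng):
        # every symbol in a serialized tree is a flag 0-4, a mode, or an index
        tree = TreeNode("pred_hsplit", (16, 16), children=(
            _leaf((8, 16), 0, 0, mode=1), _leaf((8, 16), 0, 1, mode=26)))
        for s in serialize_tree(tree):
            assert s[0] in ("flag", "mode", "index")
            if s[0] == "flag":
                assert 0 <= s[2] <= 4


class TestContainer:
    def _header(self, **kw):
        base = dict(n_samples=1000, offset=0, x_max=1433, segment_length=32,
                    preprocess="none", lam=8.0, n_rows=32, n_cols=32)
        base.update(kw)
        return CodedHeader(**base)

    def test_write_read_roundtrip(self, tmp_path):
        path = tmp_path / "x.mmp2d"
        payload = bytes(range(256))
        write_container(path, self._header(), payload)
        header, back = read_container(path)
        assert back == payload
        assert header.n_samples == 1000 and header.x_max == 1433
        assert header.preprocess == "none" and header.lam == 8.0

    def test_pds_permutation_roundtrip(self, tmp_path, rng):
        perm = rng.permutation(37)
        path = tmp_path / "p.mmp2d"
        write_container(path, self._header(preprocess="pds", permutation=perm),
                        b"\x01\x02")
        header, _ = read_container(path)
        assert np.array_equal(header.permutation, perm)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.mmp2d"
        path.write_bytes(b"NOTMMP2D!" + b"\x00" * 64)
        with pytest.raises(ValueError, match="magic"):
            read_container(path)

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "t.mmp2d"
        write_container(path, self._header(), b"abcdef")
        blob = path.read_bytes()
        path.write_bytes(blob[: len(blob) - 4])
        with pytest.raises(ValueError, match="truncated"):
            read_container(path)
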