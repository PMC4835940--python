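"""Scale formula, dictionary construction/update, matching, scale transform."""

import numpy as np
import pytest

from mmp2d.mmp_core import (
    CostModel,
    MmpConfig,
    MultiscaleDictionary,
    VALID_SIDES,
    all_scales,
    best_match,
    dims_of_scale,
    init_dictionary,
    initial_levels,
    level_step,
    optimize_block,
    redundancy_threshold,
    scale_index,
    scale_transform,
    update_dictionary,
)


class TestScaleIndex:
    @pytest.mark.parametrize("dims,expected", [
        ((16, 16), 25), ((1, 1), 1), ((16, 8), 23), ((8, 16), 24),
        ((2, 1), 2), ((1, 2), 3), ((4, 4), 9),
    ])
    def test_known_values(self, dims, expected):
        assert scale_index(*dims) == expected

    def test_bijection_onto_1_to_25(self):
        scales = {scale_index(m, n): (m, n)
                  for m in VALID_SIDES for n in VALID_SIDES}
        assert sorted(scales) == list(range(1, 26))
        for s, dims in scales.items():
            assert dims_of_scale(s) == dims

    @pytest.mark.parametrize("dims", [(3, 4), (32, 16), (0, 1)])
    def test_invalid_dims_rejected(self, dims):
        with pytest.raises(ValueError):
            scale_index(*dims)


class TestInitialDictionary:
    def test_step_bands(self):
        assert level_step(-5) == 1
        assert level_step(30) == 8
        assert level_step(50) == 8
        assert level_step(15) == 4
        assert level_step(200) == 13

    def test_level_after_minus_five_is_minus_four(self):
        lv = list(initial_levels(255))
        assert lv[lv.index(-5) + 1] == -4

    def test_step_after_magnitude_thirty_is_eight(self):
        # a level of magnitude 30 sits in the third band, so the next level is
        # 8 away; the generated sequence exercises this at -30
        assert 30 + level_step(30) == 38
        lv = list(initial_levels(255))
        assert -30 in lv and lv[lv.index(-30) + 1] == -22

    def test_first_level_is_negated_maximum(self):
        assert initial_levels(255)[0] == -255

    def test_scale1_holds_every_integer(self):
        d = init_dictionary(255)
        assert d.n_entries(1) == 511
        vals = sorted(d.scales[1].pat_i[:511, 0].tolist())
        assert vals == list(range(-255, 256))

    def test_zero_level_always_present(self):
        for x_max in (1, 86, 255, 1433, 2047):
            assert 0 in initial_levels(x_max)

    def test_higher_scales_are_homogeneous_levels(self):
        d = init_dictionary(100)
        lv = initial_levels(100)
        st = d.scales[25]
        assert st.n == lv.size
        assert np.array_equal(st.pat_i[: st.n, 0], lv)
        assert (st.pat_i[: st.n] == st.pat_i[: st.n, :1]).all()


class TestRedundancyThreshold:
    @pytest.mark.parametrize("lam,expected", [
        (0.0, 20.0), (4.0, 20.0), (4.1, 40.0), (22.0, 40.0),
        (30.0, 60.0), (50.0, 60.0), (51.0, 80.0), (1e6, 80.0),
    ])
    def test_piecewise_branches(self, lam, expected):
        assert redundancy_threshold(lam) == expected

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            redundancy_threshold(-1.0)


class TestScaleTransform:
    def test_identity_dims(self, rng):
        p = rng.integers(-99, 99, (4, 8))
        assert np.array_equal(scale_transform(p, (4, 8)), p)

    def test_constant_blocks_stay_constant(self):
        for dims in ((1, 1), (16, 16), (2, 8)):
            out = scale_transform(np.full((4, 4), -37), dims)
            assert (out == -37).all()

    def test_expand_then_contract_columns_roundtrip(self):
        p = np.array([[2], [4]])
        up = scale_transform(p, (2, 2))
        assert np.array_equal(scale_transform(up, (2, 1)), p)

    def test_matches_1d_resampler_oracle(self, rng):
        # oracle: explicit 1-D linear-weights expansion applied to rows/cols
        def resample_1d(v, dst):
            src = v.size
            if dst == src:
                return v.astype(float)
            if dst > src:
                out = np.empty(dst)
                for j in range(dst):
                    pos = (j + 0.5) * src / dst - 0.5
                    i0 = int(np.floor(pos))
                    f = pos - i0
                    a = v[min(max(i0, 0), src - 1)]
                    b = v[min(max(i0 + 1, 0), src - 1)]
                    out[j] = (1 - f) * a + f * b
                return out
            f = src // dst
            return v.reshape(dst, f).mean(axis=1)

        p = rng.integers(-50, 50, (4, 2))
        got = scale_transform(p, (8, 4))
        rows = np.stack([resample_1d(p[:, c].astype(float), 8)
                         for c in range(2)], axis=1)
        oracle = np.stack([resample_1d(rows[r], 4) for r in range(8)])
        oracle = np.copysign(np.floor(np.abs(oracle) + 0.5), oracle)
        assert np.array_equal(got, oracle.astype(np.int64))

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            scale_transform(np.zeros((3, 3)), (4, 4))


class TestBestMatch:
    def _brute_force(self, block, d, lam=0.0, rates=None):
        s = scale_index(*block.shape)
        st = d.scales[s]
        best = None
        for e in range(st.n):
            diff = block.reshape(-1).astype(float) - st.pat_f[e]
            j = float(diff @ diff)
            if lam > 0 and rates is not None:
                j += lam * rates[e]
            key = (j, int(st.partition[e]), int(st.within[e]))
            if best is None or key < best:
                best = key
        return (s, best[1], best[2]), best[0]

    def test_exact_entry_at_lambda_zero(self):
        d = init_dictionary(50)
        block = np.full((4, 4), -10)  # an initial level
        (s, part, within), j = best_match(block, d)
        assert j == 0.0 and s == 9
        assert d.entry_pattern(s, part, within)[0, 0] == -10

    def test_tie_goes_to_lowest_partition_then_index(self):
        d = init_dictionary(10)
        # insert a duplicate of an initial level into a later partition
        update_dictionary(d, np.full((16, 16), 3), 25, d=-1.0)
        block = np.full((2, 2), 3)
        (s, part, within), _ = best_match(block, d)
        assert part == 0  # initial entry wins the tie

    def test_matches_exhaustive_scan(self, rng):
        d = init_dictionary(100)
        for _ in range(10):
            pat = rng.integers(-100, 100, (16, 16))
            update_dictionary(d, pat, 25, d=20.0)
        for _ in range(50):
            block = rng.integers(-100, 100, (2, 2))
            got = best_match(block, d)
            assert got == self._brute_force(block, d)

    def test_rate_term_changes_choice(self, rng):
        d = init_dictionary(20)
        st = d.scales[1]
        rates = np.zeros(st.n)
        # make the exact match absurdly expensive; a neighbor should win
        block = np.array([[7]])
        (_, _, w0), _ = best_match(block, d)
        rates[w0] = 1e9
        cost = CostModel(lam=1.0)
        (_, _, w1), _ = best_match(block, d, cost, entry_rates=rates)
        assert w1 != w0


class TestUpdateDictionary:
    def test_duplicate_pattern_rejected_everywhere(self):
        d = init_dictionary(50)
        before = {s: d.n_entries(s) for s in all_scales()}
        accepted = update_dictionary(d, np.full((16, 16), -22), 25, d=20.0)
        assert accepted == []
        assert {s: d.n_entries(s) for s in all_scales()} == before

    def test_distant_pattern_grows_every_nonexhaustive_scale(self, rng):
        # scale 1 already holds every integer, so nothing new can ever clear
        # the redundancy distance there; all other scales must accept
        d = init_dictionary(500)
        pat = rng.integers(-500, 500, (16, 16))
        accepted = update_dictionary(d, pat, 25, d=20.0)
        assert sorted(accepted) == [s for s in all_scales() if s != 1]

    def test_additive_symmetric_adds_negation(self, rng):
        d = init_dictionary(500)
        pat = rng.integers(200, 500, (16, 16))
        update_dictionary(d, pat, 25, d=20.0, additive_symmetric=True)
        st = d.scales[25]
        added = st.pat_i[st.n - 2: st.n]
        assert np.array_equal(added[1], -added[0])

    def test_cap_blocks_insertion(self, rng):
        n_init = init_dictionary(50).n_entries(25)
        d = MultiscaleDictionary(50, cap=n_init)  # scale 25 already full
        accepted = update_dictionary(d, rng.integers(-50, 50, (16, 16)), 25,
                                     d=0.0)
        assert 25 not in accepted


class TestOptimizeBlock:
    def test_lambda_zero_reconstructs_exactly(self, rng, desk_config):
        from mmp2d.mmp_core import Mmp2dEncoder
        x = rng.integers(-200, 200, (16, 16))
        enc = Mmp2dEncoder(0.0, desk_config)
        _, recon, _, _ = enc.encode(x)
        assert np.array_equal(recon, x)

    def test_homogeneous_block_large_lambda_single_leaf(self):
        tree = optimize_block(np.full((16, 16), -22), lam=5000.0)
        assert tree.kind == "leaf"
        assert tree.mode is not None

    def test_cost_never_worse_than_unsegmented_leaf(self, rng, desk_config):
        # pruning optimality: the chosen tree's distortion at lam=0 is zero,
        # which no unsegmented leaf of a random block can beat
        from mmp2d.mmp_core import Mmp2dEncoder
        x = rng.integers(-300, 300, (16, 16))
        enc = Mmp2dEncoder(0.0, desk_config)
        _, recon, _, _ = enc.encode(x)
        assert np.array_equal(recon, x)
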