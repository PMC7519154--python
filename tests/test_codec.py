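"""Unit tests for the compression primitives: DC removal, domain selection,
pool construction, the affine fit, quantization, matching and recursive
range encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scyf
from scyf.codec import Domain, _expand_domain, _pairwise_mean
from scyf.errors import (
    ConfigurationError,
    InvalidInputError,
    MissingAnnotationError,
)

from conftest import brute_force_match, leaves_equal


# ---------------------------------------------------------------- subtract_dc

@pytest.mark.parametrize(
    "x, expected_x0, expected_dc",
    [
        ([5, 5, 5], [0, 0, 0], 5.0),
        ([1, 2, 3], [-1, 0, 1], 2.0),
    ],
)
def test_subtract_dc_examples(x, expected_x0, expected_dc):
    x0, dc = scyf.subtract_dc(x)
    assert dc == expected_dc
    np.testing.assert_array_equal(x0, expected_x0)


def test_subtract_dc_empty_rejected():
    with pytest.raises(InvalidInputError):
        scyf.subtract_dc([])


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=200))
def test_subtract_dc_zero_mean_property(x):
    x0, dc = scyf.subtract_dc(x)
    scale = max(1.0, max(abs(v) for v in x))
    # exact-summation oracle for the residual mean
    assert abs(math.fsum(x0) / len(x0)) < 1e-12 * scale


# -------------------------------------------------------------- select_domain

def test_select_domain_manual_passthrough():
    cfg = scyf.CodecConfig(block_size=256)
    x0 = np.zeros(1000)
    d = scyf.select_domain(x0, cfg, cycle_bounds=(100, 612))
    assert (d.start, d.end, len(d.samples)) == (100, 612, 512)


def test_select_domain_auto_picks_median_length_cycle():
    # lengths 500, 510, 490, 505, 495 -> median 500 -> earliest cycle [0, 500)
    onsets = [0, 500, 1010, 1500, 2005, 2500]
    cfg = scyf.CodecConfig(block_size=256)
    d = scyf.select_domain(np.zeros(2600), cfg, p_onsets=onsets)
    assert (d.start, d.end) == (0, 500)


def test_select_domain_halved_stores_pairwise_means():
    cfg = scyf.CodecConfig(block_size=256, domain_halved=True)
    x0 = np.arange(512, dtype=float)
    d = scyf.select_domain(x0, cfg, cycle_bounds=(0, 512))
    assert len(d.samples) == 256
    np.testing.assert_allclose(d.samples, np.arange(512).reshape(-1, 2).mean(axis=1))


def test_select_domain_errors():
    cfg = scyf.CodecConfig(block_size=256)
    with pytest.raises(ConfigurationError):
        scyf.select_domain(np.zeros(300), cfg, cycle_bounds=(0, 100))
    with pytest.raises(MissingAnnotationError):
        scyf.select_domain(np.zeros(300), cfg)


def test_halved_domain_expansion_inverts_averaging_to_first_order():
    # a linear ramp is reproduced exactly by interpolate-after-average
    x = np.linspace(0.0, 10.0, 512)
    half = _pairwise_mean(x)
    full = _expand_domain(half, 512, halved=True)
    np.testing.assert_allclose(full[1:-1], x[1:-1], atol=1e-12)


# ----------------------------------------------------------- build_domain_pool

@pytest.mark.parametrize(
    "ld, bs, js, max_div, expected",
    [
        (512, 256, 1, 0, {256: 257}),
        (512, 256, 1, 2, {256: 257, 128: 385, 64: 449}),
        (256, 256, 1, 0, {256: 1}),
        (512, 256, 3, 1, {256: 86, 128: 129}),
    ],
)
def test_pool_counts(ld, bs, js, max_div, expected):
    cfg = scyf.CodecConfig(block_size=bs, jump_step=js, max_divisions=max_div)
    pool = scyf.build_domain_pool(
        Domain(samples=np.zeros(ld), start=0, end=ld), cfg
    )
    assert {L: pool.count(L) for L in pool.sizes} == expected


def test_pool_blocks_lie_inside_domain_and_match_offsets():
    cfg = scyf.CodecConfig(block_size=64, jump_step=5, max_divisions=1)
    x = np.arange(200, dtype=float)
    pool = scyf.build_domain_pool(Domain(samples=x, start=0, end=200), cfg)
    for L in pool.sizes:
        blocks = pool.blocks(L)
        assert blocks.shape == (pool.count(L), L)
        last_off = (pool.count(L) - 1) * 5
        assert last_off + L <= 200
        np.testing.assert_array_equal(blocks[-1], x[last_off : last_off + L])


def test_pool_shorter_than_block_rejected():
    cfg = scyf.CodecConfig(block_size=256)
    with pytest.raises(ConfigurationError):
        scyf.build_domain_pool(Domain(samples=np.zeros(100), start=0, end=100), cfg)


# -------------------------------------------------------------- pairwise_swap

def test_pairwise_swap_definition_and_involution():
    np.testing.assert_array_equal(scyf.pairwise_swap([1, 2, 3, 4]), [2, 1, 4, 3])
    np.testing.assert_array_equal(scyf.pairwise_swap([5, 5]), [5, 5])
    rng = np.random.default_rng(0)
    b = rng.normal(size=64)
    np.testing.assert_array_equal(scyf.pairwise_swap(scyf.pairwise_swap(b)), b)
    with pytest.raises(InvalidInputError):
        scyf.pairwise_swap([1, 2, 3])


# ----------------------------------------------------------------- fit_affine

def test_fit_affine_identity_and_exact_pairs():
    d = np.array([0.0, 1.0, 2.0, 5.0])
    s, o, frms = scyf.fit_affine(d, d)
    assert (s, o) == pytest.approx((1.0, 0.0), abs=1e-12)
    assert frms == pytest.approx(0.0, abs=1e-12)
    s, o, frms = scyf.fit_affine(d, 2.0 * d + 3.0)
    assert (s, o) == pytest.approx((2.0, 3.0), abs=1e-12)
    assert frms == pytest.approx(0.0, abs=1e-12)


def test_fit_affine_against_generic_least_squares():
    d = np.array([0.0, 1.0, 2.0, 3.0])
    r = np.array([1.0, 3.0, 2.0, 0.0])
    s, o, frms = scyf.fit_affine(d, r)
    # independent oracle: generic lstsq on the design matrix [d, 1]
    coef, res, *_ = np.linalg.lstsq(np.c_[d, np.ones(4)], r, rcond=None)
    assert s == pytest.approx(coef[0], rel=1e-12)
    assert o == pytest.approx(coef[1], rel=1e-12)
    assert s == pytest.approx(-0.4) and o == pytest.approx(2.1)
    # lstsq reports the residual sum of squares; FRMS is its root mean
    assert frms == pytest.approx(math.sqrt(res[0] / 4), rel=1e-12)
    assert frms == pytest.approx(math.sqrt(1.05), rel=1e-12)


def test_fit_affine_degenerate_constant_domain():
    s, o, frms = scyf.fit_affine(np.full(8, 3.0), np.arange(8.0))
    assert s == 0.0 and o == pytest.approx(3.5)


def test_fit_affine_length_mismatch():
    with pytest.raises(InvalidInputError):
        scyf.fit_affine(np.zeros(4), np.zeros(5))


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.floats(-3, 3), st.floats(-50, 50))
def test_fit_affine_recovers_noiseless_affine_pairs(seed, s_true, o_true):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=32)
    d[0] += 1.0  # guarantee non-constant
    s, o, frms = scyf.fit_affine(d, s_true * d + o_true)
    assert s == pytest.approx(s_true, abs=1e-10 * max(1, abs(s_true)))
    assert o == pytest.approx(o_true, abs=1e-10 * max(1, abs(o_true)))
    assert frms < 1e-10


# --------------------------------------------------------------- quantization

def test_quantizer_bin_width_bound_and_clamping():
    cfg = scyf.CodecConfig(scale_bits=8, scale_range=(-2.0, 2.0))
    shift_range = (-100.0, 100.0)
    sc, oc = scyf.quantize_affine(0.0, 0.0, shift_range, cfg)
    sq, oq = scyf.dequantize_affine((sc, oc), shift_range, cfg)
    assert abs(sq) <= 4.0 / 256.0
    sc, _ = scyf.quantize_affine(10.0, 0.0, shift_range, cfg)
    assert sc == 255  # clamped into the top bin


def test_quantizer_round_trip_error_bound():
    cfg = scyf.CodecConfig(shift_bits=11)
    shift_range = (-500.0, 500.0)
    rng = np.random.default_rng(42)
    bound = 1000.0 / 2 ** (cfg.shift_bits + 1)
    for o in rng.uniform(-500, 500, size=1000):
        _, oc = scyf.quantize_affine(0.0, o, shift_range, cfg)
        _, oq = scyf.dequantize_affine((0, oc), shift_range, cfg)
        assert abs(o - oq) <= bound + 1e-12


def test_lossless_mode_passes_coefficients_through():
    cfg = scyf.CodecConfig(lossless_coeffs=True)
    codes = scyf.quantize_affine(0.123456, -7.89, (-10, 10), cfg)
    assert scyf.dequantize_affine(codes, (-10, 10), cfg) == (0.123456, -7.89)


# ---------------------------------------------------------------- match_block

def _small_pool(rng, ld=96, bs=32, js=2, max_div=1):
    cfg = scyf.CodecConfig(block_size=bs, jump_step=js, max_divisions=max_div,
                           frms_limit=1.0)
    dom = rng.normal(size=ld)
    pool = scyf.build_domain_pool(Domain(samples=dom, start=0, end=ld), cfg)
    return cfg, pool


def test_match_block_finds_exact_member():
    rng = np.random.default_rng(7)
    cfg, pool = _small_pool(rng)
    cfg = cfg.with_(lossless_coeffs=True)
    r = pool.block(32, 5).copy()
    leaf = scyf.match_block(r, pool, (-5, 5), cfg)
    assert leaf.db_index == 5 and leaf.transform == 0
    assert leaf.frms == pytest.approx(0.0, abs=1e-12)


def test_match_block_finds_constructed_swap_match():
    rng = np.random.default_rng(8)
    cfg, pool = _small_pool(rng)
    cfg = cfg.with_(lossless_coeffs=True)
    r = scyf.pairwise_swap(pool.block(32, 9).copy())
    leaf = scyf.match_block(r, pool, (-5, 5), cfg)
    assert leaf.db_index == 9 and leaf.transform == 1
    assert leaf.frms == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_match_block_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    cfg, pool = _small_pool(rng, ld=80, bs=32, js=1, max_div=1)
    shift_range = (-6.0, 6.0)
    for size in pool.sizes:
        r = rng.normal(size=size)
        got = scyf.match_block(r, pool, shift_range, cfg)
        want = brute_force_match(r, pool, shift_range, cfg)
        assert leaves_equal(got, want, frms_rel=1e-9)


# --------------------------------------------------------------- encode_range

def oracle_encode(r, pool, shift_range, cfg, depth=0):
    leaf = brute_force_match(r, pool, shift_range, cfg)
    if leaf.frms <= cfg.frms_limit or depth >= cfg.max_divisions:
        return scyf.RangeNode(depth=depth, leaf=leaf)
    half = len(r) // 2
    return scyf.RangeNode(
        depth=depth,
        children=(
            oracle_encode(r[:half], pool, shift_range, cfg, depth + 1),
            oracle_encode(r[half:], pool, shift_range, cfg, depth + 1),
        ),
    )


def _tree_shapes_and_leaves(node):
    if node.is_leaf:
        return [("leaf", node.depth, node.leaf.db_index, node.leaf.transform)]
    out = [("split", node.depth)]
    for c in node.children:
        out.extend(_tree_shapes_and_leaves(c))
    return out


def test_encode_range_infinite_limit_gives_depth0_leaf():
    rng = np.random.default_rng(1)
    cfg, pool = _small_pool(rng)
    cfg = cfg.with_(frms_limit=float("inf"))
    node = scyf.encode_range(rng.normal(size=32), pool, (-6, 6), cfg)
    assert node.is_leaf and node.depth == 0


def test_encode_range_unmeetable_limit_gives_full_depth_tree():
    rng = np.random.default_rng(2)
    cfg = scyf.CodecConfig(block_size=32, jump_step=1, max_divisions=2,
                           frms_limit=1e-12)
    dom = rng.normal(size=96)
    pool = scyf.build_domain_pool(Domain(samples=dom, start=0, end=96), cfg)
    node = scyf.encode_range(rng.normal(size=32), pool, (-6, 6), cfg)
    leaves = list(node.iter_leaves())
    assert len(leaves) == 4 and all(l.size == 8 for l in leaves)
    assert node.max_depth() == 2


@pytest.mark.parametrize("seed", range(5))
def test_encode_range_matches_oracle_recursion(seed):
    rng = np.random.default_rng(100 + seed)
    cfg = scyf.CodecConfig(block_size=32, jump_step=1, max_divisions=2,
                           frms_limit=0.5)
    dom = rng.normal(size=96)
    pool = scyf.build_domain_pool(Domain(samples=dom, start=0, end=96), cfg)
    r = rng.normal(size=32)
    got = scyf.encode_range(r, pool, (-6, 6), cfg)
    want = oracle_encode(r, pool, (-6, 6), cfg)
    assert _tree_shapes_and_leaves(got) == _tree_shapes_and_leaves(want)


# ------------------------------------------------------------------- compress

def test_compress_exact_tiling_all_depth0_identity_leaves(tiled_signal):
    x, onsets = tiled_signal
    cfg = scyf.CodecConfig(block_size=256, frms_limit=12.0, lossless_coeffs=True)
    c = scyf.compress(x, 500.0, 16, cfg, cycle_bounds=(0, 256))
    leaves = list(c.iter_leaves())
    assert len(leaves) == len(x) // 256
    for leaf in leaves:
        assert leaf.frms == pytest.approx(0.0, abs=1e-9)
        assert leaf.scale_code == pytest.approx(1.0, abs=1e-9)
        assert leaf.shift_code == pytest.approx(0.0, abs=1e-7)


def test_compress_preset_echo_in_header():
    x, onsets = scyf.generate_ecg(scyf.GeneratorSpec(seed=5))
    c = scyf.compress(x, 500.0, 16, scyf.preset("cse"), p_onsets=onsets)
    cfg = c.config
    assert (cfg.block_size, cfg.jump_step, cfg.frms_limit, cfg.max_divisions) == \
        (256, 1, 12.0, 2)


def test_compress_tail_padding_and_crop():
    rng = np.random.default_rng(3)
    x = rng.normal(size=1000) + np.sin(np.arange(1000) / 30.0)
    cfg = scyf.CodecConfig(block_size=256, frms_limit=1e-9, max_divisions=1)
    c = scyf.compress(x, 500.0, 16, cfg, cycle_bounds=(0, 300))
    assert len(c.trees) == 4 and c.n_padded == 1024
    rec = scyf.reconstruct(c)
    assert len(rec.signal) == 1000


def test_compress_rejects_bad_inputs():
    cfg = scyf.CodecConfig(block_size=256)
    with pytest.raises(ConfigurationError):
        scyf.compress(np.zeros(100), 500.0, 16, cfg, cycle_bounds=(0, 100))
    x = np.ones(600)
    x[5] = np.nan
    with pytest.raises(InvalidInputError):
        scyf.compress(x, 500.0, 16, cfg, cycle_bounds=(0, 300))


def test_frms_contract_on_noisy_record():
    """Every leaf above the maximum depth satisfies the split threshold."""
    from conftest import noisy_record

    x, onsets = noisy_record(seed=11, duration=6.0)
    cfg = scyf.preset("mitadb")
    c = scyf.compress(x, 500.0, 16, cfg, p_onsets=onsets)

    def walk(node):
        if node.is_leaf:
            assert node.depth <= cfg.max_divisions
            if node.depth < cfg.max_divisions:
                assert node.leaf.frms <= cfg.frms_limit
        else:
            for ch in node.children:
                walk(ch)

    for t in c.trees:
        walk(t)
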