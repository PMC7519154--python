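import numpy as np
import pytest

import scyf
from scyf.codec import DomainPool


ADC_GAIN = 200.0  # counts per synthetic amplitude unit (R wave = 1.0)


def tiled_spec(n_tiles: int = 8, cycle: int = 256, fs: float = 500.0, seed: int = 1):
    """Zero-jitter generator spec whose output tiles `cycle` samples exactly."""
    return scyf.GeneratorSpec(
        fs=fs,
        duration=n_tiles * cycle / fs,
        heart_rate=60.0 * fs / cycle,
        rr_jitter=0.0,
        amp_jitter=0.0,
        noise_sd=0.0,
        baseline_amp=0.0,
        seed=seed,
    )


def noisy_record(seed: int, duration: float = 10.0, noise_sd: float = 0.01,
                 gain: float = ADC_GAIN):
    """Realistic jittered record in integer ADC counts, with its onsets."""
    spec = scyf.GeneratorSpec(duration=duration, noise_sd=noise_sd, seed=seed)
    x, onsets = scyf.generate_ecg(spec)
    return np.round(x * gain), onsets


@pytest.fixture(scope="session")
def tiled_signal():
    x, onsets = scyf.generate_ecg(tiled_spec())
    return x, onsets


def random_compressed(rng: np.random.Generator) -> scyf.CompressedECG:
    """A well-formed randomized CompressedECG, built by actually compressing
    a random short synthetic record under a randomized configuration."""
    bs = int(rng.choice([32, 64, 128]))
    max_div = int(rng.integers(0, 3))
    cfg = scyf.CodecConfig(
        block_size=bs,
        jump_step=int(rng.integers(1, 4)),
        frms_limit=float(rng.uniform(0.5, 20.0)),
        max_divisions=max_div,
        domain_halved=bool(rng.integers(0, 2)),
        extension=int(rng.choice([0, 10])),
        lossless_coeffs=bool(rng.integers(0, 2)),
    )
    # keep the cycle comfortably above BS so RR jitter cannot shrink the
    # selected domain below one block
    cycle = int(rng.integers(int(1.3 * bs), 2 * bs + 1))
    fs = 250.0
    spec = scyf.GeneratorSpec(
        fs=fs,
        duration=max(5 * cycle, 3 * bs) / fs,
        heart_rate=60.0 * fs / cycle,
        noise_sd=0.02,
        dc_offset=float(rng.uniform(-1, 1)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    x, onsets = scyf.generate_ecg(spec)
    if rng.integers(0, 2):  # integer-payload path
        x = np.round(x * ADC_GAIN)
    return scyf.compress(x, fs, 16, cfg, p_onsets=onsets)


def leaves_equal(a: scyf.MatchLeaf, b: scyf.MatchLeaf, frms_rel: float = 0.0) -> bool:
    """Compare leaves field-for-field; frms is encoder bookkeeping and is
    compared with a relative tolerance (0 = must both be NaN-free equal)."""
    if (a.size, a.db_index, a.transform) != (b.size, b.db_index, b.transform):
        return False
    if isinstance(a.scale_code, int) != isinstance(b.scale_code, int):
        return False
    if isinstance(a.scale_code, int):
        if (a.scale_code, a.shift_code) != (b.scale_code, b.shift_code):
            return False
    else:
        tol = 1e-9
        if abs(a.scale_code - b.scale_code) > tol * max(1.0, abs(a.scale_code)):
            return False
        if abs(a.shift_code - b.shift_code) > tol * max(1.0, abs(a.shift_code)):
            return False
    if frms_rel:
        return abs(a.frms - b.frms) <= frms_rel * max(1.0, abs(a.frms))
    return True


def trees_equal(a: scyf.RangeNode, b: scyf.RangeNode) -> bool:
    if a.is_leaf != b.is_leaf or a.depth != b.depth:
        return False
    if a.is_leaf:
        return leaves_equal(a.leaf, b.leaf)
    return all(trees_equal(x, y) for x, y in zip(a.children, b.children))


def compressed_equal(a: scyf.CompressedECG, b: scyf.CompressedECG) -> bool:
    """Field-for-field equality of two CompressedECG (frms excluded: it is
    not serialized)."""
    return (
        a.fs == b.fs
        and a.n_samples == b.n_samples
        and a.source_bits == b.source_bits
        and a.dc_value == b.dc_value
        and a.config == b.config
        and a.shift_range == b.shift_range
        and np.array_equal(a.domain_payload, b.domain_payload)
        and a.domain_start == b.domain_start
        and a.domain_end == b.domain_end
        and len(a.trees) == len(b.trees)
        and all(
            _trees_equal_ignore_frms(x, y) for x, y in zip(a.trees, b.trees)
        )
    )


def _trees_equal_ignore_frms(a, b):
    if a.is_leaf != b.is_leaf or a.depth != b.depth:
        return False
    if a.is_leaf:
        la, lb = a.leaf, b.leaf
        if (la.size, la.db_index, la.transform) != (lb.size, lb.db_index, lb.transform):
            return False
        if isinstance(la.scale_code, int):
            return (la.scale_code, la.shift_code) == (lb.scale_code, lb.shift_code)
        return la.scale_code == lb.scale_code and la.shift_code == lb.shift_code
    return all(_trees_equal_ignore_frms(x, y) for x, y in zip(a.children, b.children))


def brute_force_match(r, pool: DomainPool, shift_range, cfg) -> scyf.MatchLeaf:
    """Independent exhaustive matcher: double loop over every domain block
    and both transforms, scalar affine fit, same post-quantization scoring
    and (frms, db_index, transform) tie-break."""
    size = len(r)
    best = None
    for transform in (0, 1):
        for k in range(pool.count(size)):
            d = pool.block(size, k)
            dt = scyf.pairwise_swap(d) if transform else d
            s, o, _ = scyf.fit_affine(dt, r)
            codes = scyf.quantize_affine(s, o, shift_range, cfg)
            sq, oq = scyf.dequantize_affine(codes, shift_range, cfg)
            resid = sq * dt + oq - r
            frms = float(np.sqrt((resid * resid).mean()))
            cand = (frms, k, transform, codes)
            if best is None or cand[:3] < best[:3]:
                best = cand
    frms, k, transform, (sc, oc) = best
    return scyf.MatchLeaf(size=size, db_index=k, scale_code=sc, shift_code=oc,
                          transform=transform, frms=frms)
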