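"""The fractal matching step in isolation.

Builds a domain pool from one stored cycle, then shows how a range block
is approximated: the best overlapping domain block is found, the affine
(scale, shift) pair fitted by least squares, quantized, and the fractal
RMS residual (FRMS) reported.  FRMS is the quantity the split threshold
acts on during compression.
"""

import numpy as np

import scyf
from scyf.codec import Domain

rng = np.random.default_rng(0)

# one synthetic cycle as the domain, 512 samples
cycle = scyf.beat_template(cycle_length=512).samples * 200.0
config = scyf.CodecConfig(block_size=256, jump_step=1, max_divisions=2,
                          frms_limit=12.0)
pool = scyf.build_domain_pool(Domain(samples=cycle, start=0, end=512), config)
print(f"domain pool: {[f'{L}: {pool.count(L)} blocks' for L in pool.sizes]}")

# a range block: a shifted, scaled, noisy copy of part of the cycle
r = 0.8 * cycle[40:296] + 15.0 + rng.normal(0, 3.0, 256)

s, o, frms = scyf.fit_affine(cycle[40:296], r)
print(f"direct affine fit against the true source block: "
      f"s={s:.3f}, o={o:.2f}, FRMS={frms:.2f}")

leaf = scyf.match_block(r, pool, shift_range=(-100.0, 250.0), config=config)
s_q, o_q = scyf.dequantize_affine((leaf.scale_code, leaf.shift_code),
                                  (-100.0, 250.0), config)
print(f"matcher: domain block #{leaf.db_index} "
      f"(true offset 40), transform={'swap' if leaf.transform else 'none'}, "
      f"dequantized s={s_q:.3f}, o={o_q:.2f}, FRMS={leaf.frms:.2f}")
print("FRMS is in ADC counts; a value under the limit (12) stops division.")
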