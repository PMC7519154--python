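# Methods

## Model and procedure

The codec treats a single-lead ECG as approximately self-similar across
beats.  One cycle of the record — from a P-wave onset to the next — is
stored verbatim as the *domain*; the rest of the signal is expressed as
affine maps of overlapping sub-blocks of that cycle.

Encoding pipeline, in order:

1. **Optional mirror extension** by `E` samples per side.  Mirror (rather
   than zero or edge-replicate) padding avoids introducing a discontinuity
   that the matcher would have to spend divisions on.  The padding is
   cropped again after decoding.
2. **DC removal.**  The arithmetic mean of the (extended) signal is
   subtracted and carried in the header; all matching happens on the
   zero-mean signal.  This is what makes the PRDN/SNR numbers honest:
   a large offset can otherwise mask distortion.
3. **Domain selection.**  With explicit bounds, the half-open window
   `[start, end)` is used as given.  With P-onset annotations, the cycle
   among the first five whose length is closest to their median length is
   chosen (earliest on ties).  This automates the otherwise manual "most
   representative cycle" choice deterministically; it is a heuristic, and
   explicit bounds always override it.
4. **Domain pool.**  At every permitted leaf size
   `L ∈ {BS/2^k, k = 0..max_divisions}` the domain is cut into overlapping
   blocks at offsets `0, JS, 2·JS, …`; there are `⌊(Ld−L)/JS⌋ + 1` of
   them.  With `JS = 1` the pool at size `L/2` contains both halves of
   every size-`L` block, which is what makes block division monotone in
   quality (see below).
5. **Range encoding.**  The signal is split into consecutive
   non-overlapping `BS`-sample range blocks (tail zero-padded to a
   multiple of `BS`; the true sample count is in the header and the
   padding cropped on decode).  For each range block, every domain block
   of the same size is tried under both transforms (identity and pairwise
   swap of adjacent samples), with the least-squares affine pair fitted in
   closed form.  Candidates are ranked by the residual achieved *after*
   coefficient quantization, so the stored code is the one actually best
   after coding — ranking on unquantized fits can pick a candidate whose
   coded version is worse.  Ties break to the lower domain-block index,
   then identity before swap, for cross-platform determinism.  If the best
   FRMS exceeds the limit and depth allows, the block is halved and each
   half encoded independently (an asymmetric binary tree, encoded with
   per-node split bits); at maximum depth the best match is kept
   regardless.
6. **Decoding** rebuilds the domain and pool deterministically from the
   header and evaluates each leaf once, in temporal order — a single pass.
   The encoder derives its own matching domain from the exact payload it
   stores, so encoder and decoder pools are bit-identical by construction.

## Parameters

| knob | unit | default | why |
|---|---|---|---|
| `block_size` (BS) | samples | 256 | power of two so halving stays integral; ≤ domain length |
| `jump_step` (JS) | samples | 1 | densest pool; also guarantees division monotonicity |
| `frms_limit` | amplitude counts | 12 | split threshold in the units of the stored samples |
| `max_divisions` | — | 2 | deepest leaf is BS/4; must leave ≥ 2 samples |
| `scale_bits`, `scale_range` | bits, — | 8 over [−2, 2] | scale quantizer; bin 1/64, well below useful FRMS limits |
| `shift_bits` | bits | 11 | shift quantizer over the per-record amplitude span (header) |
| `extension` | samples/side | 0 | mirror padding for short records |
| `domain_halved` | flag | off | store the cycle at half rate (pairwise means) |
| `smooth`, `smooth_span` | flag, samples | off, 7 | post-decode local-quadratic smoothing |

Presets mirror the per-database settings: `cse`/`upt`/`butqdb` =
(256, 1, 12, 2), `mitadb` = (128, 1, 5, 3).  The FRMS limits are
interpreted in stored-sample units (ADC counts for integer records).

Quantization is uniform mid-rise: values are clamped into range, codes map
back to bin centers, so the shift round-trip error is bounded by
(range width)/2^(bits+1).  A `lossless_coeffs` debug mode carries raw
64-bit coefficients instead, which is what the exact-reconstruction tests
use.

## Bitstream

`.scyf` = magic/version, a fixed-width little-endian header (provenance,
config echo, quantizer ranges, domain window), the domain payload, then
MSB-first body bits: per node one split bit while above maximum depth,
and per leaf `[index][transform][scale][shift]` with the index width
`⌈log2(pool count)⌉` re-derived from the header.  The payload is stored as
`source_bits`-wide two's-complement integers when every sample is an
integer in range, else as raw doubles (one header flag) — both paths are
exactly invertible, which the round-trip suite checks field-for-field.
`avL`/`CF` count the whole stream including header, domain and padding:
the stored domain is the dominant fixed cost on short records, which is
why the codec favors long, high-rate signals.

## Smoothing

The optional smoother is local polynomial regression: each sample is
replaced by the value of a tricube-weighted quadratic least-squares fit
over a centered window (span 7 by default, shrunk at edges).  Quadratics
and constants are reproduced exactly.  Whether smoothing helps depends on
the record — it softens block seams but also rounds the R peak — so it is
strictly opt-in and off by default.

## Synthetic data

The generator emulates exactly the structure the codec exploits:
quasiperiodicity.  A beat is five Gaussian bumps (P, Q, R, S, T with R = 1
unit at 23% of the cycle); records concatenate beats whose length and
amplitude are jittered beat-to-beat (5% sd each by default), plus 0.05-unit
sinusoidal baseline wander at 0.33 Hz, white noise at 1% of R, and an
optional DC offset, all from one seeded generator (`fs` 500 Hz, 60 bpm,
10 s by default).  Tests scale by a gain of 200 counts/unit to work in
16-bit integer ADC counts.

What it does *not* emulate: real ECG morphology variability (notched QRS,
arrhythmia, pacemaker spikes), electrode artefacts, or correlated noise.
Its per-beat resampling jitters the *shape* of every beat, which is
substantially harsher on a single-cycle codec than a stable clinical
recording — the distortion figures measured on synthetic records are
therefore pessimistic and demonstrate correct mechanics and trends
(noise ↑ ⇒ PRDN ↑, divisions ↑ ⇒ PRDN ↓ and bits ↑), not clinical-grade
operating points.

## Numerical choices and degenerate inputs

- Constant domain block: the affine system is rank-deficient; the
  minimum-norm solution `s = 0, o = mean(r)` is used.
- Tie-breaks in matching are exact lexicographic (FRMS, index, transform).
- Coordinates are 0-based half-open throughout.
- Halved domains are re-expanded by linear interpolation at the pairwise
  centers before pool building (the first-order inverse of averaging), so
  domain- and range-block lengths stay commensurate.
- Tail handling: zero-pad to a block multiple, record the true length,
  crop after decoding.
- A perfect reconstruction reports `SNR = +inf` and `QS = +inf` sentinels;
  PRDN is undefined (error) for a constant original.

## Problem sizes used in the tests and acceptance script

The suite runs on 5–10 s records at 500 Hz (2 500–5 000 samples), 20-record
batches for contract/monotonicity checks, 50 matcher-oracle instances with
pools up to ~250 blocks, and 100 randomized container round-trips; the
acceptance script uses 10 records of 10 s per preset.  These sizes exercise
every code path (splits at all depths, both transforms, both payload
encodings, halved domains, extensions) while keeping a full run in the
order of seconds to a couple of minutes on one CPU.

## Known limitations

- Single lead only; no streaming or real-time operation.
- The stored domain makes very short records expensive (low CF).
- Automatic domain selection is a length heuristic, not a quality measure;
  a badly chosen cycle degrades every match.
- No entropy coding of the body: avL could be lowered further by Huffman
  or arithmetic coding of indices and codes.
- WFDB binary records are not read directly; convert to CSV first.
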