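"""Seeded generator of quasiperiodic ECG-like test signals.

A beat is modelled as the sum of five Gaussian bumps (P, Q, R, S, T); a
record is a concatenation of per-beat templates with the beat length and
amplitude jittered beat-to-beat, plus sinusoidal baseline wander, additive
white Gaussian noise and a DC offset.  Each beat starts at the nominal
P-wave onset, so the returned onset list doubles as cycle boundaries for
the codec.  The morphology is deliberately schematic — it exercises the
matching, division and quantization paths, not physiology.

Default condition: 500 Hz sampling, 60 bpm, 5% RR and amplitude jitter,
noise at 1% of the R amplitude, 0.05-unit baseline wander at a 0.33 Hz
respiratory rate.  Amplitudes are in arbitrary units with R = 1; scale the
output (e.g. by an ADC gain) to work in integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = ["BeatTemplate", "GeneratorSpec", "beat_template", "generate_ecg",
           "DEFAULT_WAVES"]

#: (amplitude, center fraction of cycle, width fraction of cycle) per wave.
DEFAULT_WAVES: Dict[str, Tuple[float, float, float]] = {
    "P": (0.15, 0.09, 0.022),
    "Q": (-0.10, 0.20, 0.008),
    "R": (1.00, 0.23, 0.012),
    "S": (-0.20, 0.26, 0.009),
    "T": (0.30, 0.45, 0.045),
}


@dataclass(frozen=True)
class BeatTemplate:
    """One cycle of the synthetic beat, as wave parameters plus its
    rendered sample array."""

    waves: Dict[str, Tuple[float, float, float]]
    cycle_length: int
    samples: np.ndarray = field(repr=False, default=None)


def beat_template(
    waves: Dict[str, Tuple[float, float, float]] = None,
    cycle_length: int = 512,
) -> BeatTemplate:
    """Render one beat: the sum of Gaussian bumps on ``cycle_length``
    points.  Wave centers must be strictly increasing in (0, 1), widths
    positive, and R must dominate in magnitude."""
    waves = dict(DEFAULT_WAVES if waves is None else waves)
    centers = [w[1] for w in waves.values()]
    if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
        raise InvalidInputError("wave centers must be strictly increasing")
    if any(not (0.0 < c < 1.0) for c in centers):
        raise InvalidInputError("wave centers must lie in (0, 1)")
    if any(w[2] <= 0 for w in waves.values()):
        raise InvalidInputError("wave widths must be positive")
    amps = {k: abs(v[0]) for k, v in waves.items()}
    if "R" in waves and amps and amps["R"] < max(amps.values()):
        raise InvalidInputError("R must be the largest wave in magnitude")
    t = np.arange(cycle_length, dtype=np.float64) / cycle_length
    y = np.zeros(cycle_length)
    for amp, center, width in waves.values():
        y += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return BeatTemplate(waves=waves, cycle_length=cycle_length, samples=y)


@dataclass(frozen=True)
class GeneratorSpec:
    fs: float = 500.0
    duration: float = 10.0
    heart_rate: float = 60.0
    rr_jitter: float = 0.05      # fractional sd of the beat length
    amp_jitter: float = 0.05     # fractional sd of the beat amplitude
    noise_sd: float = 0.01       # additive white noise sd, signal units
    baseline_amp: float = 0.05   # baseline wander amplitude, signal units
    baseline_freq: float = 0.33  # baseline wander frequency, Hz
    dc_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0 or self.heart_rate <= 0:
            raise ConfigurationError("fs, duration and heart_rate must be > 0")
        if min(self.rr_jitter, self.amp_jitter, self.noise_sd,
               self.baseline_amp) < 0:
            raise ConfigurationError("jitter/noise amplitudes must be >= 0")
        if self.fs * 60.0 / self.heart_rate < 4:
            raise ConfigurationError("cycle length must be at least 4 samples")
        if self.duration * self.fs < 2 * self.fs * 60.0 / self.heart_rate:
            raise ConfigurationError("duration must cover at least two cycles")


def generate_ecg(spec: GeneratorSpec) -> Tuple[np.ndarray, List[int]]:
    """Generate a record and its P-onset (beat start) indices.

    Beat ``k`` has length ``round(fs*60/hr * (1 + N(0, rr_jitter)))`` and
    amplitude scale ``1 + N(0, amp_jitter)``; the template is resampled to
    each beat length by linear interpolation.  A fixed seed gives
    bit-identical output; with all jitters, noise and baseline at zero the
    record is an exactly periodic tiling of one beat.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    base_len = spec.fs * 60.0 / spec.heart_rate
    template = beat_template(cycle_length=max(int(round(base_len)), 4))
    ref = template.samples
    ref_x = np.arange(len(ref), dtype=np.float64) / len(ref)

    signal = np.empty(n)
    onsets: List[int] = []
    pos = 0
    while pos < n:
        if spec.rr_jitter > 0:
            blen = int(round(base_len * (1.0 + rng.normal(0.0, spec.rr_jitter))))
            blen = max(blen, 4)
        else:
            blen = int(round(base_len))
        scale = 1.0 + rng.normal(0.0, spec.amp_jitter) if spec.amp_jitter > 0 else 1.0
        if blen == len(ref):
            beat = ref if scale == 1.0 else scale * ref
        else:
            x = np.arange(blen, dtype=np.float64) / blen
            beat = scale * np.interp(x, ref_x, ref)
        onsets.append(pos)
        take = min(blen, n - pos)
        signal[pos : pos + take] = beat[:take]
        pos += blen

    if spec.baseline_amp > 0:
        t = np.arange(n) / spec.fs
        signal = signal + spec.baseline_amp * np.sin(
            2.0 * np.pi * spec.baseline_freq * t
        )
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, n)
    if spec.dc_offset:
        signal = signal + spec.dc_offset
    return signal, onsets
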