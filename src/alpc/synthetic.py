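"""Deterministic synthetic inputs: polynomials, AR processes, ECG-like signals.

The ECG generator is a sum-of-Gaussians beat model: each beat places P, Q,
R, S and T bumps (amplitude in mV, center as a fraction of the beat period,
width in seconds) on a flat baseline, optionally plus sinusoidal baseline
wander and white measurement noise.  The millivolt waveform is scaled by
the preset's ADU-per-mV gain, rounded to integers and clipped to the
preset's bit resolution.  This is not a physiological simulator — no beat-
to-beat variability, no arrhythmia, no U wave — but it reproduces what the
codec cares about: alternating flat segments (TP intervals) and steep
slopes (QRS), at the sampling rate / resolution / gain combinations of the
three classic evaluation databases.

Three acquisition presets mirror those databases' setups:

=========  ======  ============  ==========
preset     fs(Hz)  resolution    ADU per mV
=========  ======  ============  ==========
mitdb      360     11-bit        200
edb        250     12-bit        200
ptbdb      1000    16-bit        2000
=========  ======  ============  ==========

Everything is seedable and byte-reproducible after quantization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .records import ECGRecord, Lead

__all__ = [
    "AcquisitionPreset",
    "BeatMorphology",
    "PRESETS",
    "generate_polynomial",
    "generate_ar",
    "generate_ecg",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class AcquisitionPreset:
    """Sampling setup of an ECG acquisition system."""

    name: str
    fs: float
    resolution_bits: int
    adu_per_mv: float
    signed: bool = False  # classic ambulatory ADCs store offset (unsigned) codes


PRESETS: dict[str, AcquisitionPreset] = {
    # 11-bit, 10 mV range -> ~200 ADU/mV; offset binary, midpoint ~1024
    "mitdb": AcquisitionPreset("mitdb", fs=360.0, resolution_bits=11, adu_per_mv=200.0),
    "edb": AcquisitionPreset("edb", fs=250.0, resolution_bits=12, adu_per_mv=200.0),
    "ptbdb": AcquisitionPreset(
        "ptbdb", fs=1000.0, resolution_bits=16, adu_per_mv=2000.0, signed=True
    ),
}


@dataclass(frozen=True)
class BeatMorphology:
    """Gaussian bump parameters per wave: (amplitude mV, center fraction, width s)."""

    waves: dict = field(
        default_factory=lambda: {
            "P": (0.15, 0.18, 0.025),
            "Q": (-0.12, 0.35, 0.008),
            "R": (1.20, 0.38, 0.010),
            "S": (-0.25, 0.41, 0.008),
            "T": (0.30, 0.60, 0.060),
        }
    )

    def __post_init__(self):
        for name, (_amp, _c, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name} width must be positive")


def generate_polynomial(degree: int, length: int, coeffs) -> np.ndarray:
    """Exact integer polynomial sequence x(n) = sum_i c_i n^i, n = 0..length-1."""
    if degree > 3:
        raise ValueError("degree must be at most 3")
    coeffs = tuple(int(c) for c in coeffs)
    if len(coeffs) != degree + 1:
        raise ValueError("need degree+1 coefficients")
    n = np.arange(length, dtype=object)
    x = sum(c * n**i for i, c in enumerate(coeffs))
    return np.asarray(x, dtype=np.int64)


def generate_ar(coeffs, noise_sd: float, n: int, seed: int) -> np.ndarray:
    """Stable AR(p) simulation with a 1000-sample burn-in discarded.

    ``coeffs`` are in the prediction convention, x(n) = sum_i a_i x(n-i) + eps.
    """
    a = np.atleast_1d(np.asarray(coeffs, dtype=np.float64))
    # AR polynomial 1 - a_1 z^-1 - ... must have roots inside the unit circle
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    if len(roots) and np.max(np.abs(roots)) >= 1.0:
        raise ValueError(f"unstable AR coefficients {tuple(a)}")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    burn = 1000
    eps = rng.normal(0.0, noise_sd, size=n + burn)
    x = _signal.lfilter([1.0], poly, eps)
    return x[burn:]


def _quantize(mv: np.ndarray, preset: AcquisitionPreset) -> np.ndarray:
    """mV -> integer ADU at the preset's gain, resolution and offset."""
    adu = mv * preset.adu_per_mv
    if preset.signed:
        lo, hi = -(1 << (preset.resolution_bits - 1)), (1 << (preset.resolution_bits - 1)) - 1
    else:
        lo, hi = 0, (1 << preset.resolution_bits) - 1
        adu = adu + (hi + 1) // 2  # offset-binary midpoint
    q = np.rint(adu).astype(np.int64)
    if q.min() < lo or q.max() > hi:
        warnings.warn(
            f"synthetic signal clipped to the {preset.resolution_bits}-bit range "
            f"of preset {preset.name!r}",
            stacklevel=3,
        )
        q = np.clip(q, lo, hi)
    return q


def generate_ecg(
    preset: AcquisitionPreset | str,
    duration_s: float,
    heart_rate_bpm: float = 60.0,
    morphology: BeatMorphology | None = None,
    baseline_wander_mv: float = 0.0,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    name: str | None = None,
) -> ECGRecord:
    """Synthesize a single-lead integer ECG record for one acquisition preset."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    morphology = morphology or BeatMorphology()
    beat_period = 60.0 / heart_rate_bpm
    if duration_s < 2 * beat_period:
        raise ValueError("duration must cover at least 2 beats")
    n = int(round(duration_s * preset.fs))
    t = np.arange(n) / preset.fs
    phase = t % beat_period  # time within the current beat
    mv = np.zeros(n)
    for amp, center, width in morphology.waves.values():
        mv += amp * np.exp(-0.5 * ((phase - center * beat_period) / width) ** 2)
    if baseline_wander_mv:
        # respiration-band wander, ~0.3 Hz
        mv += baseline_wander_mv * np.sin(2 * np.pi * 0.3 * t)
    if noise_sd_mv:
        rng = np.random.default_rng(seed)
        mv += rng.normal(0.0, noise_sd_mv, size=n)
    samples = _quantize(mv, preset)
    return ECGRecord(
        name=name or f"synthetic-{preset.name}",
        fs=preset.fs,
        resolution_bits=preset.resolution_bits,
        leads=[Lead(name="I", samples=samples, adu_per_mv=preset.adu_per_mv)],
        signed=preset.signed,
    )


def make_fixture_suite(seed: int = 0, duration_s: float = 30.0) -> dict[str, ECGRecord]:
    """The standard regression corpus: 3 presets x {clean, noisy, wandering}."""
    variants = {
        "clean": dict(baseline_wander_mv=0.0, noise_sd_mv=0.0),
        "noisy": dict(baseline_wander_mv=0.0, noise_sd_mv=0.02),
        "wandering": dict(baseline_wander_mv=0.2, noise_sd_mv=0.01),
    }
    suite: dict[str, ECGRecord] = {}
    for i, preset in enumerate(PRESETS.values()):
        for j, (vname, kwargs) in enumerate(variants.items()):
            key = f"{preset.name}-{vname}"
            suite[key] = generate_ecg(
                preset,
                duration_s=duration_s,
                heart_rate_bpm=72.0,
                seed=seed + 13 * i + j,
                name=key,
                **kwargs,
            )
    return suite
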