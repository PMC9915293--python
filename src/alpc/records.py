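"""In-memory representation of integer-quantized ECG records.

Samples stay in raw analog-to-digital units (ADU) end to end: converting to
millivolts would destroy the exact integers the lossless codec round-trips.
The gain (ADU per mV) is metadata used only for display and synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Lead", "ECGRecord"]


@dataclass
class Lead:
    """One ECG channel: integer samples plus its ADU-per-mV gain."""

    name: str
    samples: np.ndarray
    adu_per_mv: float = 200.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.ndim != 1:
            raise ValueError("lead samples must be one-dimensional")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError(f"lead {self.name!r} has non-integer samples")
        self.samples = arr.astype(np.int64)


@dataclass
class ECGRecord:
    """A named multi-lead record with a common sampling setup.

    ``signed`` declares the sample convention: two's-complement signed
    values in [-2^(b-1), 2^(b-1) - 1], or unsigned offset values in
    [0, 2^b - 1] (the MIT-BIH style for 11-bit ADCs).
    """

    name: str
    fs: float
    resolution_bits: int
    leads: list[Lead] = field(default_factory=list)
    signed: bool = True

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if not 8 <= self.resolution_bits <= 24:
            raise ValueError("resolution must be between 8 and 24 bits")
        lengths = {len(lead.samples) for lead in self.leads}
        if len(lengths) > 1:
            raise ValueError("all leads must have the same length")
        lo, hi = self.sample_range
        for lead in self.leads:
            if len(lead.samples) and (
                lead.samples.min() < lo or lead.samples.max() > hi
            ):
                raise ValueError(
                    f"lead {lead.name!r} exceeds the {self.resolution_bits}-bit "
                    f"{'signed' if self.signed else 'unsigned'} range [{lo}, {hi}]"
                )

    @property
    def sample_range(self) -> tuple[int, int]:
        b = self.resolution_bits
        if self.signed:
            return -(1 << (b - 1)), (1 << (b - 1)) - 1
        return 0, (1 << b) - 1

    @property
    def n_samples(self) -> int:
        return len(self.leads[0].samples) if self.leads else 0

    def lead_names(self) -> list[str]:
        return [lead.name for lead in self.leads]

    def get_lead(self, name: str) -> Lead:
        for lead in self.leads:
            if lead.name == name:
                return lead
        raise KeyError(f"record {self.name!r} has no lead {name!r}")
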