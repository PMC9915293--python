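"""Append-only bit writer and cursor-based bit reader, MSB-first packing.

The entropy-coded payload is a raw bit sequence; codes are not byte aligned.
The writer packs bits most-significant-bit first into a bytearray and
records the exact bit length so that byte padding is never decoded.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BitWriter", "BitReader", "TruncatedStreamError"]


class TruncatedStreamError(ValueError):
    """Raised when a read would pass the recorded end of the bitstream."""

    def __init__(self, bit_offset: int, message: str = "bitstream exhausted"):
        self.bit_offset = bit_offset
        super().__init__(f"{message} at bit offset {bit_offset}")


class BitWriter:
    """Accumulates bits MSB-first; finalization zero-pads to a byte boundary."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0  # bits not yet flushed, right-aligned
        self._nacc = 0

    def __len__(self) -> int:
        return 8 * len(self._buf) + self._nacc

    def write_bit(self, bit: int) -> None:
        self.write_uint(bit & 1, 1)

    def write_uint(self, value: int, nbits: int) -> None:
        """Append ``value`` in exactly ``nbits`` bits, MSB first."""
        if nbits == 0:
            return
        self._acc = (self._acc << nbits) | (value & ((1 << nbits) - 1))
        self._nacc += nbits
        while self._nacc >= 8:
            self._nacc -= 8
            self._buf.append((self._acc >> self._nacc) & 0xFF)
        self._acc &= (1 << self._nacc) - 1

    def write_unary(self, q: int) -> None:
        """Append ``q`` one-bits followed by a single zero separator.

        Long runs (pathological quotients) are written as whole 0xFF bytes,
        so the cost is O(q/8) C-level byte copies, not O(q) bit operations.
        """
        if q >= 16:
            # fill the partial byte with ones to reach alignment
            if self._nacc:
                take = 8 - self._nacc
                self.write_uint((1 << take) - 1, take)
                q -= take
            self._buf += b"\xff" * (q >> 3)
            q &= 7
        # remaining ones plus the zero separator
        self.write_uint((1 << (q + 1)) - 2, q + 1)

    def getvalue(self) -> tuple[bytes, int]:
        """Return (zero-padded bytes, exact bit length)."""
        nbits = len(self)
        buf = bytes(self._buf)
        if self._nacc:
            buf += bytes([(self._acc << (8 - self._nacc)) & 0xFF])
        return buf, nbits


class BitReader:
    """Reads MSB-first bits from bytes, bounded by an exact bit length."""

    def __init__(self, data: bytes, nbits: int | None = None) -> None:
        self._data = data
        self.nbits = 8 * len(data) if nbits is None else nbits
        if self.nbits > 8 * len(data):
            raise ValueError("declared bit length exceeds the buffer")
        self.pos = 0
        self._non_ff: np.ndarray | None = None  # built on first long unary run

    def remaining(self) -> int:
        return self.nbits - self.pos

    def read_bit(self) -> int:
        if self.pos >= self.nbits:
            raise TruncatedStreamError(self.pos)
        byte = self._data[self.pos >> 3]
        bit = (byte >> (7 - (self.pos & 7))) & 1
        self.pos += 1
        return bit

    def read_uint(self, nbits: int) -> int:
        if nbits == 0:
            return 0
        if self.pos + nbits > self.nbits:
            raise TruncatedStreamError(self.pos, "remainder field truncated")
        value = 0
        pos = self.pos
        data = self._data
        end = pos + nbits
        while pos < end:
            byte = data[pos >> 3]
            take = min(8 - (pos & 7), end - pos)
            shift = 8 - (pos & 7) - take
            value = (value << take) | ((byte >> shift) & ((1 << take) - 1))
            pos += take
        self.pos = end
        return value

    def read_unary(self) -> int:
        """Count one-bits up to the zero separator; consumes the separator.

        Runs of whole 0xFF bytes are skipped via a lazily built index of
        run-breaking bytes, so pathological quotients cost O(log n) after a
        one-time O(n) scan instead of O(q) bit reads.
        """
        q = 0
        pos, nbits, data = self.pos, self.nbits, self._data
        # consume bits up to the next byte boundary
        while pos & 7:
            if pos >= nbits:
                raise TruncatedStreamError(pos, "unary run unterminated")
            if not (data[pos >> 3] >> (7 - (pos & 7))) & 1:
                self.pos = pos + 1
                return q
            pos += 1
            q += 1
        # skip whole 0xFF bytes using the non-0xFF byte index
        if pos + 8 <= nbits and data[pos >> 3] == 0xFF:
            if self._non_ff is None:
                arr = np.frombuffer(data, dtype=np.uint8)
                self._non_ff = np.flatnonzero(arr != 0xFF)
            idx = int(np.searchsorted(self._non_ff, pos >> 3))
            stop = int(self._non_ff[idx]) if idx < len(self._non_ff) else len(data)
            run = min(stop - (pos >> 3), (nbits - pos) >> 3)
            q += 8 * run
            pos += 8 * run
        while True:
            if pos >= nbits:
                raise TruncatedStreamError(pos, "unary run unterminated")
            if (data[pos >> 3] >> (7 - (pos & 7))) & 1:
                q += 1
                pos += 1
            else:
                self.pos = pos + 1
                return q
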