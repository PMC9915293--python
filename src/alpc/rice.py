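"""Modified Golomb-Rice coding of signed prediction residuals.

A signed residual e is first folded to a non-negative integer M by the
even/odd zig-zag map

    M = 2e        if e >= 0
    M = 2|e| - 1  if e < 0

and M is then split by a power-of-two divisor 2^k into a unary quotient
q = floor(M / 2^k) (q one-bits plus a zero separator) and a k-bit binary
remainder r = M mod 2^k, MSB first.  The code word is [q ones, 0, r] and is
self-delimiting given k.

The divisor exponent k adapts causally: it is the base-2 logarithm of the
mean absolute residual of the three most recently coded samples, computed
in pure integer arithmetic so encoder and decoder reproduce the identical k
sequence bit for bit:

    mae = (|e(n-1)| + |e(n-2)| + |e(n-3)|) // 3
    k   = 0                  if mae <= 1
        = floor(log2(mae))   otherwise, clamped to k_max

The window starts at (0, 0, 0), so the first coded sample uses k = 0.
There is no escape code for pathological quotients; the worst-case
expansion for a residual of magnitude E at k = 0 is 2E + 1 bits.
"""

from __future__ import annotations

from .bitstream import BitReader, BitWriter

__all__ = [
    "map_error",
    "unmap_error",
    "RiceState",
    "update_k",
    "encode_value",
    "decode_value",
    "code_length",
]


def map_error(e: int) -> int:
    """Fold a signed residual to a non-negative code value (zig-zag)."""
    e = int(e)
    return 2 * e if e >= 0 else -2 * e - 1


def unmap_error(m: int) -> int:
    """Inverse fold: even M -> M/2, odd M -> -(M+1)/2."""
    m = int(m)
    if m < 0:
        raise ValueError(f"code value must be non-negative, got {m}")
    return m // 2 if m % 2 == 0 else -(m + 1) // 2


class RiceState:
    """Causal k adaptation from the three most recent |residual| values."""

    __slots__ = ("window", "k_max", "k")

    def __init__(self, k_max: int, window: tuple[int, int, int] = (0, 0, 0)):
        if k_max < 0:
            raise ValueError("k_max must be non-negative")
        self.k_max = int(k_max)
        self.window = tuple(int(w) for w in window)
        self.k = update_k(self.window, self.k_max)

    def push(self, abs_error: int) -> None:
        """Record the latest |e| and refresh k for the next sample."""
        self.window = (int(abs_error), self.window[0], self.window[1])
        self.k = update_k(self.window, self.k_max)


def update_k(window, k_max: int) -> int:
    """k from the integer-floored mean absolute residual of the window."""
    mae = (abs(int(window[0])) + abs(int(window[1])) + abs(int(window[2]))) // 3
    if mae <= 1:
        return 0
    return min(mae.bit_length() - 1, k_max)  # floor(log2(mae))


def code_length(m: int, k: int) -> int:
    """Exact bit length of the code word: floor(M/2^k) + 1 + k."""
    return (int(m) >> k) + 1 + k


def encode_value(m: int, k: int, out: BitWriter) -> int:
    """Append the Rice code of M with parameter k; return bits appended."""
    m = int(m)
    if m < 0:
        raise ValueError("Rice coding requires a non-negative value")
    if k < 0:
        raise ValueError("k must be non-negative")
    q = m >> k
    out.write_unary(q)
    if k:
        out.write_uint(m & ((1 << k) - 1), k)
    return q + 1 + k


def decode_value(stream: BitReader, k: int) -> int:
    """Read one Rice code word with parameter k and return M."""
    q = stream.read_unary()
    r = stream.read_uint(k) if k else 0
    return (q << k) | r
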