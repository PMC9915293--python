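"""Fixed binomial-coefficient linear predictors and per-sample order selection.

The codec predicts each sample x(n) from up to four past samples with the
order-p predictor whose weights come from Pascal's triangle:

    order 1:  x̂(n) = x(n-1)
    order 2:  x̂(n) = 2 x(n-1) - x(n-2)
    order 3:  x̂(n) = 3 x(n-1) - 3 x(n-2) + x(n-3)
    order 4:  x̂(n) = 4 x(n-1) - 6 x(n-2) + 4 x(n-3) - x(n-4)

The order-p residual e_p(n) = x(n) - x̂_p(n) equals the p-th backward
difference of the signal, so the order-p predictor is exact on polynomial
trends of degree p-1: low orders win in flat regions, high orders on steep
slopes.  Adaptive selection keeps, per sample, the signed residual with the
smallest magnitude (ties broken toward the lowest order).

All arithmetic is exact integer arithmetic; intermediate predictions may
exceed the input bit range, which is fine because residuals are carried in
64-bit integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BINOMIAL_COEFFS",
    "ErrorVector",
    "OrderSelection",
    "predict",
    "compute_errors",
    "select_order",
    "reconstruct_sample",
    "error_sequences",
    "causal_orders",
]

#: Predictor weights a_p(1..p) for the past samples [x(n-1), ..., x(n-p)].
BINOMIAL_COEFFS: dict[int, tuple[int, ...]] = {
    1: (1,),
    2: (2, -1),
    3: (3, -3, 1),
    4: (4, -6, 4, -1),
}

ORDERS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ErrorVector:
    """Residuals and predictions of all four predictors at one sample."""

    errors: tuple[int, int, int, int]
    predictions: tuple[int, int, int, int]


@dataclass(frozen=True)
class OrderSelection:
    """The winning (order, signed residual) pair for one sample."""

    order: int
    error: int


def predict(window, p: int) -> int:
    """Predict the current sample from the 4 most recent past samples.

    Parameters
    ----------
    window
        Sequence ``[x(n-1), x(n-2), x(n-3), x(n-4)]`` of integers.
    p
        Predictor order, 1..4.
    """
    if p not in BINOMIAL_COEFFS:
        raise ValueError(f"prediction order must be in 1..4, got {p}")
    coeffs = BINOMIAL_COEFFS[p]
    return int(sum(int(c) * int(x) for c, x in zip(coeffs, window)))


def compute_errors(window, x: int) -> ErrorVector:
    """Residuals e_p = x - x̂_p for all four orders at one sample."""
    preds = tuple(predict(window, p) for p in ORDERS)
    errs = tuple(int(x) - xp for xp in preds)
    return ErrorVector(errors=errs, predictions=preds)


def select_order(ev: ErrorVector) -> OrderSelection:
    """Pick the signed residual with the smallest magnitude.

    Ties go to the lowest order: lower orders are cheaper and more stable
    in flat regions, where they dominate anyway.
    """
    best_p = 1
    best_e = ev.errors[0]
    for p in (2, 3, 4):
        e = ev.errors[p - 1]
        if abs(e) < abs(best_e):
            best_p, best_e = p, e
    return OrderSelection(order=best_p, error=best_e)


def reconstruct_sample(window, p: int, e: int) -> int:
    """Exact inverse of prediction: x = x̂_p + e, from reconstructed history."""
    return predict(window, p) + int(e)


def error_sequences(x: np.ndarray) -> np.ndarray:
    """Residuals of all four predictors over a whole signal, vectorized.

    Returns a (4, N) int64 array ``E`` with ``E[p-1, n] = e_p(n)``.  Entries
    at n < 4 (0-based) are invalid (set to 0): prediction starts once four
    past samples exist.  ``e_p`` equals the p-th backward difference of x.
    """
    x = np.asarray(x, dtype=np.int64)
    n = x.shape[0]
    out = np.zeros((4, n), dtype=np.int64)
    d = x
    for p in ORDERS:
        d = np.diff(d)  # p-th backward difference, length n-p
        out[p - 1, 4:] = d[4 - p:]
    return out


def causal_orders(errors: np.ndarray) -> np.ndarray:
    """Decoder-replicable order choice: argmin |e_p| at the previous sample.

    ``errors`` is the (4, N) array from :func:`error_sequences`.  The order
    used at sample n (0-based n >= 4) is the order whose residual magnitude
    was smallest at sample n-1, ties to the lowest order.  The first coded
    sample (n = 4) has no fully-predicted predecessor; it uses order 2, the
    order the data favours on ECG.

    Returns an int64 array of length N; entries below n = 4 are 0.
    """
    n = errors.shape[1]
    orders = np.zeros(n, dtype=np.int64)
    if n <= 4:
        return orders
    orders[4] = 2
    if n > 5:
        prev = np.abs(errors[:, 4:n - 1])  # |e_p| at samples 4..n-2
        orders[5:] = np.argmin(prev, axis=0) + 1  # argmin ties -> lowest p
    return orders
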