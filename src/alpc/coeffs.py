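"""Linear-prediction coefficient determination via the autocorrelation method.

The codec's fixed binomial predictors are a design choice; this toolkit
asks what coefficients the data itself would pick.  For a signal x(n) the
order-p coefficients a_1..a_p minimizing the squared prediction error of

    x̂(n) = sum_i a_i x(n-i)

solve the Yule-Walker system T a = r, where T is the symmetric Toeplitz
matrix of autocorrelations R(0)..R(p-1) and r = [R(1)..R(p)].  Outputs use
the prediction sign convention above, so a_1 is close to +1 for the nearly
random-walk ECG baseline.  The system is solved with the Levinson-Durbin
recursion in O(p^2).

The autocorrelation estimator is the biased one, R(k) = (1/N) * sum x(n)
x(n-k): it guarantees a positive-semidefinite Toeplitz system, so the
recursion cannot encounter a negative error variance.  Mean removal is off
by default — raw ADU ECG signals carry a DC offset, and the fitted a_1 near
+0.99 at order 1 is a property of the raw signal.

Rounding to integers uses round-half-to-even, the convention that makes the
rounded coefficients reproduce the published per-database tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ECGRecord

__all__ = [
    "AutocorrelationVector",
    "LPCoefficientSet",
    "autocorrelation",
    "levinson_durbin",
    "estimate_record_coefficients",
    "average_coefficients",
    "round_coefficients",
    "PUBLISHED_AVG_COEFFS",
    "PUBLISHED_ROUNDED_COEFFS",
]


class DegenerateSignalError(ValueError):
    """Zero-variance or non-positive-definite autocorrelation input."""


@dataclass(frozen=True)
class AutocorrelationVector:
    """Sample autocorrelation R(0)..R(maxlag) and the N it was computed on."""

    r: np.ndarray
    n: int

    def __post_init__(self):
        object.__setattr__(self, "r", np.asarray(self.r, dtype=np.float64))


@dataclass(frozen=True)
class LPCoefficientSet:
    """Order-p prediction coefficients a_1..a_p (prediction convention)."""

    order: int
    coefficients: tuple

    def __post_init__(self):
        if len(self.coefficients) != self.order:
            raise ValueError("coefficient count must equal the order")

    @property
    def is_integer(self) -> bool:
        return all(float(c).is_integer() for c in self.coefficients)


def autocorrelation(x, maxlag: int, demean: bool = False) -> AutocorrelationVector:
    """Biased sample autocorrelation R(k) = (1/N) sum_n x(n) x(n-k), k <= maxlag."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if maxlag < 1:
        raise ValueError("maxlag must be at least 1")
    if n <= maxlag:
        raise ValueError(f"need more than {maxlag} samples, got {n}")
    if demean:
        x = x - x.mean()
    r = np.array([np.dot(x[k:], x[: n - k]) for k in range(maxlag + 1)]) / n
    return AutocorrelationVector(r=r, n=n)


def levinson_durbin(acv: AutocorrelationVector, p: int) -> LPCoefficientSet:
    """Solve the order-p Yule-Walker system by the Levinson-Durbin recursion.

    Returns coefficients in the prediction convention (x̂ = sum a_i x(n-i)).
    Raises :class:`DegenerateSignalError` when the autocorrelation sequence
    is degenerate (zero signal power or zero innovation variance reached
    before order p, as for an exactly constant demeaned signal).
    """
    r = acv.r
    if len(r) < p + 1:
        raise ValueError(f"need R(0)..R({p}), got {len(r)} values")
    if r[0] <= 0:
        raise DegenerateSignalError("R(0) must be positive (zero-power signal)")
    a = np.zeros(p + 1)  # a[0] unused; prediction convention
    err = float(r[0])
    for m in range(1, p + 1):
        if err <= 0:
            raise DegenerateSignalError(
                f"prediction-error variance vanished at order {m - 1}"
            )
        kappa = (r[m] - np.dot(a[1:m], r[m - 1:0:-1])) / err
        a_new = a.copy()
        a_new[m] = kappa
        a_new[1:m] = a[1:m] - kappa * a[m - 1:0:-1]
        a = a_new
        err *= 1.0 - kappa * kappa
    return LPCoefficientSet(order=p, coefficients=tuple(a[1:]))


def estimate_record_coefficients(
    record_or_samples, p: int, demean: bool = False, lead: str | None = None
) -> LPCoefficientSet:
    """Fit order-p LP coefficients to a full record (or raw sample array)."""
    if isinstance(record_or_samples, ECGRecord):
        rec = record_or_samples
        samples = (rec.get_lead(lead) if lead else rec.leads[0]).samples
    else:
        samples = record_or_samples
    acv = autocorrelation(samples, maxlag=p, demean=demean)
    return levinson_durbin(acv, p)


def average_coefficients(sets) -> LPCoefficientSet:
    """Element-wise unweighted mean of same-order coefficient sets."""
    sets = list(sets)
    if not sets:
        raise ValueError("no coefficient sets to average")
    orders = {s.order for s in sets}
    if len(orders) != 1:
        raise ValueError(f"mixed orders cannot be averaged: {sorted(orders)}")
    mean = np.mean([s.coefficients for s in sets], axis=0)
    return LPCoefficientSet(order=sets[0].order, coefficients=tuple(mean))


def round_coefficients(cs: LPCoefficientSet) -> LPCoefficientSet:
    """Round each coefficient to the nearest integer (half-to-even)."""
    rounded = tuple(int(np.rint(c)) for c in cs.coefficients)
    return LPCoefficientSet(order=cs.order, coefficients=rounded)


# Published average determined LP coefficients for the three PhysioNet
# evaluation databases (orders 1..4), and their integer-rounded versions.
# Used as reference data for rounding checks and reporting.
PUBLISHED_AVG_COEFFS: dict[str, dict[int, tuple[float, ...]]] = {
    "MITDB": {
        1: (0.99,),
        2: (1.85, -0.86),
        3: (2.18, -1.57, -0.38),
        4: (2.10, -1.25, -0.06, 0.20),
    },
    "PTBDB": {
        1: (0.99,),
        2: (1.59, -0.60),
        3: (1.54, -0.51, -0.04),
        4: (1.53, -0.66, 0.40, -0.28),
    },
    "EDB": {
        1: (0.99,),
        2: (1.74, -0.75),
        3: (2.13, -1.63, 0.50),
        4: (2.14, -1.63, 0.46, 0.02),
    },
}

PUBLISHED_ROUNDED_COEFFS: dict[str, dict[int, tuple[int, ...]]] = {
    "MITDB": {
        1: (1,),
        2: (2, -1),
        3: (2, -2, 0),
        4: (2, -1, 0, 0),
    },
    "PTBDB": {
        1: (1,),
        2: (2, -1),
        3: (2, -1, 0),
        4: (2, -1, 0, 0),
    },
    "EDB": {
        1: (1,),
        2: (2, -1),
        3: (2, -2, 0),
        4: (2, -2, 0, 0),
    },
}
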