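"""Autocorrelation / Yule-Walker / Levinson-Durbin and coefficient rounding."""

import numpy as np
import pytest
from scipy.linalg import solve_toeplitz

from alpc.coeffs import (
    PUBLISHED_AVG_COEFFS,
    PUBLISHED_ROUNDED_COEFFS,
    AutocorrelationVector,
    DegenerateSignalError,
    LPCoefficientSet,
    autocorrelation,
    average_coefficients,
    estimate_record_coefficients,
    levinson_durbin,
    round_coefficients,
)
from alpc.predictor import error_sequences
from alpc.synthetic import generate_ar, generate_ecg


def toeplitz_oracle(r, p):
    """Direct dense Yule-Walker solve, independent of the recursion."""
    return solve_toeplitz((r[:p], r[:p]), r[1 : p + 1])


def test_autocorrelation_of_a_constant_has_closed_form():
    n, c = 50, 7
    acv = autocorrelation(np.full(n, c), maxlag=4)
    for k in range(5):
        assert acv.r[k] == pytest.approx(c * c * (n - k) / n)


def test_autocorrelation_of_alternating_signal_is_negative_at_lag_1():
    x = np.resize([1, -1], 100)
    acv = autocorrelation(x, maxlag=1)
    assert acv.r[1] < 0


def test_autocorrelation_recovers_ar1_decay():
    x = generate_ar([0.5], noise_sd=1.0, n=100_000, seed=7)
    acv = autocorrelation(x, maxlag=1, demean=True)
    assert acv.r[1] / acv.r[0] == pytest.approx(0.5, abs=0.02)


def test_autocorrelation_input_validation():
    with pytest.raises(ValueError):
        autocorrelation(np.arange(3), maxlag=5)
    with pytest.raises(ValueError):
        autocorrelation(np.arange(10), maxlag=0)


@pytest.mark.parametrize(
    "r, p, expected",
    [
        ((1.0, 0.5), 1, (0.5,)),
        ((1.0, 0.5, 0.25), 2, (0.5, 0.0)),  # AR(1) autocorrelation
        ((2.0, 1.0, 0.8), 2, (0.4, 0.2)),  # verified by direct 2x2 solve
    ],
)
def test_levinson_durbin_worked_examples(r, p, expected):
    r = np.asarray(r)
    assert toeplitz_oracle(r, p) == pytest.approx(expected)  # oracle on record
    got = levinson_durbin(AutocorrelationVector(r=r, n=100), p)
    assert got.coefficients == pytest.approx(expected)


def test_levinson_durbin_matches_toeplitz_solve_on_random_psd_systems(rng):
    for _ in range(250):
        p = int(rng.integers(1, 9))
        # biased autocorrelation of a random signal is guaranteed PSD
        x = rng.normal(size=200)
        acv = autocorrelation(x, maxlag=p)
        mine = levinson_durbin(acv, p).coefficients
        direct = toeplitz_oracle(acv.r, p)
        assert np.max(np.abs(np.asarray(mine) - direct)) < 1e-9


def test_levinson_durbin_degenerate_inputs():
    with pytest.raises(DegenerateSignalError):
        levinson_durbin(AutocorrelationVector(r=np.array([0.0, 0.0]), n=10), 1)
    with pytest.raises(ValueError):
        levinson_durbin(AutocorrelationVector(r=np.array([1.0, 0.5]), n=10), 3)


def test_ar1_parameter_recovery():
    x = generate_ar([0.9], noise_sd=1.0, n=100_000, seed=11)
    cs = estimate_record_coefficients(x, p=1, demean=True)
    assert cs.coefficients[0] == pytest.approx(0.9, abs=0.02)


def test_ar2_parameter_recovery():
    true = (1.2, -0.5)
    x = generate_ar(true, noise_sd=1.0, n=100_000, seed=3)
    cs = estimate_record_coefficients(x, p=2, demean=True)
    assert np.asarray(cs.coefficients) == pytest.approx(true, abs=0.02)


def test_constant_record_without_demeaning():
    n = 1000
    cs = estimate_record_coefficients(np.full(n, 42), p=1)
    assert cs.coefficients[0] == pytest.approx((n - 1) / n)


def test_constant_record_with_demeaning_is_degenerate():
    with pytest.raises(DegenerateSignalError):
        estimate_record_coefficients(np.full(1000, 42), p=1, demean=True)


def test_average_coefficients():
    sets = [
        LPCoefficientSet(2, (1.0, -1.0)),
        LPCoefficientSet(2, (3.0, 1.0)),
    ]
    avg = average_coefficients(sets)
    assert avg.coefficients == pytest.approx((2.0, 0.0))
    assert average_coefficients(sets[:1]).coefficients == sets[0].coefficients
    with pytest.raises(ValueError, match="mixed"):
        average_coefficients([sets[0], LPCoefficientSet(1, (1.0,))])


@pytest.mark.parametrize("database", sorted(PUBLISHED_AVG_COEFFS))
@pytest.mark.parametrize("order", [1, 2, 3, 4])
def test_rounding_reproduces_the_published_integer_tables(database, order):
    """All 12 published rounded cells follow from the real-valued averages."""
    avg = LPCoefficientSet(order, PUBLISHED_AVG_COEFFS[database][order])
    rounded = round_coefficients(avg)
    assert rounded.coefficients == PUBLISHED_ROUNDED_COEFFS[database][order]
    assert rounded.is_integer


def _fitted_mean_abs_error(x, p):
    cs = estimate_record_coefficients(x, p=p)
    a = np.asarray(cs.coefficients)
    preds = sum(a[i] * x[p - 1 - i : len(x) - 1 - i] for i in range(p))
    return float(np.mean(np.abs(x[p:] - preds[: len(x) - p])))


def test_order_2_is_adequate_for_ecg():
    """Fitted order-2 prediction error is within 5% of fitted order-4."""
    record = generate_ecg("mitdb", 30.0, 72.0, noise_sd_mv=0.02, seed=5)
    x = record.leads[0].samples.astype(np.float64)
    mae2 = _fitted_mean_abs_error(x, 2)
    mae4 = _fitted_mean_abs_error(x, 4)
    assert mae2 <= 1.05 * mae4
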