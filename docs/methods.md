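# Methods

## Codec model

The codec treats a lead as a stream of integers in analog-to-digital units
(ADU). Nothing on the codec path ever converts to physical units; the gain
(ADU/mV) is carried as metadata for display and synthesis only. Losslessness
is the contract: `decompress(compress(x)) == x` sample for sample, so the
percent root-mean-square difference (PRD) of the reconstruction is
identically zero and is asserted, not estimated.

Prediction uses the four binomial-coefficient predictors of orders 1–4.
Their residuals are backward differences: the order-p residual annihilates
polynomial trends of degree p−1 exactly, which is why order switching works
— ECG alternates between near-constant baselines (order 1 suffices) and
high-curvature QRS complexes (orders 3–4 pay off). All predictor arithmetic
is exact integer arithmetic. Intermediate predictions may leave the input
bit range (an order-4 extrapolation of an 11-bit signal can exceed 13 bits);
residuals are carried as 64-bit integers and no saturation is applied.

### The order-selection gap and the two modes

Choosing the order that minimizes the *current* sample's residual is not,
by itself, decodable: the decoder does not yet know the current sample.
Two resolutions are implemented, recorded in the container header:

* **causal** (default): the order for sample n is the order whose residual
  magnitude was smallest at sample n−1, evaluated on already-reconstructed
  history, so encoder and decoder derive identical order sequences with no
  side information. The first coded sample (index 5, 1-based) has no fully
  predicted predecessor and uses order 2, the order ECG data favours.
  This overhead-free mode is the default because 2 bits/sample of side
  information would consume most of the coding gain at typical ECG bit
  rates.
* **side_info**: the exact per-sample argmin is used and transmitted as a
  2-bit field preceding each code word. Guaranteed minimum residual,
  +2(N−4) bits of overhead.

Ties in any argmin go to the lowest order: lower orders are cheaper to
reason about and dominate the flat regions where ties actually occur.

### Rice coding and the k recursion

Signed residuals are folded by the even/odd zig-zag map (M = 2e for e ≥ 0,
2|e|−1 for e < 0), then split by 2^k into a unary quotient (q one-bits and
a zero separator) and a k-bit MSB-first remainder. The adaptation target is
the mean absolute residual of the three most recently coded samples, and it
is computed entirely in integer arithmetic so both sides agree bit for bit:

    mae = (|e(n−1)| + |e(n−2)| + |e(n−3)|) // 3
    k   = 0 if mae ≤ 1 else floor(log2(mae)),  clamped to k_max = b + 2

Floor-then-floor (integer division by 3, then floor log) is a deliberate
convention: a real-valued mean or a rounded logarithm would force floating
point into the decoder's control path. mae ≤ 1 maps to k = 0 so flat
regions emit 1-bit codes. k_max = b + 2 because residuals of a b-bit
signal fit in b + 2 bits and larger divisors never shorten their codes.
The window starts at (0, 0, 0), giving k = 0 at the first coded sample.
There is no escape code for pathological quotients — the code is exactly
[q ones, 0, remainder] — so a worst-case residual at k = 0 costs 2|e|+1
bits; the bitstream layer writes and reads long unary runs in whole-byte
chunks so even adversarial inputs stay fast.

### Container and accounting

The container stores magic/version/mode/sign-convention flags, resolution,
lead count, sampling frequency (milli-Hz), sample count, and per lead: the
name, the four raw initial samples, the exact payload bit length, and the
zero-padded payload bytes. Byte padding is never decoded because the bit
length is explicit. Identical record + configuration produces a
byte-identical container.

CR is reported as B0/BC with B0 = N·b and BC = 4·b + payload bits per lead
(order fields included in side_info mode), excluding the fixed container
header; this matches how per-signal coding cost is conventionally quoted.
`file_compression_ratio` additionally charges the full header for users who
care about on-disk size. Dataset means weight every evaluated lead equally;
`first_lead_only` restricts evaluation to each record's first lead.
Multi-lead records are compressed lead-independently — no inter-lead
decorrelation is attempted.

## Coefficient determination

The analysis toolkit fits order-p coefficients by the autocorrelation
method: biased estimator R(k) = (1/N) Σ x(n)x(n−k), which guarantees a
positive-semidefinite Toeplitz system so the Levinson–Durbin recursion
cannot hit a negative innovation variance on real input; a zero variance
(constant demeaned signal) raises a degeneracy error instead of emitting
garbage. Outputs use the prediction sign convention x̂ = Σ aᵢx(n−i), the
convention in which fitted ECG gives a₁ ≈ +1 at order 1. Mean removal is
off by default — raw ADU records carry a DC offset and the fit is intended
to describe the raw signal the codec sees — and is exposed as a flag.
Cross-record averages are unweighted. Rounding to integers is
round-half-to-even; it is the convention under which the published
real-valued per-database averages reproduce every cell of the published
integer table (a half-away-from-zero rule would flip one 0.50 cell).
These real-coefficient fits are analysis only; the codec path uses the
integer binomial predictors exclusively.

## Synthetic data

The generator emulates the acquisition setups of the three classic
evaluation databases — MITDB-like (360 Hz, 11-bit, ~200 ADU/mV, offset
binary), EDB-like (250 Hz, 12-bit, 200 ADU/mV), PTBDB-like (1 kHz, 16-bit,
2000 ADU/mV, signed) — with a sum-of-Gaussians beat model (P, Q, R, S, T
bumps; amplitudes in mV, centers as beat-phase fractions, widths in
seconds), optional 0.3 Hz sinusoidal baseline wander and white noise,
quantized round-to-nearest and clipped with a warning (silent wraparound
would corrupt lossless tests). Defaults: 72 bpm, R amplitude 1.2 mV, and
the regression corpus is 3 presets × {clean, noisy (0.02 mV), wandering
(0.2 mV wander + 0.01 mV noise)} × 30 s, seeded and byte-reproducible.

What this emulates is the codec-relevant structure: flat/steep alternation
at realistic sampling rates, resolutions and gains — enough to reproduce
the qualitative finding that finer quantization and faster sampling raise
the selected residuals. It is not a physiological simulator: no beat-to-
beat variability, arrhythmia, U waves, electrode artifacts, or the noise
floors of real Holter recordings. Passing tests therefore demonstrate
exact losslessness and internal consistency on realistic-shaped signals,
not that real-database compression ratios are matched; synthetic
per-preset CRs land in the same 2–4 range but do not reproduce the
per-database ordering of real recordings (the clean 16-bit synthetic
signal is smoother, relative to its quantization step, than real PTB
recordings).

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale as the package's
standard configuration: 30-s synthetic records (≈7.5–30 k samples), 1,000
codec round trips across both modes, the full 16-bit × k ∈ [0, 12] Rice
grid, 1,000 random positive-semidefinite Yule–Walker systems against a
dense Toeplitz solve (agreement demanded at 10⁻⁹; observed ~10⁻¹⁶), and
AR(1) recovery at N = 10⁵ (|â₁ − 0.9| < 0.02). All randomness flows from
explicit integer seeds.

## Known limitations

* Published per-database compression ratios and fitted-coefficient
  averages can only be recomputed against local copies of the PhysioNet
  databases (`data/{mitdb,edb,ptbdb}`); the repository does not
  redistribute them, and the dedicated test says so when they are absent.
  How the original figures accounted header bits and lead selection is not
  fully specified, so both codec modes and both accounting variants are
  reported when that comparison runs.
* WFDB support covers header + signal formats 16 and 212 (digital reads
  only) — sufficient for the three target databases, not the full format
  zoo.
* No error resilience beyond truncation detection: a flipped payload bit
  desynchronizes the remainder of that lead.
* Streaming/chunked encoding is out of scope; a record is processed in
  memory.
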