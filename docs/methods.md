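# Methods

## Model and units

The ADEX neuron is integrated with forward Euler at a fixed step
dt = 1/128 ms, the step the digital design uses.  Units are pF / nS / mV /
pA / ms throughout, which make both state equations dimensionally
consistent with no conversion factors.  The eight firing-pattern presets
are stored verbatim; the default protocol for every model comparison is
dt = 1/128 ms, duration 1000 ms, initial state (EL, 0), stimulus constant
from t = 0.

Spike handling: a spike is the first recorded sample with V > 0.  The
trace keeps the pre-reset value at that sample (the apex stays visible in
plots); the reset V ← Vr, W ← W + b is applied before the next step.

## Saturation of the membrane current

Both the reference integrator and the lookup table saturate ADX(V) at the
same level, `adx_ceiling = C · 80 mV / dt` (~2·10^6 pA for C = 200 pF).
This is the smallest level at which a single Euler step at the saturated
rate spans the entire remaining rise to the apex, so saturation changes
*how far* the final step overshoots, never *when* the spike is detected.
Two degenerate alternatives motivated this choice:

* an unsaturated exponential makes the apex sample essentially unbounded
  (exp(20) ≈ 5·10^8 drives single-step excursions of hundreds of mV), and
* a low cap (e.g. the ADX value five slope factors above threshold,
  ~2668 pA for tonic) stretches every upstroke by milliseconds — with it
  the tonic LUT model fires 80 spikes per second against the reference's
  103 *regardless of table resolution*.

Sharing one timing-neutral cap makes the suprathreshold dynamics of the
two models identical by construction, so trace comparisons measure only
the quantization of the subthreshold/spike-initiation region.  The
exponent argument is additionally clamped at 20 so the exponential itself
never overflows.

## Bandwidth estimate and table size

The design-time tabulation covers the voltage-register range
[-60, +10] mV.  The tabulated objective is not periodic, so a raw DFT is
dominated by the wraparound discontinuity; the estimator therefore
subtracts the line through the endpoints (bridge detrend, which leaves a
pure sinusoid and a constant untouched), removes the mean, normalizes the
amplitude, and treats the span as one normalized second so bin k reads as
k cycles per span.  The bandwidth is the smallest k whose cumulative
spectral power (DC excluded) reaches 99%.  For the tonic objective this
gives 8–9 cycles per span; the table size is `max(ceil(2B), 20)`, i.e. the
20-address SRAM of the digital design for every preset.

## Table span and addressing

A deployed table spends its 20 addresses where the trajectory goes: the
span runs from `min(EL, Vr)` (deeper excursions clamp to the end address,
whose value is locally accurate) up to the voltage where the exponential
term alone reaches the saturation ceiling — beyond that every address
would store the same capped word.  Lookup is a nearest-address read
(`round((V - v_min)/Δv)`, ends clamped), exactly an SRAM access; no
interpolation exists anywhere in the pipeline, because the hardware reads
one address per step.

## Fixed-point datapath

The emulator performs the entire update in integer arithmetic:

* every constant scaling — dt/C, dt/τw, the adaptation gain a, and the
  LUT addressing factor 1/Δv — is pre-decomposed into at most three signed
  powers of two (exponents down to 2^-25 for sub-unity constants) and
  applied as arithmetic shifts combined with adds/subs;
* `a` uses its published digitized decomposition; dt/C and dt/τw are
  decomposed from the digitized C and τw, which is the only reading
  consistent with a zero-divider datapath when C and τw are not powers of
  two (the realized coefficients differ from the exact ratios by the
  documented CSD truncation error);
* arithmetic right shifts floor-truncate, as hardware does;
* results saturate to the working word; saturations are counted and the
  run continues (hardware behaviour), and the default run is
  saturation-free.

The published width analysis (6 integer + 20 fraction + 1 guard + 1 sign
= 28 bits) covers the voltage register, and `bit_width_analysis`
reproduces it.  The shared working word must also carry currents — the
stimulus, the adaptation current and the saturated table entries
(~2^21 pA) — so the default emulation format is 46 bits with the same 20
fraction bits.  An operation trace tallies every shift, add, sub, memory
read and (would-be) multiply/divide/exponential; the multiplierless
contract `mul = div = exp = 0` is asserted over full one-second runs of
all eight patterns.

The digitized parameter table is stored verbatim, including entries that
deviate from the continuous presets beyond rounding (tonic τw realized as
28 versus 30, reset at -56 versus -58, and three entries beyond 10%:
the RS slope factor and gain, and the cAD leak).  One printed entry — a
negative capacitance in the "can" row — is sign-corrected by default, with
the printed value available behind an explicit flag.
`table4_divergence_report()` enumerates every difference rather than
hiding them, and the greedy CSD utility independently reproduces all
exactly-representable entries by value (its term lists are the canonical
signed-digit forms, e.g. 200 = 256 - 64 + 8, which may differ from the
printed but equal-valued sums).

## Operator census

`resource_census` tallies explicit canonical operator schedules, one per
model, reflecting the budgeting conventions of the hardware comparison:
the original datapath is the direct realization in which no constant
products are folded (gL·V, gL·EL, a·V, a·EL), every constant ratio —
including the two dt = 1/128 step scalings — occupies a divider, and the
spike comparator and reset adder are part of the datapath (1 exponential,
6 multipliers, 5 dividers, 5 adders, 6 subtractors).  The proposed
schedule counts the steady-state arithmetic of the two update equations
only — CSD scalings are shifts, and the comparator/reset live in the
control unit — giving 3 adders and 3 subtractors and nothing nonlinear.
The two rows use deliberately different conventions; a single convention
cannot produce both inventories, and the schedules are data, so either
convention is auditable.

## Trace metrics

MAE is the mean absolute voltage difference on the shared grid; the
correlation is the Pearson coefficient of the voltage sequences in
percent; the trough error is the absolute difference of the two traces'
minima.  Under the standard protocol the initial state (EL, 0) is usually
the global voltage minimum of both traces, so the trough error is ~0 for
most presets.

A known limitation, measured not hidden: a 20-address nearest-read table
quantizes the membrane current in steps of a few tens of pA, giving
per-period timing errors of ~0.1–0.5%.  Over a 1000 ms window these
accumulate into spike-phase drift of several periods, which dominates the
MAE (tonic ≈ 2.7 mV) and collapses the sample-wise correlation (tonic
≈ 35%) even though the firing pattern, spike count (±1) and phase-plane
loop are preserved.  Correlations above 95% appear only for windows
≲ 50 ms, before drift accumulates.  For the same reason the MAE across
the doubling sweep of table sizes (20 → 640) decreases only in trend, not
monotonically: the sign of the quantization-error cancellation flips with
the grid.  True convergence is verified differently — a 20000-point table
tracks the reference to below 1% of the 20-point error.

## Nullclines and Jacobian

The V-nullcline is W = ADX(V) + I (the LUT read for the proposed model,
hence piecewise constant); the W-nullcline is W = a(V - EL).  The
analytic Jacobian of the original model has
A1 = (gL/C)(exp((V-VT)/ΔT) - 1), B1 = -1/C, C1 = a/τw, D1 = -1/τw; the
proposed model's piecewise-constant table has A1 = 0.  A `paper_table`
mode reproduces the published entry B1 = -1 for the proposed row, which
is dimensionally inconsistent with the state equation (the analytic value
is -1/C); both behaviours are exposed and neither intent is guessed.

## Population network

The published experiment fixes only the size (2000), the 4:1
excitatory:inhibitory split, random connectivity, and the observation of
a ~6 Hz collective rhythm.  The unspecified construction is filled in
with the minimal standard scheme, all of it exposed in `NetworkConfig`:

* directed Bernoulli connectivity, p = 0.1, no self-connections;
* delta-pulse synapses: a presynaptic spike delivers a fixed charge
  (pA·ms) to each target on the following step (injected as charge/dt for
  one step); excitatory weights uniform in [0, 85], inhibitory in
  [-170, 0];
* per-step Gaussian current noise, 30 pA referred to a 1 ms step (scaled
  by sqrt(1 ms/dt) so the voltage diffusion is step-size independent);
* one shared base preset — the adaptation pattern, whose spike-triggered
  adaptation (b = 60 pA, τw = 300 ms) provides the slow timescale that
  paces population bursts — with ±5% uniform heterogeneity in the drive
  current and initial potentials scattered in [EL, VT];
* a single seed drives construction and noise, and the noise stream is
  independent of the model choice, so original and N-LUT runs are
  compared under identical input.

Mechanism: recurrent excitation synchronizes spikes into population
bursts; each burst increments every participant's adaptation current,
which silences the population until W decays; the interburst interval
τw·ln(W_peak/W_restart) lands near 170 ms.  The weight scales were chosen
(once) to sit in this slow-burst regime: weaker coupling leaves the
population asynchronous at the single-neuron adapted rate (~17 Hz, no
spectral peak), stronger coupling produces runaway high-rate bursting.
The resulting rhythm is 6 Hz in both models across seeds, read off as the
largest non-DC peak of the spectrum of the 1 ms-binned population rate
(1 Hz resolution over a 1 s window).

The mean relative spike-timing error (MRE) pairs the i-th spikes of each
neuron across the two rasters inside the window, scores each pair by
|Δt|/t_reference with the original model's spike time as reference, and
averages over paired spikes in percent; surplus unpaired spikes are
counted separately, never averaged.  What these simulations do *not*
emulate: synaptic kinetics (no rise/decay times), conduction delays,
structured topology, and parameter heterogeneity beyond the drive jitter
— so agreement here shows the LUT approximation is benign at population
scale, not that the network reproduces any particular biological circuit.

## Numerical choices

* Euler only, fixed step — the hardware has no other integrator.
* Exponent clamp 20; shared ADX saturation as above.
* Nearest-address rounding via floor(x + 0.5) (round-half-up, matching
  the hardware adder+truncate idiom); table ends clamp.
* Fixed-point encoding rounds to nearest (half up); decode is exact.
* Greedy CSD ties break toward the larger exponent; the expansion stops
  at the term budget, at zero residual, or when no admissible power
  reduces the residual.
* A diverging network neuron is clamped to (Vr, 0) with a logged warning;
  single-neuron simulators abort with the offending step instead.
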