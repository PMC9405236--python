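"""N-LUT design: sample the ADX objective function at the Nyquist rate.

The exponential membrane current ADX(V) is treated as a signal over the
operating voltage range.  Its spectral bandwidth is estimated by DFT on a
dense tabulation (the span normalized to one "second" so bin k reads as k
Hz-equivalents), and the sampling theorem's twice-the-bandwidth rule fixes
the number of lookup-table points — 20 for the default tonic configuration.
The LUT replaces the exponential at run time with a single memory read
(nearest-address, no interpolation), which is what the digital datapath does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from nlutadex.adex_core import (
    ADEXParams,
    EXP_CAP,
    DEFAULT_DT,
    DEFAULT_T,
    NeuronState,
    SimulationDiverged,
    VoltageTrace,
    adx,
    adx_ceiling,
)

__all__ = [
    "LUTSpec", "BandwidthEstimate", "default_ceiling", "operating_range",
    "tabulate_objective", "estimate_bandwidth", "nyquist_point_count",
    "build_lut", "lut_lookup", "simulate_nlut",
    "write_lut_txt", "read_lut_txt",
    "V_MIN_DEFAULT", "V_MAX_DEFAULT", "N_POINTS_MIN",
]

#: Voltage-register range of the digital design (mV) — the span over which
#: the objective is tabulated for the design-time spectral analysis.
V_MIN_DEFAULT = -60.0
V_MAX_DEFAULT = 10.0

#: Floor on the LUT point count; with the default bandwidth estimate of
#: about 10 cycles per span the twice-the-bandwidth rule lands on the same
#: 20-point table regardless of the estimator's exact output.
N_POINTS_MIN = 20


@dataclass(frozen=True)
class LUTSpec:
    """A sampled ADX table: ``values[k] = min(adx(v_min + k*dv), ceiling)``.

    ``dv = (v_max - v_min) / (n_points - 1)``; ``ceiling`` is the saturation
    cap applied to the exponential tail (see :func:`default_ceiling`).
    """

    v_min: float
    v_max: float
    n_points: int
    values: np.ndarray
    source_params: ADEXParams
    ceiling: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("LUT needs at least 2 points")
        if not self.v_min < self.v_max:
            raise ValueError("v_min must be below v_max")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != self.n_points:
            raise ValueError("length of values must equal n_points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LUT values must be finite")
        if np.any(self.values > self.ceiling + 1e-9):
            raise ValueError("LUT values must not exceed the ceiling")

    @property
    def dv(self) -> float:
        """Voltage spacing between adjacent addresses (mV)."""
        return (self.v_max - self.v_min) / (self.n_points - 1)


@dataclass(frozen=True)
class BandwidthEstimate:
    """Spectral bandwidth of the tabulated objective.

    ``base_frequency`` is in cycles per normalized span ("Hz-equivalents"):
    the dense tabulation is treated as occupying one second, so DFT bin k
    maps to k.  ``power_fraction`` is the cumulative-power threshold used.
    """

    base_frequency: float
    power_fraction: float
    n_dense: int

    def __post_init__(self) -> None:
        if self.base_frequency < 0:
            raise ValueError("base_frequency must be non-negative")
        if not 0 < self.power_fraction < 1:
            raise ValueError("power_fraction must lie in (0, 1)")


def default_ceiling(p: ADEXParams, dt: float = DEFAULT_DT) -> float:
    """Saturation cap for stored ADX values.

    The same timing-neutral level the reference integrator uses
    (:func:`nlutadex.adex_core.adx_ceiling`): high enough that one Euler
    step at the capped rate spans the remaining rise to the apex, so
    capping changes neither model's spike times, while keeping stored
    words finite.
    """
    return adx_ceiling(p, dt)


def operating_range(p: ADEXParams, dt: float = DEFAULT_DT) -> tuple[float, float]:
    """Default sampling span of a deployed LUT for parameter set ``p``.

    The 20 addresses are spent where the trajectory actually goes: the span
    starts at the lowest resting/reset potential ``min(EL, Vr)`` (deeper
    excursions read the end address, whose value is locally accurate) and
    ends where the exponential term alone reaches the saturation ceiling —
    beyond that every address would store the same capped word.
    """
    ceiling = default_ceiling(p, dt)
    v_lo = min(p.EL, p.Vr)
    v_hi = p.VT + p.DeltaT * math.log(ceiling / (p.gL * p.DeltaT))
    return v_lo, v_hi


def tabulate_objective(
    p: ADEXParams,
    v_min: float = V_MIN_DEFAULT,
    v_max: float = V_MAX_DEFAULT,
    n_dense: int = 4096,
    ceiling: float | None = None,
) -> np.ndarray:
    """ADX(V) on a dense uniform grid, ceiling-clamped.

    ``n_dense >= 64`` so the spectrum below is resolvable.
    """
    if n_dense < 64:
        raise ValueError("n_dense must be at least 64")
    if not v_min < v_max:
        raise ValueError("empty voltage range")
    if ceiling is None:
        ceiling = default_ceiling(p)
    grid = np.linspace(v_min, v_max, n_dense)
    return np.minimum(adx(grid, p, exp_cap=EXP_CAP), ceiling)


def estimate_bandwidth(
    values: np.ndarray, power_fraction: float = 0.99
) -> BandwidthEstimate:
    """Bandwidth of a dense tabulation by cumulative spectral power.

    The sequence is bridge-detrended (the line through its endpoints is
    subtracted, so the implicit periodic extension is continuous and the
    spectrum reflects the function's shape rather than the wraparound jump),
    mean-removed and amplitude-normalized, with the span treated as one
    normalized second; the base frequency is the smallest bin index whose
    cumulative power (DC excluded) reaches ``power_fraction`` of the total.
    An all-constant input has zero bandwidth.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 64:
        raise ValueError("need at least 64 samples to estimate bandwidth")
    ramp = np.linspace(values[0], values[-1], len(values))
    x = values - ramp
    x = x - x.mean()
    peak = np.abs(x).max()
    if peak == 0.0:
        return BandwidthEstimate(0.0, power_fraction, len(values))
    x = x / peak
    power = np.abs(np.fft.rfft(x)) ** 2
    power[0] = 0.0  # DC excluded
    cum = np.cumsum(power)
    total = cum[-1]
    if total == 0.0:
        return BandwidthEstimate(0.0, power_fraction, len(values))
    k = int(np.searchsorted(cum, power_fraction * total))
    return BandwidthEstimate(float(k), power_fraction, len(values))


def nyquist_point_count(est: BandwidthEstimate, minimum: int = N_POINTS_MIN) -> int:
    """LUT point count from the sampling theorem: ``max(ceil(2B), minimum)``."""
    return max(int(math.ceil(2.0 * est.base_frequency)), minimum)


def build_lut(
    p: ADEXParams,
    v_min: float | None = None,
    v_max: float | None = None,
    n_points: int = N_POINTS_MIN,
    ceiling: float | None = None,
) -> LUTSpec:
    """Sample ADX(V) at ``n_points`` uniform grid points, ceiling-clamped.

    The span defaults to the per-pattern :func:`operating_range`; either
    end may be overridden.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    auto_lo, auto_hi = operating_range(p)
    if v_min is None:
        v_min = auto_lo
    if v_max is None:
        v_max = auto_hi
    if not v_min < v_max:
        raise ValueError("empty voltage range")
    if ceiling is None:
        ceiling = default_ceiling(p)
    grid = np.linspace(v_min, v_max, n_points)
    values = np.minimum(adx(grid, p, exp_cap=EXP_CAP), ceiling)
    return LUTSpec(v_min, v_max, n_points, values, p, ceiling)


def lut_lookup(lut: LUTSpec, V):
    """Read the table at the nearest address (piecewise-constant; no interpolation).

    ``index = round((V - v_min) / dv)`` clamped to the table — the behaviour
    of an SRAM read.  Accepts scalars or arrays.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("lut_lookup: membrane potential must be finite")
    idx = np.floor((V - lut.v_min) / lut.dv + 0.5).astype(int)
    idx = np.clip(idx, 0, lut.n_points - 1)
    out = lut.values[idx]
    return float(out) if out.ndim == 0 else out


def simulate_nlut(
    p: ADEXParams,
    lut: LUTSpec,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_T,
    init: NeuronState | None = None,
) -> VoltageTrace:
    """Forward-Euler trajectory with ADX(V) replaced by the LUT read.

    Identical protocol and reset rule to
    :func:`nlutadex.adex_core.simulate_original`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least one step")
    if init is None:
        init = NeuronState(p.EL, 0.0)

    n = int(math.floor(T / dt)) + 1
    V = np.empty(n)
    W = np.empty(n)
    spikes: list[float] = []

    C, EL, a, tw, b, Vr, I = p.C, p.EL, p.a, p.tau_w, p.b, p.Vr, p.I
    vals = lut.values
    v_min = lut.v_min
    inv_dv = 1.0 / lut.dv
    top = lut.n_points - 1

    v, w = init.V, init.W
    for i in range(n):
        V[i] = v
        W[i] = w
        if not (math.isfinite(v) and math.isfinite(w)):
            raise SimulationDiverged(
                f"state diverged at step {i} (t={i * dt:.6g} ms): V={v}, W={w}"
            )
        if v > 0:
            spikes.append(i * dt)
            v, w = Vr, w + b
        if i == n - 1:
            break
        k = int((v - v_min) * inv_dv + 0.5) if v >= v_min else 0
        if k > top:
            k = top
        fv = vals[k]
        v, w = (
            v + dt * (fv + I - w) / C,
            w + dt * (a * (v - EL) - w) / tw,
        )

    t = np.arange(n) * dt
    return VoltageTrace(t, V, W, np.asarray(spikes))


def write_lut_txt(lut: LUTSpec, path) -> None:
    """Write LUT values as a plain-text memory file, one value per line.

    A comment header records the voltage range so the file round-trips.
    """
    with open(path, "w") as fh:
        fh.write(f"# v_min={lut.v_min} v_max={lut.v_max} ceiling={lut.ceiling}\n")
        for val in lut.values:
            fh.write(f"{float(val)!r}\n")


def read_lut_txt(path, source_params: ADEXParams) -> LUTSpec:
    """Read a memory file written by :func:`write_lut_txt`."""
    with open(path) as fh:
        header = fh.readline()
        meta = dict(item.split("=") for item in header.lstrip("# ").split())
        values = [float(line) for line in fh if line.strip()]
    return LUTSpec(
        float(meta["v_min"]), float(meta["v_max"]), len(values),
        np.asarray(values), source_params, float(meta["ceiling"]),
    )
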