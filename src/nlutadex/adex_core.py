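"""Continuous ADEX neuron model.

The adaptive exponential integrate-and-fire neuron is the two-variable system

    C  dV/dt = -gL (V - EL) + gL * DeltaT * exp((V - VT) / DeltaT) + I - W
    tau_w dW/dt = a (V - EL) - W

with the reset rule  V > 0  =>  V <- Vr, W <- W + b.  Units are fixed as
pF / nS / mV / pA / ms, which make the equations dimensionally consistent
without conversion factors.

The voltage-dependent part of the membrane current,

    ADX(V) = -gL (V - EL) + gL * DeltaT * exp((V - VT) / DeltaT),

is the objective function later replaced by a lookup table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ADEXParams", "NeuronState", "VoltageTrace", "PatternPreset",
    "adx", "adx_ceiling", "derivatives", "apply_reset", "simulate_original",
    "preset", "preset_names", "write_trace_csv", "read_trace_csv",
    "DEFAULT_DT", "DEFAULT_T", "EXP_CAP", "APEX_SPAN",
]

#: Euler time step used throughout the digital design (ms).
DEFAULT_DT = 1.0 / 128.0

#: Default simulation window (ms).
DEFAULT_T = 1000.0

#: Cap on the exponent argument of the spike-initiation term.  The neuron is
#: reset one sample after V crosses its apex, so the exponential is only ever
#: evaluated slightly above threshold; the cap (exp(20) ~ 4.85e8) keeps that
#: single step finite without affecting subthreshold dynamics.
EXP_CAP = 20.0

#: Upper bound on the distance (mV) from any operating potential to the
#: spike-detection apex; sets the default membrane-current saturation level.
APEX_SPAN = 80.0


def adx_ceiling(p: "ADEXParams", dt: float = DEFAULT_DT) -> float:
    """Default saturation level for the membrane current (pA).

    ``C * APEX_SPAN / dt``: the smallest level at which a single Euler step
    at the saturated rate spans the whole remaining rise to the apex.  Above
    it the exponential only changes *how far* one step overshoots, not
    *when* the spike is detected, so saturating there is timing-neutral;
    saturating lower would stretch every spike upstroke and desynchronize
    the models being compared.  Both the reference integrator and the
    lookup table use this same level, so their suprathreshold dynamics are
    identical by construction.
    """
    return p.C * APEX_SPAN / dt


class SimulationDiverged(RuntimeError):
    """Raised when a state variable becomes non-finite during integration."""


@dataclass(frozen=True)
class ADEXParams:
    """The ten parameters of the ADEX neuron.

    Attributes
    ----------
    C : float
        Membrane capacitance (pF).
    gL : float
        Leak conductance (nS).
    EL : float
        Effective rest potential (mV).
    VT : float
        Threshold potential (mV).
    DeltaT : float
        Threshold slope factor (mV).
    a : float
        Subthreshold adaptation conductance (nS).
    tau_w : float
        Adaptation time constant (ms).
    b : float
        Spike-triggered adaptation increment (pA).
    Vr : float
        Reset potential (mV), below the V > 0 spike-detection apex.
    I : float
        Constant stimulus current (pA).
    """

    C: float
    gL: float
    EL: float
    VT: float
    DeltaT: float
    a: float
    tau_w: float
    b: float
    Vr: float
    I: float

    def __post_init__(self) -> None:
        vals = [self.C, self.gL, self.EL, self.VT, self.DeltaT,
                self.a, self.tau_w, self.b, self.Vr, self.I]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all ADEX parameters must be finite")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.tau_w <= 0:
            raise ValueError(f"tau_w must be positive, got {self.tau_w}")
        if self.DeltaT <= 0:
            raise ValueError(f"DeltaT must be positive, got {self.DeltaT}")
        if self.Vr >= 0:
            raise ValueError(f"Vr must lie below the spike apex (0 mV), got {self.Vr}")


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous state: membrane potential V (mV), adaptation W (pA)."""

    V: float
    W: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.V) and math.isfinite(self.W)):
            raise ValueError(f"state must be finite, got V={self.V}, W={self.W}")


@dataclass
class VoltageTrace:
    """Uniformly sampled (t, V, W) trajectory with recorded spike times.

    ``spike_times`` holds the time stamps of samples at which V exceeded the
    0 mV apex; the stored V at those samples is the pre-reset value so the
    spike apex remains visible in plots.
    """

    t: np.ndarray
    V: np.ndarray
    W: np.ndarray
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if not (len(self.t) == len(self.V) == len(self.W)):
            raise ValueError("t, V, W must have equal lengths")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0


@dataclass(frozen=True)
class PatternPreset:
    """A named firing-pattern parameter set from the published preset table."""

    name: str
    params: ADEXParams


# The eight firing-pattern rows: C, gL, EL, VT, DeltaT, a, tau_w, b, Vr, I.
_PRESET_TABLE: dict[str, ADEXParams] = {
    "Tonic spiking":        ADEXParams(200, 10,  -70, -50, 2,    2,   30,  0,   -58, 500),
    "Adaptation":           ADEXParams(200, 12,  -70, -50, 2,    2,   300, 60,  -58, 500),
    "Initial bursting":     ADEXParams(130, 18,  -58, -50, 2,    4,   150, 120, -50, 400),
    "Delayed accelerating": ADEXParams(200, 12,  -70, -50, 2,   -10,  300, 0,   -58, 300),
    "Irregular spiking":    ADEXParams(100, 12,  -60, -50, 2,   -11,  130, 30,  -48, 160),
    "can":                  ADEXParams(59,  2.9, -62, -42, 3,    1.8, 16,  61,  -54, 184),
    "cAD":                  ADEXParams(83,  1.7, -59, -56, 5.5,  2,   41,  55,  -54, 116),
    "RS":                   ADEXParams(104, 4.3, -65, -52, 0.8, -0.8, 88,  65,  -53, 98),
}


def preset_names() -> list[str]:
    """Names of the eight firing-pattern presets, in table order."""
    return list(_PRESET_TABLE)


def preset(name: str) -> PatternPreset:
    """Return the named firing-pattern preset.

    Raises
    ------
    KeyError
        If ``name`` is not one of the eight preset labels; the message lists
        the valid names.
    """
    try:
        return PatternPreset(name, _PRESET_TABLE[name])
    except KeyError:
        raise KeyError(
            f"unknown pattern {name!r}; valid names: {', '.join(_PRESET_TABLE)}"
        ) from None


def adx(V, p: ADEXParams, exp_cap: float = EXP_CAP):
    """Voltage-dependent membrane current ADX(V) in pA.

    ``-gL (V - EL) + gL * DeltaT * exp((V - VT) / DeltaT)``, with the exponent
    argument clamped at ``exp_cap``.  Accepts scalars or numpy arrays.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("adx: membrane potential must be finite")
    arg = np.minimum((V - p.VT) / p.DeltaT, exp_cap)
    out = -p.gL * (V - p.EL) + p.gL * p.DeltaT * np.exp(arg)
    return float(out) if out.ndim == 0 else out


def derivatives(s: NeuronState, p: ADEXParams) -> tuple[float, float]:
    """Time derivatives (dV/dt in mV/ms, dW/dt in pA/ms) at state ``s``."""
    dV = (adx(s.V, p) + p.I - s.W) / p.C
    dW = (p.a * (s.V - p.EL) - s.W) / p.tau_w
    return dV, dW


def apply_reset(s: NeuronState, p: ADEXParams) -> NeuronState:
    """Post-spike reset: V <- Vr, W <- W + b.

    Must only be called when the membrane potential has crossed the 0 mV
    apex (``s.V > 0``); calling it below the apex is a contract violation.
    """
    if not s.V > 0:
        raise ValueError(f"apply_reset called with V={s.V} <= 0 (no spike)")
    return NeuronState(p.Vr, s.W + p.b)


def simulate_original(
    p: ADEXParams,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_T,
    init: NeuronState | None = None,
    exp_cap: float = EXP_CAP,
    ceiling: float | None = None,
) -> VoltageTrace:
    """Forward-Euler integration of the ADEX equations with the exact exponential.

    At each recorded sample with V > 0 the spike time is logged and the reset
    is applied before the next step; the stored V at that sample is the
    pre-reset value.  The trace has ``floor(T/dt) + 1`` samples.

    The membrane current is saturated at ``ceiling`` (default
    :func:`adx_ceiling`, the timing-neutral level shared with the lookup
    table); pass ``math.inf`` for the unsaturated exponential.

    Parameters default to the protocol used for all model comparisons:
    dt = 1/128 ms, T = 1000 ms, initial state (EL, 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least one step")
    if init is None:
        init = NeuronState(p.EL, 0.0)
    if ceiling is None:
        ceiling = adx_ceiling(p, dt)

    n = int(math.floor(T / dt)) + 1
    V = np.empty(n)
    W = np.empty(n)
    spikes: list[float] = []

    # Hoist parameters: the inner loop runs ~1e5 times.
    C, gL, EL, VT, DT = p.C, p.gL, p.EL, p.VT, p.DeltaT
    a, tw, b, Vr, I = p.a, p.tau_w, p.b, p.Vr, p.I
    exp = math.exp

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
        arg = (v - VT) / DT
        if arg > exp_cap:
            arg = exp_cap
        fv = -gL * (v - EL) + gL * DT * exp(arg)
        if fv > ceiling:
            fv = ceiling
        v, w = (
            v + dt * (fv + I - w) / C,
            w + dt * (a * (v - EL) - w) / tw,
        )

    t = np.arange(n) * dt
    return VoltageTrace(t, V, W, np.asarray(spikes))


def write_trace_csv(trace: VoltageTrace, path) -> None:
    """Write a trace as CSV with columns ``t_ms,V_mV,W_pA,spike``."""
    spike = np.isin(trace.t, trace.spike_times).astype(int)
    df = pd.DataFrame(
        {"t_ms": trace.t, "V_mV": trace.V, "W_pA": trace.W, "spike": spike}
    )
    df.to_csv(path, index=False)


def read_trace_csv(path) -> VoltageTrace:
    """Read a trace written by :func:`write_trace_csv`."""
    df = pd.read_csv(path)
    spikes = df.loc[df["spike"] == 1, "t_ms"].to_numpy()
    return VoltageTrace(
        df["t_ms"].to_numpy(), df["V_mV"].to_numpy(), df["W_pA"].to_numpy(), spikes
    )
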