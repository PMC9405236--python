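"""Population experiment: 2000 randomly connected ADEX neurons, 4:1 E:I.

The published experiment specifies only the population size, the 4:1
excitatory:inhibitory split, random connectivity, and the observation of a
slow (~6 Hz) population rhythm shared by the original and LUT models.  The
construction here fills in the unstated parts with the minimal standard
scheme: delta-pulse synapses (each presynaptic spike delivers a fixed
charge to its targets on the following step), uniform random weights,
per-step Gaussian current noise, one shared base parameter set (the
adaptation preset, whose spike-triggered adaptation paces slow population
bursts) with seeded heterogeneity in the drive current and initial state.
Everything is exposed in :class:`NetworkConfig` and fully reproducible
under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nlutadex.adex_core import ADEXParams, DEFAULT_DT, EXP_CAP, preset
from nlutadex.lut_designer import LUTSpec, build_lut

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig", "Network", "RasterData",
    "build_network", "simulate_population", "rhythm_frequency", "mre",
    "mre_detail", "write_raster_csv", "read_raster_csv", "write_edge_list",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Construction parameters of the random E/I network.

    Weights are synaptic charges in pA*ms: a presynaptic spike injects
    ``w / dt`` pA for one integration step, i.e. a delta-pulse carrying
    charge ``w``.  ``noise_pA`` is the standard deviation of the Gaussian
    current noise referred to a 1 ms step (scaled by sqrt(1 ms / dt) so the
    voltage diffusion is step-size independent).  ``jitter`` is the relative
    half-width of the uniform per-neuron spread applied to the drive
    current; initial potentials are drawn uniformly between EL and VT.
    """

    n_neurons: int = 2000
    exc_fraction: float = 0.8
    connection_prob: float = 0.1
    w_exc_max: float = 85.0
    w_inh_max: float = 170.0
    noise_pA: float = 30.0
    preset_name: str = "Adaptation"
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.exc_fraction < 1:
            raise ValueError("exc_fraction must lie in (0, 1)")
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if not 0 <= self.connection_prob <= 1:
            raise ValueError("connection_prob must lie in [0, 1]")
        if self.w_exc_max < 0 or self.w_inh_max < 0 or self.noise_pA < 0:
            raise ValueError("weight ranges and noise scale must be non-negative")


@dataclass
class Network:
    """A built network: weights, classes, per-neuron drive and initial state."""

    cfg: NetworkConfig
    params: ADEXParams
    weights: np.ndarray        # (post, pre), charge in pA*ms; 0 = no edge
    is_exc: np.ndarray         # bool per neuron
    I: np.ndarray              # per-neuron drive current (pA)
    V0: np.ndarray             # initial membrane potentials (mV)

    @property
    def n(self) -> int:
        return self.cfg.n_neurons


@dataclass
class RasterData:
    """Per-neuron spike times (ms) with duration and E/I class labels."""

    spike_times: list[np.ndarray]
    duration: float
    is_exc: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(s, dtype=float) for s in self.spike_times]
        for s in self.spike_times:
            if len(s) and (s.min() < 0 or s.max() > self.duration):
                raise ValueError("spike times must lie within [0, duration]")
            if np.any(np.diff(s) <= 0):
                raise ValueError("per-neuron spike times must be strictly increasing")

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_times))


def build_network(cfg: NetworkConfig) -> Network:
    """Build the seeded random directed network.

    The first ``round(n * exc_fraction)`` neurons are excitatory with
    weights in [0, w_exc_max]; the rest inhibitory with weights in
    [-w_inh_max, 0].  Self-connections are excluded.  The same config and
    seed always produce the identical network.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons
    n_exc = int(round(n * cfg.exc_fraction))
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:n_exc] = True

    mask = rng.random((n, n)) < cfg.connection_prob
    np.fill_diagonal(mask, False)
    mag = rng.random((n, n))
    weights = np.where(is_exc[None, :], mag * cfg.w_exc_max, -mag * cfg.w_inh_max)
    weights = np.where(mask, weights, 0.0).astype(np.float64)

    base = preset(cfg.preset_name).params
    I = base.I * (1.0 + cfg.jitter * (2.0 * rng.random(n) - 1.0))
    V0 = base.EL + (base.VT - base.EL) * rng.random(n)
    return Network(cfg, base, weights, is_exc, I, V0)


def simulate_population(
    net: Network,
    model: str = "original",
    T: float = 1000.0,
    dt: float = DEFAULT_DT,
    lut: LUTSpec | None = None,
) -> RasterData:
    """Integrate the whole population with forward Euler.

    ``model`` selects the exact exponential (``"original"``) or the LUT read
    (``"nlut"``).  Each neuron receives its jittered drive, the delta-pulse
    synaptic input from the previous step's spikes, and seeded noise; the
    noise stream depends only on the network seed, so the two models run
    under identical noise.  A diverging neuron is clamped to the reset
    potential, logged, and the run continues.
    """
    if model not in ("original", "nlut"):
        raise ValueError(f"unknown model {model!r}; use 'original' or 'nlut'")
    if model == "nlut" and lut is None:
        lut = build_lut(net.params)

    p = net.params
    n = net.n
    n_steps = int(math.floor(T / dt))
    rng = np.random.default_rng(np.random.SeedSequence((net.cfg.seed, 1)))
    sigma_step = net.cfg.noise_pA * math.sqrt(1.0 / dt)

    V = net.V0.copy()
    W = np.zeros(n)
    spikes: list[list[float]] = [[] for _ in range(n)]
    fired = np.zeros(n, dtype=bool)

    if lut is not None:
        lut_vals = lut.values
        inv_dv = 1.0 / lut.dv
        v_min_lut = lut.v_min
        top = lut.n_points - 1

    inv_C = dt / p.C
    inv_tw = dt / p.tau_w
    w_per_dt = net.weights / dt

    for i in range(n_steps + 1):
        t = i * dt
        just = V > 0.0
        if just.any():
            idx = np.nonzero(just)[0]
            for j in idx:
                spikes[j].append(t)
            V[just] = p.Vr
            W[just] += p.b
        fired = just
        if i == n_steps:
            break

        if model == "original":
            arg = np.minimum((V - p.VT) / p.DeltaT, EXP_CAP)
            fv = -p.gL * (V - p.EL) + p.gL * p.DeltaT * np.exp(arg)
        else:
            k = np.clip(((V - v_min_lut) * inv_dv + 0.5).astype(np.int64), 0, top)
            fv = lut_vals[k]

        if fired.any():
            syn = w_per_dt[:, fired].sum(axis=1)
        else:
            syn = 0.0
        noise = sigma_step * rng.standard_normal(n)
        I_tot = net.I + syn + noise

        dV = inv_C * (fv + I_tot - W)
        dW = inv_tw * (p.a * (V - p.EL) - W)
        V += dV
        W += dW

        bad = ~np.isfinite(V) | ~np.isfinite(W)
        if bad.any():
            logger.warning("clamping %d diverged neurons at t=%.3f ms", bad.sum(), t)
            V[bad] = p.Vr
            W[bad] = 0.0

    return RasterData([np.asarray(s) for s in spikes], float(T), net.is_exc.copy())


def rhythm_frequency(r: RasterData, bin_ms: float = 1.0) -> float:
    """Dominant population-rhythm frequency in Hz.

    Bins all spikes into a population rate histogram, removes the mean, and
    returns the frequency of the largest non-DC peak of its spectrum.
    """
    if r.duration < 500.0:
        raise ValueError("need at least 500 ms of data for a rhythm estimate")
    all_spikes = np.concatenate([s for s in r.spike_times if len(s)]) \
        if r.total_spikes() else np.empty(0)
    if len(all_spikes) == 0:
        raise ValueError("empty raster")
    n_bins = int(round(r.duration / bin_ms))
    counts, _ = np.histogram(all_spikes, bins=n_bins, range=(0.0, r.duration))
    x = counts - counts.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    power[0] = 0.0
    k = int(np.argmax(power))
    return float(k / (r.duration / 1000.0))


def mre_detail(
    r_orig: RasterData, r_prop: RasterData, window: float = 1000.0
) -> tuple[float, int, int]:
    """Mean relative spike-timing error with pairing bookkeeping.

    For each neuron the i-th spikes of the two rasters inside the window are
    paired in order; the error of a pair is |t_prop - t_orig| / t_orig with
    the original model's spike time as reference.  Returns
    ``(MRE %, paired count, unpaired surplus count)``; surplus spikes in
    either raster are excluded from the average.
    """
    if r_orig.n_neurons != r_prop.n_neurons:
        raise ValueError("rasters must have the same neuron count")
    total = 0.0
    n_pairs = 0
    n_unpaired = 0
    for so, sp in zip(r_orig.spike_times, r_prop.spike_times):
        so = so[(so <= window) & (so > 0)]
        sp = sp[(sp <= window) & (sp > 0)]
        m = min(len(so), len(sp))
        n_unpaired += abs(len(so) - len(sp))
        if m == 0:
            continue
        total += float(np.sum(np.abs(sp[:m] - so[:m]) / np.abs(so[:m])))
        n_pairs += m
    if n_pairs == 0:
        raise ValueError("no paired spikes within the window")
    return total / n_pairs * 100.0, n_pairs, n_unpaired


def mre(r_orig: RasterData, r_prop: RasterData, window: float = 1000.0) -> float:
    """Mean relative spike-timing error in percent (see :func:`mre_detail`)."""
    return mre_detail(r_orig, r_prop, window)[0]


def write_raster_csv(r: RasterData, path) -> None:
    """Write a raster as CSV: ``neuron_id,t_ms,class``."""
    rows = [
        (j, t, "exc" if r.is_exc[j] else "inh")
        for j, s in enumerate(r.spike_times)
        for t in s
    ]
    pd.DataFrame(rows, columns=["neuron_id", "t_ms", "class"]).to_csv(path, index=False)


def read_raster_csv(path, n_neurons: int, duration: float) -> RasterData:
    """Read a raster written by :func:`write_raster_csv`."""
    df = pd.read_csv(path)
    spikes = [np.empty(0)] * n_neurons
    is_exc = np.ones(n_neurons, dtype=bool)
    for j, grp in df.groupby("neuron_id"):
        spikes[int(j)] = np.sort(grp["t_ms"].to_numpy())
        is_exc[int(j)] = grp["class"].iloc[0] == "exc"
    return RasterData(spikes, duration, is_exc)


def write_edge_list(net: Network, path) -> None:
    """Write the weighted edge list (``pre,post,weight``) for reproducibility audits."""
    post, pre = np.nonzero(net.weights)
    pd.DataFrame(
        {"pre": pre, "post": post, "weight": net.weights[post, pre]}
    ).to_csv(path, index=False)
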