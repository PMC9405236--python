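# nlutadex

Lookup-table modelling of the adaptive exponential integrate-and-fire
(ADEX) neuron for digital/neuromorphic hardware, with a bit-exact software
emulation of the multiplierless fixed-point datapath.

## The problem

The ADEX neuron couples a membrane potential V (mV) to an adaptation
current W (pA):

    C  dV/dt = -gL (V - EL) + gL ΔT exp((V - VT)/ΔT) + I - W
    τw dW/dt = a (V - EL) - W
    if V > 0:  V ← Vr,  W ← W + b

With suitable parameters it reproduces eight canonical cortical firing
patterns (tonic spiking, adaptation, initial bursting, delayed
accelerating, irregular spiking, "can", "cAD", regular spiking), which
makes it attractive for large-scale spiking-network hardware — except that
the exponential term is expensive to realize digitally.

This package implements the **N-LUT-ADEX** approach: treat the
voltage-dependent membrane current

    ADX(V) = -gL (V - EL) + gL ΔT exp((V - VT)/ΔT)

as a signal over the operating voltage range, estimate its spectral
bandwidth B by DFT, sample it at the Nyquist rate (≥ 2B points — 20 for
the tonic configuration), and replace the exponential at run time with a
single memory read.  Every remaining constant multiplication is decomposed
into canonical signed digits (a short signed sum of powers of two), so the
whole update step runs on shifts, adds and subtracts only: no multipliers,
dividers or exponential units.

## What's in the box

| module | contents |
| --- | --- |
| `nlutadex.adex_core` | continuous model, the 8 firing-pattern presets, forward-Euler reference simulator |
| `nlutadex.lut_designer` | dense tabulation, DFT bandwidth estimate, Nyquist point count, LUT build/lookup, N-LUT simulator |
| `nlutadex.digital_pipeline` | CSD decomposition, the digitized (power-of-two) parameter table, fixed-point formats, the shift/add datapath emulator with an operation trace, bit-width rule, operator census, LUT memory export (hex/COE) |
| `nlutadex.dynamics_validation` | MAE / Pearson correlation / trough-error metrics, nullclines, Jacobians, phase portraits |
| `nlutadex.network_sim` | 2000-neuron 4:1 excitatory:inhibitory random network, raster analysis, population rhythm, mean relative spike-timing error (MRE) |
| `nlutadex.cli` | `nlutadex` console script: `simulate`, `build-lut`, `validate`, `network`, `export-lut`, `fixtures` |

## Worked example

```python
from nlutadex import *
from nlutadex.lut_designer import tabulate_objective

p = preset("Tonic spiking").params

# 1. design the table: bandwidth -> Nyquist point count
est = estimate_bandwidth(tabulate_objective(p))
n = nyquist_point_count(est)
print(f"bandwidth {est.base_frequency:.0f} cycles/span -> {n} LUT points")

# 2. simulate both models under the standard protocol
orig = simulate_original(p)                  # dt = 1/128 ms, T = 1000 ms
prop = simulate_nlut(p, build_lut(p, n_points=n))
print(f"spikes: original {len(orig.spike_times)}, N-LUT {len(prop.spike_times)}")
print(f"MAE {mae(orig, prop):.2f} mV, correlation {correlation(orig, prop):.1f} %")

# 3. prove the fixed-point datapath is multiplierless
trace, ops = simulate_fixed("Tonic spiking", T=1000.0)
print(f"fixed-point ops: mul={ops.mul} div={ops.div} exp={ops.exp} "
      f"shifts={ops.shift} lut_reads={ops.lut_read}")
```

prints

    bandwidth 8 cycles/span -> 20 LUT points
    spikes: original 103, N-LUT 103
    MAE 2.68 mV, correlation 34.7 %
    fixed-point ops: mul=0 div=0 exp=0 shifts=1408000 lut_reads=128000

The 20-point table preserves the firing pattern exactly (same spike count,
same phase-plane loop) while the quantized membrane current introduces a
slow spike-phase drift over the 1-second window, which is what the MAE and
correlation quantify.  `bit_width_analysis(-60, 10, 20)` gives the 28-bit
voltage-register word (6 integer + 20 fraction + guard + sign), and
`resource_census` compares the operator inventories of the two datapaths
(original: 1 exponential, 6 multipliers, 5 dividers; proposed: adders and
subtractors only).

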