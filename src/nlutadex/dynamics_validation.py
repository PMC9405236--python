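"""Quantitative and phase-plane comparison of the original and N-LUT models.

Trace metrics: mean absolute voltage error (MAE), Pearson correlation in
percent, and the trough error ERRp — the absolute difference between the
two traces' lowest membrane potentials.  Phase-plane tools: nullclines of
both models, the 2x2 Jacobian, and (V, W) phase portraits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nlutadex.adex_core import ADEXParams, VoltageTrace, adx
from nlutadex.lut_designer import LUTSpec, lut_lookup

__all__ = [
    "ErrorReport", "Jacobian2x2", "mae", "correlation", "err_p",
    "error_report", "nullclines", "jacobian", "phase_portrait",
    "write_metrics_csv",
]


@dataclass(frozen=True)
class ErrorReport:
    """Trace-comparison summary: trough error, MAE (both mV), correlation (%)."""

    err_p: float
    mae: float
    correlation_pct: float

    def __post_init__(self) -> None:
        if self.mae < 0 or self.err_p < 0:
            raise ValueError("error magnitudes must be non-negative")
        if not -100.0 <= self.correlation_pct <= 100.0 + 1e-9:
            raise ValueError("correlation must lie in [-100, 100]")


@dataclass(frozen=True)
class Jacobian2x2:
    """Entries of the Jacobian of the (V, W) system.

    A1 = d(dV/dt)/dV (1/ms), B1 = d(dV/dt)/dW (mV/(pA ms)),
    C1 = d(dW/dt)/dV (pA/(mV ms)), D1 = d(dW/dt)/dW (1/ms).
    """

    A1: float
    B1: float
    C1: float
    D1: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.A1, self.B1, self.C1, self.D1))):
            raise ValueError("Jacobian entries must be finite")


def _check_grids(a: VoltageTrace, b: VoltageTrace) -> None:
    if len(a) != len(b) or not np.allclose(a.t, b.t):
        raise ValueError("traces must share the same time grid")


def mae(a: VoltageTrace, b: VoltageTrace) -> float:
    """Mean absolute voltage error between two traces on a shared grid (mV)."""
    _check_grids(a, b)
    return float(np.mean(np.abs(a.V - b.V)))


def correlation(a: VoltageTrace, b: VoltageTrace) -> float:
    """Pearson correlation of the two voltage sequences, in percent."""
    _check_grids(a, b)
    if np.std(a.V) == 0 or np.std(b.V) == 0:
        raise ValueError("correlation undefined for a constant trace")
    r = stats.pearsonr(a.V, b.V).statistic
    return float(r * 100.0)


def err_p(a: VoltageTrace, b: VoltageTrace) -> float:
    """Trough error: |min V_a - min V_b| (mV)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("traces must be non-empty")
    return float(abs(a.V.min() - b.V.min()))


def error_report(a: VoltageTrace, b: VoltageTrace) -> ErrorReport:
    """All three trace metrics in one record."""
    return ErrorReport(err_p(a, b), mae(a, b), correlation(a, b))


def nullclines(
    p: ADEXParams,
    model: str = "original",
    lut: LUTSpec | None = None,
    v_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nullclines over a voltage grid: ``(v_grid, W_V_nullcline, W_W_nullcline)``.

    V-nullcline: W = ADX(V) + I (exact for the original model, the LUT read
    for the proposed one, hence piecewise constant between addresses).
    W-nullcline: W = a (V - EL).  Intersections are the fixed points.
    """
    if v_grid is None:
        v_grid = np.linspace(p.EL - 10.0, p.VT + 10.0, 512)
    v_grid = np.asarray(v_grid, dtype=float)
    if model == "original":
        w_v = adx(v_grid, p) + p.I
    elif model == "proposed":
        if lut is None:
            raise ValueError("proposed-model nullclines need a LUTSpec")
        w_v = lut_lookup(lut, v_grid) + p.I
    else:
        raise ValueError(f"unknown model {model!r}")
    w_w = p.a * (v_grid - p.EL)
    return v_grid, w_v, w_w


def jacobian(
    p: ADEXParams,
    model: str = "original",
    state=None,
    mode: str = "analytic",
) -> Jacobian2x2:
    """Jacobian of the (V, W) system at ``state`` (defaults to V = EL).

    ``analytic`` differentiates the model equations: for the original model
    A1 = (gL/C)(exp(f(V)) - 1) and B1 = -1/C; the proposed model's
    piecewise-constant LUT has zero voltage derivative, so A1 = 0.
    ``paper_table`` reproduces the published table verbatim instead,
    including its dimensionally odd B1 = -1 entry for the proposed row
    (the analytic value is -1/C); no intent is guessed, both are available.
    """
    if mode not in ("analytic", "paper_table"):
        raise ValueError(f"unknown mode {mode!r}")
    if model not in ("original", "proposed"):
        raise ValueError(f"unknown model {model!r}")
    V = p.EL if state is None else state.V
    C1 = p.a / p.tau_w
    D1 = -1.0 / p.tau_w
    if model == "original":
        A1 = (p.gL / p.C) * (math.exp((V - p.VT) / p.DeltaT) - 1.0)
        B1 = -1.0 / p.C
    else:
        A1 = 0.0
        B1 = -1.0 if mode == "paper_table" else -1.0 / p.C
    return Jacobian2x2(A1, B1, C1, D1)


def phase_portrait(trace: VoltageTrace) -> np.ndarray:
    """The (V, W) projection of a trace, shape (n, 2), for overlay plots.

    Resets appear as horizontal jumps back to the reset potential.
    """
    if len(trace) == 0:
        raise ValueError("trace must be non-empty")
    return np.column_stack((trace.V, trace.W))


def write_metrics_csv(rows: dict[str, ErrorReport], path) -> None:
    """Write per-pattern metrics as CSV: ``pattern,ERRp,MAE,correlation_pct``."""
    df = pd.DataFrame(
        [
            {"pattern": name, "ERRp": r.err_p, "MAE": r.mae,
             "correlation_pct": r.correlation_pct}
            for name, r in rows.items()
        ]
    )
    df.to_csv(path, index=False)
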