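"""Fixed-point pipeline: CSD, digitized presets, shift/add scaling, emulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlutadex.adex_core import preset
from nlutadex.digital_pipeline import (
    DATAPATH_FORMAT,
    CSDDecomposition,
    FixedPointFormat,
    OpTrace,
    bit_width_analysis,
    csd_decompose,
    digital_params,
    digital_preset,
    export_fixed_lut,
    from_fixed,
    import_fixed_lut,
    resource_census,
    shift_add_scale,
    simulate_fixed,
    table4_divergence_report,
    to_fixed,
)
from nlutadex.lut_designer import build_lut, simulate_nlut


class TestCSD:
    @pytest.mark.parametrize("x", [200, 500, 61, 5.5, 10, -10, 1, 0.5, 184])
    def test_exactly_representable_values_reproduced(self, x):
        d = csd_decompose(x)
        assert d.value == x
        assert len(d.terms) <= 3

    def test_sub_unity_tail_truncated(self):
        # 1.8 with exponents floored at 2^-2 realizes 1.75
        assert csd_decompose(1.8).value == 1.75

    def test_power_of_two_is_single_term(self):
        assert csd_decompose(1).terms == ((1, 0),)

    def test_zero_is_empty(self):
        d = csd_decompose(0)
        assert d.terms == () and d.value == 0.0

    def test_canonical_form_of_200(self):
        # greedy nearest-power reduction yields the canonical signed-digit
        # form 256 - 64 + 8 (three nonzero digits, same realized value)
        assert csd_decompose(200).terms == ((1, 8), (-1, 6), (1, 3))

    @given(x=st.floats(-1000, 1000).filter(lambda v: abs(v) > 1e-3))
    @settings(max_examples=100, deadline=None)
    def test_invariants_and_error_bound(self, x):
        d = csd_decompose(x, max_terms=4, min_exponent=-6)
        exps = [e for _, e in d.terms]
        assert exps == sorted(exps, reverse=True)
        assert len(set(exps)) == len(exps)
        # each greedy step at least halves the residual scale
        assert abs(d.value - x) <= max(2.0 ** (min(exps) - 1), 2.0 ** -7) if exps else x == 0


class TestDigitalPresets:
    def test_tonic_row_verbatim(self):
        row = digital_preset("Tonic spiking")
        assert row["C"].terms == ((1, 7), (1, 6), (1, 3))        # 128+64+8
        assert row["I"].terms == ((1, 9), (-1, 3), (-1, 2))      # 512-8-4
        assert row["tau_w"].value == 28                          # printed 16+8+4
        assert row["Vr"].value == -56

    def test_cad_threshold_slope(self):
        assert digital_preset("cAD")["DeltaT"].value == 5.5      # 4+1+(1/2)

    def test_can_capacitance_sign_corrected_by_default(self):
        assert digital_preset("can")["C"].value == 56
        printed = digital_preset("can", printed_can_capacitance=True)
        assert printed["C"].value == -56

    def test_unknown_pattern(self):
        with pytest.raises(KeyError):
            digital_preset("nope")

    def test_divergence_report_flags_only_known_rows(self):
        report = table4_divergence_report()
        flagged = {(r["pattern"], r["parameter"])
                   for r in report if r["beyond_10pct"]}
        assert flagged == {("RS", "DeltaT"), ("RS", "a"), ("cAD", "gL")}
        # every realized value is within 10% of its continuous counterpart
        # except the flagged entries
        for r in report:
            if not r["beyond_10pct"]:
                assert r["rel_error"] <= 0.10

    def test_realized_params_form_valid_preset(self):
        p = digital_params("Tonic spiking")
        assert p.C == 200 and p.I == 500 and p.tau_w == 28


class TestFixedPoint:
    FMT = FixedPointFormat(28, 20)

    def test_unit_encoding(self):
        assert to_fixed(1.0, self.FMT) == 1 << 20

    def test_zero(self):
        assert to_fixed(0.0, self.FMT) == 0

    def test_saturation_logged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="nlutadex.digital_pipeline"):
            rep = to_fixed(1e9, self.FMT)
        assert rep == self.FMT.max_int
        assert "overflow" in caplog.text

    @given(x=st.floats(-100.0, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_error_bound(self, x):
        rep = to_fixed(x, self.FMT)
        assert abs(from_fixed(rep, self.FMT) - x) <= 2.0 ** -21


class TestShiftAddScale:
    def test_identity_scale(self):
        d = CSDDecomposition(((1, 0),), 1.0)
        trace = OpTrace()
        v = to_fixed(3.25, DATAPATH_FORMAT)
        assert shift_add_scale(v, d, trace) == v
        assert (trace.shift, trace.add, trace.sub) == (1, 0, 0)

    def test_scale_by_200(self):
        d = csd_decompose(200)
        trace = OpTrace()
        out = shift_add_scale(to_fixed(1.0, DATAPATH_FORMAT), d, trace)
        assert from_fixed(out, DATAPATH_FORMAT) == 200.0

    def test_never_multiplies(self):
        trace = OpTrace()
        shift_add_scale(12345, csd_decompose(500), trace)
        assert trace.mul == 0 and trace.div == 0 and trace.exp == 0

    def test_bit_identical_to_integer_product(self, rng):
        # oracle: for integer-valued decompositions the shift/add network
        # must reproduce the direct product exactly
        for _ in range(500):
            x = int(rng.integers(-1_000_000, 1_000_000))
            c = int(rng.integers(1, 1023))
            d = csd_decompose(c, max_terms=11, min_exponent=0)
            assert d.value == c
            assert shift_add_scale(x, d, OpTrace()) == x * c


class TestBitWidth:
    def test_published_design_width(self):
        assert bit_width_analysis(-60.0, 10.0, 20) == 28

    def test_minimal_case(self):
        assert bit_width_analysis(-1.0, 1.0, 0) == 2

    def test_monotone_in_range(self):
        widths = [bit_width_analysis(-v, v, 20) for v in (10, 60, 200, 1000)]
        assert widths == sorted(widths)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            bit_width_analysis(5.0, 5.0)


class TestCensus:
    def test_proposed_inventory(self):
        c = resource_census("proposed")
        assert (c.exponential, c.multiplier, c.divider, c.adder, c.subtractor) \
            == (0, 0, 0, 3, 3)

    def test_original_inventory(self):
        c = resource_census("original")
        assert (c.exponential, c.multiplier, c.divider, c.adder, c.subtractor) \
            == (1, 6, 5, 5, 6)

    def test_proposed_has_no_nonlinear_units(self):
        c = resource_census("proposed")
        assert c.exponential == 0 and c.multiplier == 0 and c.divider == 0

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            resource_census("hybrid")


class TestExport:
    FMT = FixedPointFormat(28, 20)

    def test_zero_word(self, tmp_path, tonic):
        lut = build_lut(tonic, n_points=2, ceiling=1.0)
        lut.values[:] = 0.0
        path = tmp_path / "lut.hex"
        export_fixed_lut(lut, self.FMT, path, "hex")
        assert path.read_text().split() == ["0000000", "0000000"]

    def test_minus_one_twos_complement(self, tmp_path, tonic):
        lut = build_lut(tonic, n_points=2, ceiling=1.0)
        lut.values[:] = [-1.0, -1.0]
        path = tmp_path / "lut.hex"
        export_fixed_lut(lut, self.FMT, path, "hex")
        assert path.read_text().split()[0] == "FF00000"

    @pytest.mark.parametrize("dialect", ["hex", "coe"])
    def test_round_trip(self, tmp_path, tonic, dialect):
        fmt = FixedPointFormat(46, 20)
        lut = build_lut(tonic)
        path = tmp_path / f"lut.{dialect}"
        export_fixed_lut(lut, fmt, path, dialect)
        back = import_fixed_lut(path, fmt, dialect)
        assert back == [to_fixed(v, fmt) for v in lut.values]

    def test_overflow_is_an_error(self, tmp_path, tonic):
        lut = build_lut(tonic)  # values reach ~2^21 pA
        with pytest.raises(OverflowError):
            export_fixed_lut(lut, self.FMT, tmp_path / "x.hex", "hex")

    def test_coe_header(self, tmp_path, tonic):
        fmt = FixedPointFormat(46, 20)
        lut = build_lut(tonic)
        path = tmp_path / "lut.coe"
        export_fixed_lut(lut, fmt, path, "coe")
        assert path.read_text().startswith("memory_initialization_radix=16;")


class TestSimulateFixed:
    def test_multiplierless_and_spiking(self):
        trace, ops = simulate_fixed("Tonic spiking", T=100.0)
        assert ops.mul == 0 and ops.div == 0 and ops.exp == 0
        assert ops.lut_read > 0 and ops.shift > 0
        assert len(trace.spike_times) > 3
        assert np.all(np.isfinite(trace.V))

    def test_precision_sweep_approaches_float_model(self):
        # the float N-LUT run with the same (digitized) parameters is the
        # limit of the fixed-point emulation as fraction bits grow
        p = digital_params("Tonic spiking")
        lut = build_lut(p)
        ref = simulate_nlut(p, lut, T=100.0)

        def err(frac):
            fmt = FixedPointFormat(frac + 26, frac)
            tr, _ = simulate_fixed("Tonic spiking", lut=lut, fmt=fmt, T=100.0)
            return np.mean(np.abs(tr.V - ref.V))

        assert err(24) < err(6)

    def test_trace_has_no_saturation_with_default_format(self):
        _, ops = simulate_fixed("Adaptation", T=100.0)
        assert ops.saturations == 0
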