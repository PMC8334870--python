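"""Stream propagation, sizing, yields and batch output."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hatea
from hatea.process import FIXED_YIELDS, VARIABLE_OPS, StreamState, UnitOperation

FIXED_PRODUCT = 0.95 * 0.90 * 0.90 * 0.90 * 0.95  # ops 2,3,5,8,11


def op2_dilution():
    return UnitOperation(
        op_id=2, name="Dilution with water", equipment_kind="stainless_tank",
        recovery_yield=0.95, volume_rule="add_equal_volume",
    )


class TestStreamState:
    def test_mass_derived_from_volume_and_conc(self):
        s = StreamState(100.0, 6.8)
        assert s.ha_mass == pytest.approx(680.0)

    def test_inconsistent_mass_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            StreamState(100.0, 6.8, ha_mass=600.0)

    def test_negative_fields_rejected(self):
        with pytest.raises(ValueError):
            StreamState(-1.0, 1.0)


class TestPropagate:
    def test_dilution_step_hand_arithmetic(self):
        # 1:1 water addition at 95% recovery: 6.8*100*0.95/200 = 3.23 g/L
        out, trace = hatea.propagate(op2_dilution(), StreamState(100.0, 6.8))
        assert out.volume == pytest.approx(200.0)
        assert out.ha_conc == pytest.approx(3.23)
        assert out.ha_mass == pytest.approx(646.0)
        assert trace.mass_out == pytest.approx(646.0)

    def test_identity_operation_changes_nothing(self):
        op = UnitOperation(op_id=2, name="noop", equipment_kind="stainless_tank",
                           recovery_yield=1.0)
        out, _ = hatea.propagate(op, StreamState(50.0, 2.0))
        assert (out.volume, out.ha_conc, out.ha_mass) == (50.0, 2.0, 100.0)

    @pytest.mark.parametrize("rule, kwargs", [
        ("none", {}),
        ("add_equal_volume", {}),
        ("resuspend_to_reference", {}),
        ("concentration_factor", {"concentration_factor": 2.0}),
    ])
    def test_mass_follows_yield_regardless_of_volume_rule(self, rule, kwargs):
        op = UnitOperation(op_id=2, name="x", equipment_kind="stainless_tank",
                           recovery_yield=0.2, volume_rule=rule, **kwargs)
        out, _ = hatea.propagate(op, StreamState(50.0, 2.0), reference_volume=10.0)
        assert out.ha_mass == pytest.approx(20.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            hatea.propagate(op2_dilution(), StreamState(0.0, 1.0))

    @given(
        volume=st.floats(1e-3, 1e4),
        conc=st.floats(1e-6, 100.0),
        recovery=st.floats(0.01, 1.0),
    )
    def test_mass_balance_and_conc_consistency(self, volume, conc, recovery):
        op = UnitOperation(op_id=2, name="x", equipment_kind="stainless_tank",
                           recovery_yield=recovery, volume_rule="add_equal_volume")
        out, _ = hatea.propagate(op, StreamState(volume, conc))
        assert out.ha_mass / (volume * conc) == pytest.approx(recovery)
        assert out.ha_mass == pytest.approx(out.volume * out.ha_conc)


class TestSizing:
    @pytest.mark.parametrize("volume, expected", [(100.0, 100.0), (1000.0, 1000.0),
                                                  (381.0, 381.0)])
    def test_centrifuge_processes_feed_in_one_hour(self, volume, expected):
        assert hatea.centrifuge_flow_rate(volume) == pytest.approx(expected)

    @pytest.mark.parametrize("volume, expected", [(400.0, 100.0), (4.0, 1.0),
                                                  (100.0, 25.0)])
    def test_membrane_area_at_constant_flux(self, volume, expected):
        assert hatea.membrane_area(volume) == pytest.approx(expected)

    def test_invalid_sizing_inputs(self):
        with pytest.raises(ValueError):
            hatea.centrifuge_flow_rate(0.0)
        with pytest.raises(ValueError):
            hatea.membrane_area(10.0, flux=0.0)


class TestOverallYield:
    def test_best_case_is_66_percent(self, endo_train):
        # 0.95*0.90*0.90*0.90*0.95 with all variable yields at 100%
        y = hatea.overall_yield(endo_train, (1.0,) * 5)
        assert y == pytest.approx(0.6579225)
        assert round(100 * y) == 66

    def test_worst_case_is_0_02_percent(self, endo_train):
        y = hatea.overall_yield(endo_train, (0.2,) * 5)
        assert y == pytest.approx(0.6579225 * 0.2**5)
        assert y == pytest.approx(2.105e-4, rel=1e-3)

    def test_doubling_one_yield_doubles_output(self, endo_train):
        lo = hatea.overall_yield(endo_train, (0.5, 0.8, 0.8, 0.8, 0.8))
        hi = hatea.overall_yield(endo_train, (1.0, 0.8, 0.8, 0.8, 0.8))
        assert hi / lo == pytest.approx(2.0)

    def test_matches_bruteforce_product_oracle(self, endo_train):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ys = rng.uniform(0.05, 1.0, size=5)
            expected = FIXED_PRODUCT * math.prod(ys)
            assert hatea.overall_yield(endo_train, ys) == pytest.approx(
                expected, rel=1e-12
            )

    def test_out_of_range_yield_rejected(self, endo_train):
        with pytest.raises(ValueError):
            hatea.overall_yield(endo_train, (0.0, 1.0, 1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            hatea.overall_yield(endo_train, (1.1, 1.0, 1.0, 1.0, 1.0))


class TestRunBatch:
    def test_final_mass_closed_form(self, rec_train):
        # 6.8 g/L * 100 L * 0.6579 ~ 447.4 g
        batch = hatea.run_batch(rec_train, scale=100.0)
        assert batch.final_mass_g == pytest.approx(6.8 * 100 * 0.6579225)
        assert batch.final_mass_g == pytest.approx(447.4, abs=0.05)

    def test_titer_multiplier_is_linear(self, rec_train):
        base = hatea.run_batch(rec_train, scale=100.0)
        tenfold = hatea.run_batch(rec_train, titer_multiplier=10.0, scale=100.0)
        assert tenfold.final_mass_g == pytest.approx(10 * base.final_mass_g)
        assert tenfold.titer_g_per_L == pytest.approx(68.0)

    def test_mass_conservation_at_every_operation(self, endo_train):
        batch = hatea.run_batch(endo_train, variable_yields=(0.8, 0.6, 1.0, 0.4, 0.9))
        for row in batch.trace[1:]:
            assert row.mass_out / row.mass_in == pytest.approx(row.recovery_yield)

    def test_final_mass_invariant_to_volume_rules(self, endo_train):
        """Volume rules reshape the stream but never the product mass."""
        batch = hatea.run_batch(endo_train, variable_yields=(0.7,) * 5)
        expected = (endo_train.titer_g_per_L * endo_train.scale_L
                    * FIXED_PRODUCT * 0.7**5)
        assert batch.final_mass_g == pytest.approx(expected, rel=1e-12)

    def test_volume_trace_follows_rules(self, endo_train):
        batch = hatea.run_batch(endo_train, scale=100.0)
        volumes = {t.op_id: t.volume_out for t in batch.trace}
        assert volumes[2] == 200.0     # 1:1 water
        assert volumes[4] == 400.0     # 1:1 isopropanol
        assert volumes[6] == 100.0     # resuspension to fermentation volume
        assert volumes[10] == 100.0    # 1X concentration factor

    def test_additive_quantities(self, endo_train):
        batch = hatea.run_batch(endo_train, scale=100.0)
        assert batch.isopropanol_L == pytest.approx(200.0)
        assert batch.materials_kg["sodium acetate"] == pytest.approx(3.0)
        assert batch.materials_kg["silica gel"] == pytest.approx(3.0)
        assert batch.diafiltration_buffer_L == pytest.approx(500.0)

    @given(st.integers(0, 4), st.floats(0.21, 1.0))
    def test_monotone_in_each_variable_yield(self, endo_train, idx, y):
        base = [0.6] * 5
        bumped = list(base)
        bumped[idx] = max(y, base[idx] + 0.01)
        low = hatea.run_batch(endo_train, variable_yields=base).final_mass_g
        high = hatea.run_batch(endo_train, variable_yields=bumped).final_mass_g
        assert high > low

    def test_batch_duration_ferm_plus_10h(self, endo_train, rec_train):
        assert hatea.run_batch(endo_train).batch_duration_h == pytest.approx(30.0)
        assert hatea.run_batch(rec_train).batch_duration_h == pytest.approx(58.0)
        stretched = hatea.run_batch(endo_train, time_multiplier=2.0)
        assert stretched.batch_duration_h == pytest.approx(60.0)

    def test_trace_frame_schema(self, endo_train):
        frame = hatea.run_batch(endo_train).trace_frame()
        assert len(frame) == 11
        assert {"op_id", "volume_in", "volume_out", "conc_out", "mass_out",
                "recovery_yield", "flow_rate_L_per_h",
                "membrane_area_m2"} <= set(frame.columns)


class TestAnnualProduction:
    def test_24h_batch_gives_one_batch_per_operating_day(self):
        assert hatea.batches_per_year(24.0, operating_days=200) == 200

    def test_linear_in_batch_mass(self):
        one = hatea.annual_production(100.0, 30.0)
        two = hatea.annual_production(200.0, 30.0)
        assert two == pytest.approx(2 * one)

    def test_slow_large_batch_vs_fast_small_batch(self, fixtures):
        """Higher titer with a longer fermentation wins per batch but loses
        per year (fermentation-only comparison of options 1 and 2)."""
        opt1, opt2 = fixtures.option(1), fixtures.option(2)
        scale = 100.0
        batch1, batch2 = opt1.titer_g_per_L * scale, opt2.titer_g_per_L * scale
        annual1 = hatea.annual_production(batch1, opt1.duration_h)
        annual2 = hatea.annual_production(batch2, opt2.duration_h)
        assert batch1 > batch2
        assert annual1 < annual2

    def test_train_structure_invariants(self, endo_train):
        variable = tuple(op.op_id for op in endo_train.operations
                         if op.yield_class == "variable")
        assert variable == VARIABLE_OPS
        fixed = {op.op_id: op.recovery_yield for op in endo_train.operations
                 if op.yield_class == "fixed"}
        assert fixed == FIXED_YIELDS
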