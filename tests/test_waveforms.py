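"""Cardiac-cycle waveform generator: anchors, invariants, CSV round trip."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from lvmech import (
    ActiveElastanceRule,
    CycleSpec,
    active_modulus,
    build_reference_cycle_spec,
    generate_cycle,
    load_cycle_csv,
)
from lvmech.waveforms import WaveformError
from dataclasses import replace


@pytest.fixture(scope="module")
def ref_cycle():
    return generate_cycle(build_reference_cycle_spec())


class TestReferenceSpec:
    def test_printed_anchor_values(self):
        spec = build_reference_cycle_spec()
        assert spec.edv == 130.0
        assert spec.esv == 50.0
        assert spec.v_start == 110.0
        assert spec.p_peak == 16.93
        assert spec.phase_times[1] == 0.21
        assert spec.phase_times == (0.1, 0.21, 0.3, 0.43, 0.5, 0.65, 0.8)
        assert spec.cycle_length == 0.8

    def test_stroke_volume_is_80_ml(self, ref_cycle):
        sv = ref_cycle.v_target.max() - ref_cycle.v_target.min()
        assert sv == pytest.approx(80.0, abs=1e-12)

    def test_isovolumic_phases_exactly_constant(self, ref_cycle):
        t, v = ref_cycle.t, ref_cycle.v_target
        ivc = (t >= 0.1) & (t <= 0.21)
        ivr = (t >= 0.43) & (t <= 0.5)
        assert np.ptp(v[ivc]) == 0.0
        assert np.ptp(v[ivr]) == 0.0
        assert v[ivc][0] == 130.0
        assert v[ivr][0] == 50.0

    def test_volume_monotone_within_each_phase(self, ref_cycle):
        spec = ref_cycle.spec
        bounds = np.concatenate([[0.0], spec.phase_times])
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = ref_cycle.v_target[(ref_cycle.t >= a) & (ref_cycle.t <= b)]
            d = np.diff(seg)
            assert np.all(d >= -1e-12) or np.all(d <= 1e-12)

    def test_pressure_peak_attained(self, ref_cycle):
        assert ref_cycle.p.max() == pytest.approx(16.93, abs=1e-12)

    def test_doubling_samples_reproduces_anchors(self):
        c1 = generate_cycle(build_reference_cycle_spec(41))
        c2 = generate_cycle(build_reference_cycle_spec(81))
        for c in (c1, c2):
            assert c.v_target.max() == pytest.approx(130.0, abs=1e-12)
            assert c.v_target.min() == pytest.approx(50.0, abs=1e-12)
            assert c.p.max() == pytest.approx(16.93, abs=1e-12)


class TestActiveElastance:
    def test_reference_constant_is_29_5(self):
        rule = ActiveElastanceRule.for_peak_pressure(16.93)
        assert rule.c_act == pytest.approx(29.5, abs=0.05)  # 3 s.f.

    def test_proportionality_through_origin(self):
        rule = ActiveElastanceRule.for_peak_pressure(16.93)
        assert active_modulus(0.0, rule) == 0.0
        # half of peak pressure maps to exactly half the modulus cap
        assert active_modulus(16.93 / 2, rule) == pytest.approx(250.0, abs=1e-9)

    def test_modulus_capped_at_500_kPa(self, ref_cycle):
        assert ref_cycle.e_active.max() <= 500.0 + 1e-9
        assert ref_cycle.e_active.max() == pytest.approx(
            ref_cycle.rule.c_act * ref_cycle.p.max()
        )

    def test_zero_pressure_gives_zero_schedule(self):
        spec = replace(
            build_reference_cycle_spec(),
            p_peak=16.93,
            p_anchors=tuple([0.0] * 8),
        )
        cycle = generate_cycle(spec)
        assert np.all(cycle.e_active == 0.0)

    def test_negative_pressure_rejected(self):
        with pytest.raises(WaveformError):
            active_modulus(-1.0, ActiveElastanceRule())


class TestValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"esv": 140.0},                       # esv >= edv
            {"v_start": 131.0},                   # v_start > edv
            {"p_peak": -1.0},
            {"phase_times": (0.1, 0.05, 0.3, 0.43, 0.5, 0.65, 0.8)},
            {"phase_times": (0.1, 0.21, 0.3, 0.43, 0.5, 0.65, 0.7)},
            {"n_samples": 3},
        ],
    )
    def test_inconsistent_anchors_rejected(self, bad):
        spec = replace(build_reference_cycle_spec(), **bad)
        with pytest.raises(WaveformError):
            generate_cycle(spec)

    @hyp_settings(max_examples=30, deadline=None)
    @given(
        edv=st.floats(90, 200),
        frac=st.floats(0.2, 0.8),
        n=st.integers(20, 101),
    )
    def test_generated_cycles_honour_anchor_invariants(self, edv, frac, n):
        esv = frac * edv
        spec = replace(build_reference_cycle_spec(), edv=edv, esv=esv,
                       v_start=0.9 * edv, n_samples=n)
        cycle = generate_cycle(spec)
        assert cycle.v_target.max() == pytest.approx(edv, rel=1e-12)
        assert cycle.v_target.min() == pytest.approx(esv, rel=1e-12)
        assert np.all(cycle.v_target > 0)
        assert cycle.e_active.max() == pytest.approx(
            cycle.rule.c_act * cycle.p.max()
        )


class TestCsvIO:
    def test_round_trip(self, ref_cycle, tmp_path):
        path = tmp_path / "cycle.csv"
        ref_cycle.to_csv(path)
        loaded = load_cycle_csv(path, p_peak=16.93)
        np.testing.assert_allclose(loaded.t, ref_cycle.t)
        np.testing.assert_allclose(loaded.p, ref_cycle.p)
        np.testing.assert_allclose(loaded.v_target, ref_cycle.v_target)
        np.testing.assert_allclose(loaded.e_active, ref_cycle.e_active, rtol=1e-12)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"t_s": [0, 1], "p_kPa": [0, 1]}).to_csv(path, index=False)
        with pytest.raises(WaveformError):
            load_cycle_csv(path)

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"t_s": [0.0, 0.2, 0.1], "p_kPa": [1, 1, 1], "v_ml": [50, 60, 70]}
        ).to_csv(path, index=False)
        with pytest.raises(WaveformError):
            load_cycle_csv(path)

    def test_negative_volume_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"t_s": [0.0, 0.1], "p_kPa": [1, 1], "v_ml": [50, -1]}
        ).to_csv(path, index=False)
        with pytest.raises(WaveformError):
            load_cycle_csv(path)
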