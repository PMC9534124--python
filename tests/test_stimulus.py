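"""Temporal-profile properties of the eight hybrid stimuli."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssvepkit.errors import ConfigurationError
from ssvepkit.stimulus import (
    BaseKind,
    MotionWaveform,
    StimulusSpec,
    binary_state,
    enumerate_stimuli,
    motion_frequency,
    render_frame_table,
    size_profile,
)


def spec(kind="FS", wave="none", f=6.0, **kw):
    return StimulusSpec(
        base_kind=kind, motion_waveform=wave, stim_frequency_hz=f, **kw
    )


@pytest.mark.parametrize(
    "kind, f, expected",
    [("FS", 6.0, 6.0), ("PRS", 6.0, 3.0), ("PRS", 10.0, 5.0), ("FS", 7.5, 7.5)],
)
def test_motion_runs_at_half_rate_for_pattern_reversal(kind, f, expected):
    assert motion_frequency(spec(kind, f=f)) == expected


class TestSizeProfile:
    def test_no_motion_is_constant_base_size(self):
        t = np.linspace(0, 2, 300)
        assert np.all(size_profile("none", 3.0, 0.33, t) == 1.0)

    def test_square_alternates_between_extremes(self):
        # high half-period then low half-period, 1.33 / 0.67 at r = 0.33
        f_m = 3.0
        high = size_profile("square", f_m, 0.33, np.array([0.0, 0.1]))
        low = size_profile("square", f_m, 0.33, np.array([1 / 6 + 0.01, 0.3]))
        assert np.allclose(high, 1.33)
        assert np.allclose(low, 0.67)

    def test_sine_starts_at_base_and_is_mean_one(self):
        f_m = 3.0
        assert size_profile("sine", f_m, 0.33, 0.0) == pytest.approx(1.0)
        t = np.arange(3000) / 3000 / f_m  # one period
        assert size_profile("sine", f_m, 0.33, t).mean() == pytest.approx(1.0, abs=1e-6)

    def test_triangular_ramps_between_extremes(self):
        f_m = 2.0
        vals = size_profile(
            "triangular", f_m, 0.33, np.array([0.0, 0.125, 0.25, 0.375])
        )
        assert vals == pytest.approx([0.67, 1.0, 1.33, 1.0])

    @pytest.mark.parametrize("wave", ["square", "triangular", "sine"])
    def test_periodic_profiles_attain_exact_extremes(self, wave):
        f_m, r = 3.0, 0.33
        t = np.linspace(0, 1 / f_m, 2001)
        vals = size_profile(wave, f_m, r, t)
        assert vals.max() == pytest.approx(1 + r, abs=1e-9)
        assert vals.min() == pytest.approx(1 - r, abs=1e-9)

    def test_rejects_bad_waveform_and_ratio(self):
        with pytest.raises(ValueError):
            size_profile("sawtooth", 3.0, 0.33, 0.0)
        with pytest.raises(ConfigurationError):
            size_profile("sine", 3.0, 1.5, 0.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        wave=st.sampled_from(["square", "triangular", "sine"]),
        f_m=st.floats(0.5, 10.0),
        r=st.floats(0.05, 0.95),
        t=st.floats(0.0, 100.0),
    )
    def test_profile_bounded_and_periodic(self, wave, f_m, r, t):
        v = float(size_profile(wave, f_m, r, t))
        assert 1 - r - 1e-9 <= v <= 1 + r + 1e-9
        v_shift = float(size_profile(wave, f_m, r, t + 1.0 / f_m))
        assert v_shift == pytest.approx(v, abs=1e-6)


class TestBinaryState:
    def test_flicker_full_cycle_at_f(self):
        s = spec("FS", f=6.0)
        assert binary_state(s, 0.0) == 1
        assert binary_state(s, 1 / 12 - 1e-6) == 1
        assert binary_state(s, 1 / 12 + 1e-6) == 0
        assert binary_state(s, 2 / 12 + 1e-6) == 1

    def test_pattern_reversal_toggles_at_f(self):
        s = spec("PRS", f=6.0)
        assert binary_state(s, 0.05) == 1  # within [0, 1/6)
        assert binary_state(s, 1 / 6 + 0.01) == 0
        assert binary_state(s, 2 / 6 + 0.01) == 1

    def test_periodicity(self):
        s = spec("FS", f=6.0)
        t0 = 0.04
        assert binary_state(s, t0) == binary_state(s, t0 + 1 / 6)

    @pytest.mark.parametrize(
        "kind, f, expected_transitions", [("FS", 6.0, 12), ("PRS", 6.0, 6), ("FS", 10.0, 20)]
    )
    def test_transition_counts_per_second(self, kind, f, expected_transitions):
        # count on a fine grid over exactly 1 s (integer number of periods),
        # endpoint included so the wrap-around transition is counted
        t = np.linspace(0.0, 1.0, 10001)
        states = binary_state(spec(kind, f=f), t)
        assert int(np.sum(np.abs(np.diff(states)))) == expected_transitions


class TestFrameTable:
    def test_flicker_period_in_frames(self):
        table = render_frame_table(spec("FS", "none", 6.0), 1.0)
        assert len(table) == 60
        assert np.all(table.relative_radius == 1.0)
        # 60 Hz refresh / 6 Hz flicker = 10-frame state period
        assert np.array_equal(table.binary_state[:-10], table.binary_state[10:])

    def test_prs_square_motion_period_is_twenty_frames(self):
        table = render_frame_table(spec("PRS", "square", 6.0), 1.0)
        r = table.relative_radius
        assert np.array_equal(r[:-20], r[20:])  # motion at 3 Hz -> 20 frames
        assert set(np.round(r, 2)) == {0.67, 1.33}

    def test_frame_count_floor(self):
        assert len(render_frame_table(spec("FS", "sine", 7.5), 0.5)) == 30

    def test_exact_periodicity_at_commensurate_frequencies(self):
        for f in (6.0, 7.5, 10.0):
            table = render_frame_table(spec("FS", "sine", f), 2.0)
            period = int(round(60 / f))
            assert np.allclose(
                table.relative_radius[:-period], table.relative_radius[period:]
            )


class TestEnumerateStimuli:
    def test_eight_stimuli_in_canonical_order(self):
        specs = enumerate_stimuli(6.0)
        assert len(specs) == 8
        assert specs[0].base_kind is BaseKind.FS
        assert specs[0].motion_waveform is MotionWaveform.NONE
        assert [s.name for s in specs[:4]] == [
            "FS-None", "FS-Square", "FS-Triangular", "FS-Sine",
        ]
        assert specs[4].base_kind is BaseKind.PRS

    def test_same_layout_at_different_frequencies(self):
        a, b = enumerate_stimuli(6.0), enumerate_stimuli(10.0)
        assert [(s.base_kind, s.motion_waveform) for s in a] == [
            (s.base_kind, s.motion_waveform) for s in b
        ]
        assert all(s.stim_frequency_hz == 10.0 for s in b)


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        spec("FS", f=40.0)  # above half the 60 Hz refresh
    with pytest.raises(ConfigurationError):
        StimulusSpec("FS", "none", 6.0, modulation_ratio=1.2)
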