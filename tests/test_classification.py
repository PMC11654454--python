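"""Sustained amplitude, switch threshold, oscillation statistics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from entrace import (
    ClassificationError,
    ClassificationParams,
    GeneratorConfig,
    ParameterError,
    TraceField,
    classify_cells,
    classify_field,
    decompose_field,
    detect_oscillations,
    oscillation_change,
    simulate_field,
    sustained_amplitude,
)
from entrace.decomposition import DecomposedTrace


def fake_decomposed(slow, fast=None):
    slow = np.asarray(slow, dtype=float)
    fast = np.ones_like(slow) if fast is None else np.asarray(fast, dtype=float)
    return DecomposedTrace(raw=slow * fast, slow=slow, fast=fast,
                           converged=True, iterations_used=1)


TIME = np.arange(1800) / 5.0  # 360 s at 5 Hz


class TestSustainedAmplitude:
    def test_flat_slow_component_has_zero_amplitude(self):
        d = fake_decomposed(np.ones_like(TIME))
        assert sustained_amplitude(d, TIME) == pytest.approx(0.0)

    def test_step_to_plateau_gives_plateau_height(self):
        slow = np.where(TIME < 180, 1.0, 1.5)
        d = fake_decomposed(slow)
        assert sustained_amplitude(d, TIME) == pytest.approx(0.5)

    def test_downward_drift_gives_negative_amplitude(self):
        d = fake_decomposed(np.linspace(1.2, 0.8, TIME.size))
        assert sustained_amplitude(d, TIME) < 0

    def test_overlapping_windows_rejected(self):
        d = fake_decomposed(np.ones(100))
        t = np.arange(100) / 5.0  # 20 s recording
        with pytest.raises(ParameterError):
            sustained_amplitude(d, t, ClassificationParams(
                tail_window_s=15, baseline_window_s=15))

    def test_recovers_generative_amplitude_noiseless(self):
        cfg = GeneratorConfig(
            n_cells=1, noise_sd=0.0, osc_rate_max_hz=0.0, switch_prob=0.0,
            slow_amp_max=0.8, slow_amp_sigma=0.0, concentration_nmol=1000.0,
            slow_onset_sd_s=0.0, seed=8,
        )
        field, truth = simulate_field(cfg)
        decomposed, _ = decompose_field(field)
        amp = sustained_amplitude(decomposed[0], field.time_s)
        assert abs(amp - truth.cells[0].true_slow_amplitude) < 0.05


class TestClassifyField:
    def test_equal_amplitudes_give_no_switched_cells(self):
        flags, s = classify_field(np.full(6, 0.7))
        assert not flags.any()
        assert s.pct_switched == 0.0
        assert s.threshold == pytest.approx(0.7)

    def test_worked_example_one_outlier_in_five(self):
        # mean 0.4, SD sqrt(0.8), SEM 0.4 -> threshold 1.6; one cell above
        flags, s = classify_field(np.array([0.0, 0.0, 0.0, 0.0, 2.0]))
        assert s.mean_amplitude == pytest.approx(0.4)
        assert s.sem_amplitude == pytest.approx(0.4)
        assert s.threshold == pytest.approx(1.6)
        assert flags.sum() == 1
        assert s.pct_switched == pytest.approx(20.0)

    def test_single_cell_rejected(self):
        with pytest.raises(ClassificationError):
            classify_field(np.array([1.0]))

    def test_sem_only_mode(self):
        _, s = classify_field(
            np.array([0.0, 0.0, 0.0, 0.0, 2.0]),
            ClassificationParams(threshold_mode="sem_only"),
        )
        assert s.threshold == pytest.approx(1.2)

    @given(
        amps=hnp.arrays(float, st.integers(3, 30),
                        elements=st.floats(-2, 4, allow_nan=False)),
        shift=st.floats(-5, 5, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_threshold_shifts_with_constant_offset_flags_unchanged(self, amps, shift):
        f0, s0 = classify_field(amps)
        f1, s1 = classify_field(amps + shift)
        assert s1.threshold == pytest.approx(s0.threshold + shift, abs=1e-9)
        # flags can only legitimately differ for cells sitting at the
        # threshold to within float rounding of the shifted comparison
        clear = np.abs(amps - s0.threshold) > 1e-9 * max(1.0, abs(shift))
        assert (f0[clear] == f1[clear]).all()

    def test_pct_switched_invariant_under_reordering(self, rng):
        amps = rng.normal(1.0, 0.5, 40)
        _, a = classify_field(amps)
        _, b = classify_field(rng.permutation(amps))
        assert a.pct_switched == b.pct_switched

    def test_zero_multiplier_threshold_is_the_mean(self, rng):
        amps = rng.normal(1.0, 0.5, 25)
        _, s = classify_field(amps, ClassificationParams(sem_multiplier=0.0))
        assert s.threshold == pytest.approx(amps.mean())

    def test_huge_multiplier_switches_nobody(self, rng):
        amps = rng.normal(1.0, 0.5, 25)
        _, s = classify_field(amps, ClassificationParams(sem_multiplier=1e9))
        assert s.pct_switched == 0.0


class TestDetectOscillations:
    def test_quiescent_cell_has_no_events(self):
        times, proms = detect_oscillations(np.ones_like(TIME), TIME)
        assert times.size == 0 and proms.size == 0

    def test_five_clear_spikes_detected(self):
        fast = np.ones_like(TIME)
        for te in (30, 90, 150, 210, 300):
            m = TIME >= te
            fast[m] += 0.5 * np.exp(-(TIME[m] - te) / 1.2)
        times, _ = detect_oscillations(
            fast, TIME, ClassificationParams(peak_min_prominence=0.2))
        assert times.size == 5

    def test_subthreshold_spikes_ignored(self):
        fast = np.ones_like(TIME)
        fast[500] += 0.05
        times, _ = detect_oscillations(
            fast, TIME, ClassificationParams(peak_min_prominence=0.1))
        assert times.size == 0


class TestOscillationChange:
    def test_no_post_switch_events_gives_zero_frequency(self):
        slow = np.where(TIME < 180, 1.0, 2.0)
        d = fake_decomposed(slow)
        ts, n_pre, n_post, f_pre, f_post = oscillation_change(
            d, TIME, np.array([30.0, 60.0, 90.0]), amplitude=1.0)
        assert ts == pytest.approx(180.0, abs=0.5)
        assert n_pre == 3 and n_post == 0
        assert f_pre == pytest.approx(3 / ts)
        assert f_post == 0.0

    def test_refuses_when_slow_never_crosses_level(self):
        d = fake_decomposed(np.ones_like(TIME))
        with pytest.raises(ClassificationError):
            oscillation_change(d, TIME, np.array([10.0]), amplitude=1.0)


class TestWholeFieldAverage:
    def test_identical_traces_have_zero_sem(self):
        tf = TraceField(time_s=TIME, traces=np.tile(np.linspace(1, 2, TIME.size), (4, 1)))
        mean, sem = tf.whole_field_average()
        np.testing.assert_allclose(sem, 0.0)
        np.testing.assert_allclose(mean, np.linspace(1, 2, TIME.size))

    def test_two_constant_traces_mean_and_sem(self):
        tf = TraceField(time_s=TIME, traces=np.vstack([np.ones_like(TIME),
                                                       2 * np.ones_like(TIME)]))
        mean, sem = tf.whole_field_average()
        np.testing.assert_allclose(mean, 1.5)
        np.testing.assert_allclose(sem, 0.5)  # SD sqrt(0.5), /sqrt(2)


def test_classify_cells_end_to_end_counts():
    cfg = GeneratorConfig(n_cells=30, seed=77)
    field, _ = simulate_field(cfg)
    decomposed, _ = decompose_field(field)
    cells, summary = classify_cells(decomposed, field.time_s)
    assert len(cells) == 30
    assert summary.n_cells == 30
    switched = [c for c in cells if c.switched]
    assert summary.pct_switched == pytest.approx(100 * len(switched) / 30)
    for c in switched:
        assert c.switch_time_s is not None
    for c in cells:
        if not c.switched:
            assert c.switch_time_s is None
            assert c.osc_freq_post_hz is None
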