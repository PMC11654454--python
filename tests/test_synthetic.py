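"""Generator contracts: determinism, component algebra, dose behaviour."""
import dataclasses

import numpy as np
import pytest

from entrace import (
    EmptyFieldError,
    GeneratorConfig,
    LayoutError,
    MovieGeometry,
    ParameterError,
    PRESETS,
    hill,
    render_movie,
    simulate_cell,
    simulate_field,
)
from entrace.synthetic import true_fast_curve, true_slow_curve


def quiet_config(**kw):
    base = dict(n_cells=4, duration_s=60.0, noise_sd=0.0, seed=7)
    base.update(kw)
    return GeneratorConfig(**base)


class TestSimulateCell:
    def test_all_components_off_gives_flat_unit_trace(self):
        cfg = quiet_config(osc_rate_max_hz=0.0, slow_amp_max=0.0, switch_prob=0.0)
        trace, truth = simulate_cell(cfg, np.random.default_rng(0))
        assert trace.shape == (cfg.n_samples,)
        np.testing.assert_allclose(trace, 1.0)
        assert truth.osc_event_times_s.size == 0

    def test_saturating_concentration_plateaus_at_one_plus_amp(self):
        # logistic saturates at 1 + A once t - t0 >> tau
        cfg = quiet_config(
            duration_s=400.0,
            osc_rate_max_hz=0.0,
            slow_amp_max=0.5,
            slow_amp_sigma=0.0,
            switch_prob=0.0,
            concentration_nmol=5000.0,
            slow_onset_mean_s=50.0,
            slow_onset_sd_s=0.0,
            slow_tau_s=10.0,
        )
        trace, _ = simulate_cell(cfg, np.random.default_rng(0))
        assert abs(trace[-1] - 1.5) < 0.015

    def test_fixed_seed_is_bit_identical(self):
        cfg = GeneratorConfig(seed=3)
        a, _ = simulate_cell(cfg, np.random.default_rng(123))
        b, _ = simulate_cell(cfg, np.random.default_rng(123))
        np.testing.assert_array_equal(a, b)

    def test_trace_is_strictly_positive(self):
        cfg = GeneratorConfig(noise_sd=0.1, seed=5)
        trace, _ = simulate_cell(cfg, np.random.default_rng(9))
        assert (trace > 0).all()

    def test_noiseless_trace_equals_slow_times_fast_exactly(self):
        cfg = quiet_config(duration_s=120.0)
        trace, truth = simulate_cell(cfg, np.random.default_rng(11))
        z = true_slow_curve(truth, cfg)
        r = true_fast_curve(truth, cfg)
        np.testing.assert_allclose(trace, z * r, rtol=1e-12)

    def test_non_finite_parameter_rejected(self):
        with pytest.raises(ParameterError):
            GeneratorConfig(slow_amp_max=float("nan"))
        with pytest.raises(ParameterError):
            GeneratorConfig(noise_sd=float("inf"))

    @pytest.mark.parametrize(
        "kw",
        [
            {"switch_prob": 1.5},
            {"frame_rate_hz": 0.0},
            {"duration_s": -1.0},
            {"switch_amp_multiplier": 0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ParameterError):
            GeneratorConfig(**kw)


class TestSimulateField:
    def test_empty_field_raises(self):
        with pytest.raises(EmptyFieldError):
            simulate_field(quiet_config(n_cells=0))

    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_switch_probability(self, p, expected):
        _, truth = simulate_field(quiet_config(switch_prob=p))
        assert truth.true_switched_fraction == expected

    def test_switched_fraction_matches_mean_of_flags(self, small_field):
        _, truth = small_field
        assert truth.true_switched_fraction == pytest.approx(truth.is_switcher.mean())

    def test_switcher_count_is_binomial_across_seeds(self):
        # Monte-Carlo check against the binomial expectation: mean switcher
        # fraction over 200 independent fields of 100 cells within 0.02 of 0.4
        fracs = []
        for seed in range(200):
            cfg = GeneratorConfig(
                n_cells=100, duration_s=2.0, osc_rate_max_hz=0.0, noise_sd=0.0,
                switch_prob=0.4, seed=seed,
            )
            _, truth = simulate_field(cfg)
            fracs.append(truth.true_switched_fraction)
        assert abs(np.mean(fracs) - 0.4) < 0.02

    def test_event_times_sorted_within_duration(self, small_field):
        field, truth = small_field
        for cell in truth.cells:
            t = cell.osc_event_times_s
            assert (np.diff(t) > 0).all() if t.size > 1 else True
            assert ((t >= 0) & (t <= field.time_s[-1] + 1)).all()

    def test_expected_slow_amplitude_nondecreasing_in_concentration(self):
        means = []
        for conc in (1.0, 3.0, 10.0, 30.0, 100.0):
            cfg = GeneratorConfig(
                n_cells=50, duration_s=2.0, osc_rate_max_hz=0.0, noise_sd=0.0,
                slow_amp_sigma=0.0, switch_prob=0.0, concentration_nmol=conc, seed=1,
            )
            _, truth = simulate_field(cfg)
            means.append(np.mean([c.true_slow_amplitude for c in truth.cells]))
        assert (np.diff(means) >= 0).all()

    def test_preset_contrast_in_switched_fraction(self):
        fracs = {}
        for name in PRESETS:
            cfg = GeneratorConfig(
                n_cells=300, duration_s=2.0, osc_rate_max_hz=0.0, noise_sd=0.0,
                concentration_nmol=100.0, seed=5,
            )
            _, truth = simulate_field(cfg, PRESETS[name])
            fracs[name] = truth.true_switched_fraction
        assert fracs["hypertensive-like"] > fracs["normotensive-like"]

    def test_hypertensive_preset_overrides_are_larger(self):
        n = PRESETS["normotensive-like"].overrides
        h = PRESETS["hypertensive-like"].overrides
        assert h["switch_prob"] > n["switch_prob"]
        assert h["slow_amp_max"] > n["slow_amp_max"]


class TestHill:
    def test_limits(self):
        assert hill(0.0, 5.0, 2.0) == 0.0
        assert hill(5.0, 5.0, 2.0) == pytest.approx(0.5)
        assert hill(5e6, 5.0, 2.0) == pytest.approx(1.0, abs=1e-6)


class TestRenderMovie:
    def test_single_cell_constant_trace_gives_identical_frames(self):
        cfg = quiet_config(n_cells=1, osc_rate_max_hz=0.0, slow_amp_max=0.0,
                           duration_s=2.0)
        field, _ = simulate_field(cfg)
        stack, label = render_movie(field, MovieGeometry(shape=(32, 32)))
        assert stack.shape[0] == field.n_samples
        np.testing.assert_array_equal(stack[0], stack[-1])
        assert label.max() == 1

    def test_grid_of_cells_recovers_traces_from_footprints(self):
        cfg = quiet_config(n_cells=12, duration_s=30.0)
        field, _ = simulate_field(cfg)
        geom = MovieGeometry(shape=(96, 128), background=0.0, gain=50.0)
        stack, label = render_movie(field, geom)
        for k in range(12):
            roi_mean = stack[:, label == k + 1].mean(axis=1)
            np.testing.assert_allclose(roi_mean / geom.gain, field.traces[k], rtol=1e-12)

    def test_zero_background_empty_footprints_are_zero(self):
        cfg = quiet_config(n_cells=1, duration_s=2.0)
        field, _ = simulate_field(cfg)
        stack, label = render_movie(field, MovieGeometry(shape=(48, 48), background=0.0))
        assert (stack[:, label == 0] == 0).all()

    def test_canvas_too_small_raises(self):
        field, _ = simulate_field(quiet_config(n_cells=50, duration_s=2.0))
        with pytest.raises(LayoutError):
            render_movie(field, MovieGeometry(shape=(32, 32)))

    def test_poisson_rendering_is_seeded(self):
        field, _ = simulate_field(quiet_config(n_cells=2, duration_s=2.0))
        geom = MovieGeometry(shape=(48, 48), photon_scale=5.0)
        a, _ = render_movie(field, geom, seed=1)
        b, _ = render_movie(field, geom, seed=1)
        np.testing.assert_array_equal(a, b)


def test_field_determinism_is_bit_identical():
    cfg = GeneratorConfig(n_cells=6, seed=99)
    fa, ta = simulate_field(cfg, PRESETS["hypertensive-like"])
    fb, tb = simulate_field(cfg, PRESETS["hypertensive-like"])
    np.testing.assert_array_equal(fa.traces, fb.traces)
    assert ta.true_switched_fraction == tb.true_switched_fraction


def test_preset_application_does_not_mutate_config():
    cfg = GeneratorConfig(n_cells=2, duration_s=2.0, seed=0)
    before = dataclasses.asdict(cfg)
    simulate_field(cfg, PRESETS["hypertensive-like"])
    assert dataclasses.asdict(cfg) == before
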