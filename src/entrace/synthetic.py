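"""Synthetic endothelial Ca2+ field generator.

Real recordings of agonist-stimulated endothelium show, in every cell, two
superimposed signal components: a slow sustained F/F0 rise produced by
plasma-membrane Ca2+ influx and a train of fast transients produced by
repetitive store release.  The generator emulates exactly that structure so
each downstream stage (decomposition, classification, population summaries)
can be tested against known ground truth.

Generative model (per cell, noiseless):

    y(t) = z(t) * r(t) * b(t)

    z(t) = 1 + A * logistic((t - t0) / tau)        sustained influx
    r(t) = 1 + sum_i a_i * g(t - t_i)              oscillatory release
    b(t) = exp(-bleach_rate * t)                   photobleaching

where ``g`` is a unit-peak bi-exponential transient (fast rise, slower
decay), event times ``t_i`` follow a Poisson process, and ``A`` is set by a
Hill function of agonist concentration.  A Bernoulli-chosen subpopulation of
"switcher" cells has its sustained amplitude multiplied by
``switch_amp_multiplier`` and its post-switch oscillation rate multiplied by
``post_switch_osc_suppression``, emulating the transition from oscillatory
release to dominant sustained influx.  Multiplicative Gaussian noise is
added last, so with ``noise_sd = 0`` the trace equals ``z * r * b`` exactly
and the decomposition has an exact target.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import EmptyFieldError, LayoutError, ParameterError
from .traces import TraceField

__all__ = [
    "GeneratorConfig",
    "CellTruth",
    "SyntheticGroundTruth",
    "StrainPreset",
    "PRESETS",
    "MovieGeometry",
    "hill",
    "simulate_cell",
    "simulate_field",
    "render_movie",
]


def hill(concentration: float, ec50: float, coefficient: float) -> float:
    """Fractional occupancy ``c^h / (c^h + ec50^h)`` (0 at c=0, ->1 at c>>ec50)."""
    if concentration <= 0:
        return 0.0
    ch = concentration**coefficient
    return ch / (ch + ec50**coefficient)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated field.

    Defaults describe a 6-minute wide-field recording at 5 frames/s of an
    en-face endothelial field responding to a saturating agonist dose:
    sustained influx developing over ~2 min (onset 120 +/- 20 s, tau 25 s,
    plateau amplitude up to 1 F/F0 unit at saturation, EC50 5 nmol/L), and
    sparse sharp oscillations (<= ~2.5 events/min, amplitude 0.3 +/- 0.1
    F/F0, 0.3 s rise / 1.2 s decay, EC50 3 nmol/L).  One cell in five is a
    switcher whose sustained amplitude is tripled and whose oscillations are
    suppressed tenfold after the switch.
    """

    n_cells: int = 200
    duration_s: float = 360.0
    frame_rate_hz: float = 5.0
    concentration_nmol: float = 30.0
    # slow sustained (influx) component
    slow_amp_max: float = 1.0
    slow_ec50_nmol: float = 5.0
    slow_hill: float = 2.0
    slow_amp_sigma: float = 0.15  # lognormal cell-to-cell spread of A
    slow_onset_mean_s: float = 120.0
    slow_onset_sd_s: float = 20.0
    slow_tau_s: float = 25.0
    # fast oscillatory (release) component
    osc_rate_max_hz: float = 0.04
    osc_ec50_nmol: float = 3.0
    osc_amp_mean: float = 0.3
    osc_amp_sd: float = 0.1
    osc_amp_min: float = 0.05  # truncation floor for event amplitudes
    osc_rise_s: float = 0.3
    osc_decay_s: float = 1.2
    # switching subpopulation
    switch_prob: float = 0.2
    switch_amp_multiplier: float = 3.0
    post_switch_osc_suppression: float = 0.1
    # nuisance processes
    noise_sd: float = 0.02
    bleach_rate_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ParameterError(f"{f.name} must be finite, got {v!r}")
        nonneg = (
            "duration_s slow_amp_max slow_ec50_nmol slow_hill slow_amp_sigma "
            "slow_onset_mean_s slow_onset_sd_s slow_tau_s osc_rate_max_hz "
            "osc_ec50_nmol osc_amp_mean osc_amp_sd osc_amp_min osc_rise_s "
            "osc_decay_s switch_amp_multiplier noise_sd bleach_rate_per_s"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("switch_prob", "post_switch_osc_suppression"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        if self.switch_amp_multiplier < 1:
            raise ParameterError("switch_amp_multiplier must be >= 1")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be nonnegative")
        if 0 < self.osc_rise_s and self.osc_rise_s >= self.osc_decay_s > 0:
            raise ParameterError("osc_rise_s must be < osc_decay_s")

    @property
    def n_samples(self) -> int:
        return int(self.duration_s * self.frame_rate_hz)

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.frame_rate_hz


@dataclass
class CellTruth:
    """Generative ground truth for one cell."""

    is_switcher: bool
    true_slow_amplitude: float
    true_switch_time_s: float | None
    osc_event_times_s: np.ndarray
    osc_event_amplitudes: np.ndarray
    slow_onset_s: float = float("nan")


@dataclass
class SyntheticGroundTruth:
    """Per-cell ground truth for a whole field, aligned by cell index."""

    cells: list[CellTruth]

    @property
    def true_switched_fraction(self) -> float:
        if not self.cells:
            return 0.0
        return float(np.mean([c.is_switcher for c in self.cells]))

    @property
    def is_switcher(self) -> np.ndarray:
        return np.array([c.is_switcher for c in self.cells], dtype=bool)


@dataclass(frozen=True)
class StrainPreset:
    """Named partial override of :class:`GeneratorConfig`.

    The two shipped presets encode the strain contrast the analysis is meant
    to detect: the hypertensive-like preset has a larger sustained (influx)
    amplitude and a larger switcher fraction, while the oscillation
    amplitude distribution is identical between presets.
    """

    name: str
    overrides: dict

    def apply(self, config: GeneratorConfig) -> GeneratorConfig:
        return replace(config, **self.overrides)


PRESETS: dict[str, StrainPreset] = {
    "normotensive-like": StrainPreset(
        "normotensive-like", {"switch_prob": 0.15, "slow_amp_max": 0.8}
    ),
    "hypertensive-like": StrainPreset(
        "hypertensive-like", {"switch_prob": 0.45, "slow_amp_max": 1.4}
    ),
}


def _logistic(x: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _biexp_pulse(t: np.ndarray, t_event: float, amp: float, rise: float, decay: float) -> np.ndarray:
    """Unit-peak bi-exponential transient scaled to ``amp``, zero before onset."""
    dt = t - t_event
    out = np.zeros_like(t)
    m = dt >= 0
    if rise <= 0:
        out[m] = amp * np.exp(-dt[m] / decay)
        return out
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    norm = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    out[m] = amp * (np.exp(-dt[m] / decay) - np.exp(-dt[m] / rise)) / norm
    return out


def _poisson_times(rng: np.random.Generator, rate: float, t_start: float, t_stop: float) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [t_start, t_stop)."""
    span = t_stop - t_start
    if rate <= 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return np.sort(rng.uniform(t_start, t_stop, n))


def simulate_cell(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, CellTruth]:
    """Simulate one cell's F/F0 trace plus its generative ground truth.

    All randomness is drawn from ``rng``; passing generators with identical
    state yields bit-identical output.
    """
    t = config.time_s()
    dur = config.duration_s

    is_switcher = bool(rng.random() < config.switch_prob)
    amp = config.slow_amp_max * hill(
        config.concentration_nmol, config.slow_ec50_nmol, config.slow_hill
    )
    if config.slow_amp_sigma > 0:
        amp *= math.exp(rng.normal(0.0, config.slow_amp_sigma))
    if is_switcher:
        amp *= config.switch_amp_multiplier

    t0 = rng.normal(config.slow_onset_mean_s, config.slow_onset_sd_s)
    # keep onset away from the edges so the plateau is reached in-recording
    t0 = float(np.clip(t0, 0.1 * dur, 0.75 * dur))

    if config.slow_tau_s > 0 and amp > 0:
        z = 1.0 + amp * _logistic((t - t0) / config.slow_tau_s)
    elif amp > 0:
        z = 1.0 + amp * (t >= t0)
    else:
        z = np.ones_like(t)

    # oscillation events: full rate before the switch, suppressed after (switchers)
    osc_rate = config.osc_rate_max_hz * hill(
        config.concentration_nmol, config.osc_ec50_nmol, 1.0
    )
    switch_time = t0 if is_switcher else None
    if is_switcher:
        times = np.concatenate(
            [
                _poisson_times(rng, osc_rate, 0.0, t0),
                _poisson_times(
                    rng, osc_rate * config.post_switch_osc_suppression, t0, dur
                ),
            ]
        )
    else:
        times = _poisson_times(rng, osc_rate, 0.0, dur)

    amps = np.maximum(
        rng.normal(config.osc_amp_mean, config.osc_amp_sd, times.size),
        config.osc_amp_min,
    )
    r = np.ones_like(t)
    for te, a in zip(times, amps):
        r += _biexp_pulse(t, te, a, config.osc_rise_s, config.osc_decay_s)

    trace = z * r
    if config.bleach_rate_per_s > 0:
        trace = trace * np.exp(-config.bleach_rate_per_s * t)
    if config.noise_sd > 0:
        trace = trace * (1.0 + rng.normal(0.0, config.noise_sd, trace.shape))
    trace = np.maximum(trace, 1e-9)  # F/F0 is strictly positive

    truth = CellTruth(
        is_switcher=is_switcher,
        true_slow_amplitude=amp,
        true_switch_time_s=switch_time,
        osc_event_times_s=times,
        osc_event_amplitudes=amps,
        slow_onset_s=t0,
    )
    return trace, truth


def true_slow_curve(truth: CellTruth, config: GeneratorConfig) -> np.ndarray:
    """Reconstruct a cell's generative slow component z(t) from its truth."""
    t = config.time_s()
    amp, t0 = truth.true_slow_amplitude, truth.slow_onset_s
    if amp <= 0:
        return np.ones_like(t)
    if config.slow_tau_s > 0:
        return 1.0 + amp * _logistic((t - t0) / config.slow_tau_s)
    return 1.0 + amp * (t >= t0)


def true_fast_curve(truth: CellTruth, config: GeneratorConfig) -> np.ndarray:
    """Reconstruct a cell's generative fast component r(t) from its truth."""
    t = config.time_s()
    r = np.ones_like(t)
    for te, a in zip(truth.osc_event_times_s, truth.osc_event_amplitudes):
        r += _biexp_pulse(t, te, a, config.osc_rise_s, config.osc_decay_s)
    return r


def simulate_field(
    config: GeneratorConfig, preset: StrainPreset | None = None
) -> tuple[TraceField, SyntheticGroundTruth]:
    """Simulate a whole field of cells.

    Each cell gets an independent child RNG spawned from ``config.seed`` so
    the output is reproducible and insensitive to evaluation order.
    """
    if preset is not None:
        config = preset.apply(config)
    if config.n_cells < 1:
        raise EmptyFieldError("simulate_field requires n_cells >= 1")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_cells)
    traces = np.empty((config.n_cells, config.n_samples))
    cells: list[CellTruth] = []
    for i, ss in enumerate(streams):
        traces[i], truth = simulate_cell(config, np.random.default_rng(ss))
        cells.append(truth)

    f0_stop = max(1, int(0.1 * config.n_samples))
    tf = TraceField(
        time_s=config.time_s(),
        traces=traces,
        group_label=preset.name if preset is not None else "",
        concentration_nmol=config.concentration_nmol,
        f0_window=(0, f0_stop),
    )
    return tf, SyntheticGroundTruth(cells)


@dataclass(frozen=True)
class MovieGeometry:
    """Canvas layout for rendering a field to a movie.

    Cells are placed as non-overlapping disks on a regular grid.
    Intensities are ``background + gain * trace(t)`` inside each footprint;
    with ``photon_scale`` set, Poisson photon noise is applied at that
    photons-per-intensity-unit scale.
    """

    shape: tuple[int, int] = (96, 128)
    cell_radius_px: int = 8
    spacing_px: int = 24
    background: float = 10.0
    gain: float = 100.0
    photon_scale: float | None = None

    def __post_init__(self):
        if self.cell_radius_px < 1 or self.spacing_px <= 2 * self.cell_radius_px:
            raise ParameterError("spacing_px must exceed the cell diameter")

    @classmethod
    def for_cells(cls, n_cells: int, **kw) -> "MovieGeometry":
        """A square-ish canvas just large enough for ``n_cells``."""
        base = cls(**kw) if kw else cls()
        sp = base.spacing_px
        n_cols = max(1, math.ceil(math.sqrt(n_cells)))
        n_rows = max(1, math.ceil(n_cells / n_cols))
        shape = (sp // 2 + n_rows * sp, sp // 2 + n_cols * sp)
        return replace(base, shape=shape)


def render_movie(
    field_: TraceField,
    geometry: MovieGeometry = MovieGeometry(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a field into a movie stack plus its ground-truth label image.

    Returns ``(stack, label_image)`` where ``stack`` has shape
    ``(n_frames, rows, cols)`` and ``label_image`` assigns pixel -> cell
    index (1-based; 0 is background).
    """
    rows, cols = geometry.shape
    sp = geometry.spacing_px
    n_rows = (rows - sp // 2) // sp + 1
    n_cols = (cols - sp // 2) // sp + 1
    capacity = max(0, n_rows) * max(0, n_cols)
    if capacity < field_.n_cells:
        raise LayoutError(
            f"canvas {geometry.shape} holds {capacity} cells at spacing "
            f"{sp}px; {field_.n_cells} requested"
        )

    label = np.zeros((rows, cols), dtype=np.int32)
    yy, xx = np.mgrid[0:rows, 0:cols]
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            if k >= field_.n_cells:
                break
            cy, cx = sp // 2 + i * sp, sp // 2 + j * sp
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= geometry.cell_radius_px**2
            label[disk] = k + 1
            k += 1

    n_t = field_.n_samples
    stack = np.full((n_t, rows, cols), geometry.background, dtype=float)
    for c in range(field_.n_cells):
        mask = label == c + 1
        stack[:, mask] = geometry.background + geometry.gain * field_.traces[c][:, None]

    if geometry.photon_scale is not None:
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack * geometry.photon_scale) / geometry.photon_scale
    return stack, label
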