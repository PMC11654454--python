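"""Per-cell sustained amplitude, switch classification and oscillation
statistics.

A cell's *sustained amplitude* is the mean of its slow (ALS) component over
the final ``tail_window_s`` of the recording minus its mean over a
pre-stimulus baseline window.  A field-level threshold — by default the
field mean amplitude plus ``sem_multiplier`` x SEM across cells — marks
*switched* cells: those whose sustained influx strictly exceeds the
threshold, interpreted as the transition from oscillatory store release to
dominant Ca2+ influx.  Oscillations are counted as prominence-filtered
peaks of the fast ratio component, and for switched cells the event rate is
compared before and after the switch time (first crossing of half the
final amplitude).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .decomposition import DecomposedTrace
from .errors import ClassificationError, ParameterError

__all__ = [
    "ClassificationParams",
    "CellClassification",
    "FieldSummary",
    "sustained_amplitude",
    "classify_field",
    "detect_oscillations",
    "oscillation_change",
    "classify_cells",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationParams:
    tail_window_s: float = 30.0
    baseline_window_s: float = 30.0
    sem_multiplier: float = 3.0
    threshold_mode: str = "mean_plus_sem"  # or "sem_only": threshold = k * SEM
    peak_min_prominence: float = 0.1
    peak_min_separation_s: float = 1.5
    peak_smooth_s: float = 0.6  # moving-average width before peak finding
    switch_fraction: float = 0.5

    def __post_init__(self):
        if self.tail_window_s <= 0 or self.baseline_window_s <= 0:
            raise ParameterError("analysis windows must be positive")
        if self.sem_multiplier < 0:
            raise ParameterError("sem_multiplier must be >= 0")
        if not 0.0 < self.switch_fraction < 1.0:
            raise ParameterError("switch_fraction must be in (0, 1)")
        if self.threshold_mode not in ("mean_plus_sem", "sem_only"):
            raise ParameterError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass
class CellClassification:
    """Summary statistics for one cell."""

    sustained_amplitude: float
    switched: bool
    switch_time_s: float | None
    osc_count: int
    osc_count_pre: int | None
    osc_count_post: int | None
    osc_freq_pre_hz: float | None
    osc_freq_post_hz: float | None
    mean_osc_amplitude: float  # mean peak prominence of (fast - 1); 0 if no events


@dataclass
class FieldSummary:
    """Field-level aggregation used for dose-response and group statistics."""

    n_cells: int
    threshold: float
    mean_amplitude: float
    sem_amplitude: float
    pct_switched: float
    slow_component_amplitude: float  # field mean of per-cell sustained amplitudes
    fast_component_amplitude: float  # field mean of per-cell mean osc amplitudes
    whole_field_average: np.ndarray | None = None
    whole_field_sem: np.ndarray | None = None


def _window_indices(time_s: np.ndarray, params: ClassificationParams) -> tuple[slice, slice]:
    duration = time_s[-1] - time_s[0]
    if params.tail_window_s + params.baseline_window_s > duration:
        raise ParameterError(
            "baseline and tail windows overlap: "
            f"{params.baseline_window_s}+{params.tail_window_s}s exceeds the "
            f"{duration:.1f}s recording"
        )
    base_stop = int(np.searchsorted(time_s, time_s[0] + params.baseline_window_s))
    tail_start = int(np.searchsorted(time_s, time_s[-1] - params.tail_window_s))
    return slice(0, max(base_stop, 1)), slice(tail_start, len(time_s))


def sustained_amplitude(
    d: DecomposedTrace, time_s: np.ndarray, params: ClassificationParams | None = None
) -> float:
    """Tail-window mean minus baseline-window mean of the slow component.

    May legitimately be negative for a cell whose baseline drifts down.
    """
    params = params or ClassificationParams()
    base, tail = _window_indices(np.asarray(time_s, dtype=float), params)
    return float(d.slow[tail].mean() - d.slow[base].mean())


def classify_field(
    amplitudes: np.ndarray, params: ClassificationParams | None = None
) -> tuple[np.ndarray, FieldSummary]:
    """Flag switched cells against the field-level threshold.

    threshold = mean + sem_multiplier * SEM (default) or
    sem_multiplier * SEM alone (``threshold_mode="sem_only"``); a cell is
    switched when its amplitude is *strictly* above the threshold, so a
    field of identical amplitudes has no switched cells.
    """
    params = params or ClassificationParams()
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = amplitudes.size
    if n < 2:
        raise ClassificationError("SEM undefined: need at least 2 cells")
    mean = float(amplitudes.mean())
    sem = float(amplitudes.std(ddof=1) / np.sqrt(n))
    if params.threshold_mode == "mean_plus_sem":
        threshold = mean + params.sem_multiplier * sem
    else:
        threshold = params.sem_multiplier * sem
    flags = amplitudes > threshold
    summary = FieldSummary(
        n_cells=n,
        threshold=threshold,
        mean_amplitude=mean,
        sem_amplitude=sem,
        pct_switched=100.0 * flags.sum() / n,
        slow_component_amplitude=mean,
        fast_component_amplitude=float("nan"),
    )
    return flags, summary


def detect_oscillations(
    fast: np.ndarray, time_s: np.ndarray, params: ClassificationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Oscillation event times and prominences from the fast ratio component.

    The ratio trace minus 1 is smoothed with a short moving average
    (``peak_smooth_s``, acting as a matched filter against sample noise)
    and local maxima with prominence >= ``peak_min_prominence`` and
    separation >= ``peak_min_separation_s`` are reported.  Returns
    (times, prominences); both empty when the cell is quiescent.
    """
    params = params or ClassificationParams()
    time_s = np.asarray(time_s, dtype=float)
    dt = time_s[1] - time_s[0] if time_s.size > 1 else 1.0
    distance = max(1, int(round(params.peak_min_separation_s / dt)))
    signal = np.asarray(fast, dtype=float) - 1.0
    width = max(1, int(round(params.peak_smooth_s / dt)))
    if width > 1:
        signal = uniform_filter1d(signal, width)
    peaks, props = find_peaks(
        signal,
        prominence=params.peak_min_prominence,
        distance=distance,
    )
    return time_s[peaks], props["prominences"]


def _switch_time(
    d: DecomposedTrace,
    time_s: np.ndarray,
    amplitude: float,
    params: ClassificationParams,
) -> float | None:
    """First time the slow component crosses baseline + switch_fraction * amplitude."""
    base, _ = _window_indices(time_s, params)
    level = d.slow[base].mean() + params.switch_fraction * amplitude
    above = d.slow > level
    if not above.any():
        return None
    return float(time_s[int(np.argmax(above))])


def oscillation_change(
    d: DecomposedTrace,
    time_s: np.ndarray,
    event_times: np.ndarray,
    amplitude: float,
    params: ClassificationParams | None = None,
) -> tuple[float, int, int, float, float | None]:
    """Pre/post-switch oscillation statistics for a switched cell.

    Returns ``(switch_time, n_pre, n_post, freq_pre, freq_post)``.
    Frequencies are event counts divided by window length; the post
    frequency is ``None`` when the post-switch window is shorter than the
    peak separation (too short to count events meaningfully).  Raises if
    the slow component never reaches the switch level.
    """
    params = params or ClassificationParams()
    time_s = np.asarray(time_s, dtype=float)
    ts = _switch_time(d, time_s, amplitude, params)
    if ts is None:
        raise ClassificationError("slow component never crosses the switch level")
    event_times = np.asarray(event_times, dtype=float)
    pre_len = ts - time_s[0]
    post_len = time_s[-1] - ts
    n_pre = int((event_times < ts).sum())
    n_post = int((event_times >= ts).sum())
    freq_pre = n_pre / pre_len if pre_len > 0 else 0.0
    freq_post = n_post / post_len if post_len >= params.peak_min_separation_s else None
    return ts, n_pre, n_post, freq_pre, freq_post


def classify_cells(
    decomposed: list[DecomposedTrace],
    time_s: np.ndarray,
    params: ClassificationParams | None = None,
) -> tuple[list[CellClassification], FieldSummary]:
    """Full per-cell classification for one field.

    Computes sustained amplitudes, the field threshold and switched flags,
    per-cell oscillation statistics, and (for switched cells) the switch
    time with pre/post oscillation frequencies.
    """
    params = params or ClassificationParams()
    time_s = np.asarray(time_s, dtype=float)
    amplitudes = np.array(
        [sustained_amplitude(d, time_s, params) for d in decomposed]
    )
    flags, summary = classify_field(amplitudes, params)

    cells: list[CellClassification] = []
    osc_amps = np.zeros(len(decomposed))
    for i, d in enumerate(decomposed):
        ev_times, ev_proms = detect_oscillations(d.fast, time_s, params)
        mean_amp = float(ev_proms.mean()) if ev_proms.size else 0.0
        osc_amps[i] = mean_amp
        switch_time = n_pre = n_post = f_pre = f_post = None
        if flags[i]:
            try:
                switch_time, n_pre, n_post, f_pre, f_post = oscillation_change(
                    d, time_s, ev_times, amplitudes[i], params
                )
            except ClassificationError:
                log.warning("cell %d flagged but no switch-level crossing", i)
        cells.append(
            CellClassification(
                sustained_amplitude=float(amplitudes[i]),
                switched=bool(flags[i]),
                switch_time_s=switch_time,
                osc_count=int(ev_times.size),
                osc_count_pre=n_pre,
                osc_count_post=n_post,
                osc_freq_pre_hz=f_pre,
                osc_freq_post_hz=f_post,
                mean_osc_amplitude=mean_amp,
            )
        )
    summary.fast_component_amplitude = float(osc_amps.mean())
    raw = np.vstack([d.raw for d in decomposed])
    summary.whole_field_average = raw.mean(axis=0)
    if len(decomposed) > 1:
        summary.whole_field_sem = raw.std(axis=0, ddof=1) / np.sqrt(len(decomposed))
    else:
        summary.whole_field_sem = np.zeros_like(summary.whole_field_average)
    return cells, summary
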