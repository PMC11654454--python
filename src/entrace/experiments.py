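"""Canned end-to-end simulation experiments.

These functions run the full analysis chain (generate -> decompose ->
classify -> aggregate) under defined study conditions and return the
population summaries.  They are what the worked examples, the test suite
and the reproduction script call.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classification import ClassificationParams, classify_cells
from .decomposition import ALSParams, decompose_field
from .population import (
    DoseResponse,
    GroupComparison,
    build_dose_response,
    compare_groups,
    field_component_amplitudes,
    normalize_to_max,
)
from .synthetic import PRESETS, GeneratorConfig, simulate_field

__all__ = [
    "analyze_field",
    "FieldResult",
    "StrainContrastResult",
    "strain_contrast_experiment",
    "DEFAULT_CONCENTRATIONS",
]

#: default agonist concentration series (nmol/L) for dose-response runs
DEFAULT_CONCENTRATIONS = (1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass
class FieldResult:
    """One simulated-and-analysed field."""

    concentration_nmol: float
    group_label: str
    slow_amplitude: float
    fast_amplitude: float
    pct_switched: float
    true_switched_fraction: float
    estimated_switched_fraction: float


def analyze_field(
    config: GeneratorConfig,
    preset=None,
    als: ALSParams | None = None,
    cls: ClassificationParams | None = None,
) -> FieldResult:
    """Simulate one field and run decomposition + classification on it."""
    field_, truth = simulate_field(config, preset)
    decomposed, _ = decompose_field(field_, als)
    cells, summary = classify_cells(decomposed, field_.time_s, cls)
    slow, fast = field_component_amplitudes(cells)
    return FieldResult(
        concentration_nmol=config.concentration_nmol,
        group_label=field_.group_label,
        slow_amplitude=slow,
        fast_amplitude=fast,
        pct_switched=summary.pct_switched,
        true_switched_fraction=truth.true_switched_fraction,
        estimated_switched_fraction=summary.pct_switched / 100.0,
    )


@dataclass
class StrainContrastResult:
    """Dose-response curves and group statistics for the two strain presets."""

    dose_response: dict[str, DoseResponse]
    normalized: dict[str, DoseResponse]
    pct_switched: dict[str, np.ndarray]  # per-field, at top concentration
    slow_comparison_top: GroupComparison  # hypertensive vs normotensive
    fast_comparison_top: GroupComparison
    switched_comparison: GroupComparison

    @property
    def max_normalized_curve_difference(self) -> float:
        a = self.normalized["hypertensive-like"]
        b = self.normalized["normotensive-like"]
        return float(
            max(
                np.abs(a.slow_mean - b.slow_mean).max(),
                np.abs(a.fast_mean - b.fast_mean).max(),
            )
        )


def strain_contrast_experiment(
    seed: int,
    n_fields: int = 6,
    n_cells: int = 200,
    concentrations=DEFAULT_CONCENTRATIONS,
    base_config: GeneratorConfig | None = None,
) -> StrainContrastResult:
    """Simulate the two strain presets across a concentration series.

    For each preset, ``n_fields`` independent fields are simulated at each
    concentration and analysed end-to-end; per-field component amplitudes
    are aggregated into dose-response curves, and Welch comparisons are
    computed between presets for the top-concentration slow and fast
    amplitudes and for the percentage of switched cells.
    """
    base = base_config or GeneratorConfig(n_cells=n_cells)
    concentrations = tuple(sorted(concentrations))
    top = concentrations[-1]
    root = np.random.SeedSequence(seed)
    curves: dict[str, DoseResponse] = {}
    normalized: dict[str, DoseResponse] = {}
    pct: dict[str, np.ndarray] = {}
    top_slow: dict[str, list[float]] = {}
    top_fast: dict[str, list[float]] = {}
    for preset_name, preset_seed in zip(sorted(PRESETS), root.spawn(len(PRESETS))):
        preset = PRESETS[preset_name]
        entries = []
        pct_top, slow_top, fast_top = [], [], []
        field_seeds = preset_seed.generate_state(len(concentrations) * n_fields)
        k = 0
        for conc in concentrations:
            for _ in range(n_fields):
                cfg = replace(
                    base,
                    concentration_nmol=conc,
                    seed=int(field_seeds[k] % (2**31)),
                )
                k += 1
                res = analyze_field(cfg, preset)
                entries.append((conc, res.slow_amplitude, res.fast_amplitude))
                if conc == top:
                    pct_top.append(res.pct_switched)
                    slow_top.append(res.slow_amplitude)
                    fast_top.append(res.fast_amplitude)
        curves[preset_name] = build_dose_response(entries, preset_name)
        normalized[preset_name] = normalize_to_max(curves[preset_name])
        pct[preset_name] = np.array(pct_top)
        top_slow[preset_name] = slow_top
        top_fast[preset_name] = fast_top

    hyp, nor = "hypertensive-like", "normotensive-like"
    return StrainContrastResult(
        dose_response=curves,
        normalized=normalized,
        pct_switched=pct,
        slow_comparison_top=compare_groups(top_slow[hyp], top_slow[nor]),
        fast_comparison_top=compare_groups(top_fast[hyp], top_fast[nor]),
        switched_comparison=compare_groups(pct[hyp], pct[nor]),
    )
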