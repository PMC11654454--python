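"""Orchestration: run the simulate -> decompose -> classify -> summarise
chain from a validated config, writing every stage's table plus a manifest.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io
from .classification import classify_cells
from .config import PipelineConfig
from .decomposition import ALSParams, decompose_field
from .experiments import DEFAULT_CONCENTRATIONS  # noqa: F401  (re-export convenience)
from .population import (
    build_dose_response,
    compare_groups,
    field_component_amplitudes,
)
from .synthetic import PRESETS, simulate_field
from .traces import write_trace_field_csv

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the output directory.

    Outputs: per-field trace/decomposition/classification CSVs, a field
    summary table, a dose-response table (plus a group comparison table
    when both presets are run), and ``manifest.yaml``.  Partial outputs
    are retained if a stage fails (the failing stage is in the log).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = PRESETS[config.preset] if config.preset else None
    field_seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.concentrations) * config.n_fields
    )

    outputs: list[Path] = []
    summaries = []
    entries = []
    als_used: ALSParams | None = config.als
    k = 0
    for conc in config.concentrations:
        for rep in range(config.n_fields):
            cfg = replace(
                config.simulate, concentration_nmol=conc, seed=int(field_seeds[k] % 2**31)
            )
            k += 1
            tag = f"c{conc:g}_f{rep}"
            log.info("stage simulate: field %s", tag)
            field_, truth = simulate_field(cfg, preset)
            p = outdir / f"traces_{tag}.csv"
            write_trace_field_csv(field_, p)
            outputs.append(p)
            p = outdir / f"truth_{tag}.csv"
            io.write_ground_truth_csv(truth, p)
            outputs.append(p)

            log.info("stage decompose: field %s", tag)
            decomposed, als_used = decompose_field(field_, config.als)
            p = outdir / f"decomposition_{tag}.csv"
            io.write_decomposition_csv(decomposed, field_.time_s, p, field_.cell_ids)
            outputs.append(p)

            log.info("stage classify: field %s", tag)
            cells, summary = classify_cells(
                decomposed, field_.time_s, config.classification
            )
            p = outdir / f"classification_{tag}.csv"
            io.write_classification_csv(cells, p, field_.cell_ids)
            outputs.append(p)

            slow, fast = field_component_amplitudes(cells)
            summaries.append(
                (
                    {
                        "field": tag,
                        "concentration_nmol": conc,
                        "group_label": field_.group_label,
                    },
                    summary,
                )
            )
            entries.append((conc, slow, fast))

    log.info("stage summarise")
    p = outdir / "field_summaries.csv"
    io.write_field_summary_csv(summaries, p)
    outputs.append(p)
    curve = build_dose_response(entries, config.preset or "")
    p = outdir / "dose_response.csv"
    io.write_dose_response_csv([curve], p)
    outputs.append(p)

    io.write_manifest(
        outdir / "manifest.yaml",
        config.to_dict(),
        config.seed,
        outputs,
        stage_params={"als": dataclasses.asdict(als_used) if als_used else None},
    )
    return outdir


def summarize_groups(per_group_values: dict[str, list[float]]) -> dict:
    """Welch-compare every pair of groups on per-field values."""
    names = sorted(per_group_values)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[f"{a}_vs_{b}"] = compare_groups(
                per_group_values[a], per_group_values[b]
            )
    return out
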