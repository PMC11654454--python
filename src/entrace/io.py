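"""CSV/TIFF serialisation and the run manifest.

All tables are plain UTF-8 comma-separated files with a header row; times
in seconds, concentrations in nmol/L, fluorescence quantities dimensionless
F/F0.  The manifest is a YAML snapshot of every parameter, seed and output
digest so a run can be reproduced bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classification import CellClassification, FieldSummary
from .decomposition import DecomposedTrace
from .population import DoseResponse, GroupComparison

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_label_tiff",
    "read_label_tiff",
    "write_decomposition_csv",
    "read_decomposition_csv",
    "write_classification_csv",
    "write_field_summary_csv",
    "write_dose_response_csv",
    "write_comparison_csv",
    "write_ground_truth_csv",
    "write_manifest",
    "file_digest",
]


def write_movie_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_label_tiff(label_image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(label_image, dtype=np.int32))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_decomposition_csv(
    decomposed: list[DecomposedTrace], time_s: np.ndarray, path, cell_ids=None
) -> None:
    cell_ids = cell_ids if cell_ids is not None else np.arange(1, len(decomposed) + 1)
    frames = []
    for cid, d in zip(cell_ids, decomposed):
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cid,
                    "time_s": time_s,
                    "raw": d.raw,
                    "slow": d.slow,
                    "fast": d.fast,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_decomposition_csv(path) -> tuple[list[DecomposedTrace], np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    out = []
    cell_ids = df["cell_id"].unique()
    time_s = None
    for cid in cell_ids:
        sub = df[df["cell_id"] == cid].sort_values("time_s")
        time_s = sub["time_s"].to_numpy()
        out.append(
            DecomposedTrace(
                raw=sub["raw"].to_numpy(),
                slow=sub["slow"].to_numpy(),
                fast=sub["fast"].to_numpy(),
                converged=True,
                iterations_used=0,
            )
        )
    return out, time_s, cell_ids


def write_classification_csv(
    cells: list[CellClassification], path, cell_ids=None
) -> None:
    cell_ids = cell_ids if cell_ids is not None else np.arange(1, len(cells) + 1)
    rows = [dataclasses.asdict(c) | {"cell_id": cid} for cid, c in zip(cell_ids, cells)]
    df = pd.DataFrame(rows)
    cols = ["cell_id"] + [c for c in df.columns if c != "cell_id"]
    df[cols].to_csv(path, index=False)


def write_field_summary_csv(summaries: list[tuple[dict, FieldSummary]], path) -> None:
    """Each entry is (metadata dict, FieldSummary); traces are not serialised."""
    rows = []
    for meta, s in summaries:
        d = dataclasses.asdict(s)
        d.pop("whole_field_average", None)
        d.pop("whole_field_sem", None)
        rows.append(meta | d)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dose_response_csv(curves: list[DoseResponse], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "group_label": c.group_label,
                    "concentration_nmol": c.concentrations_nmol,
                    "slow_mean": c.slow_mean,
                    "slow_sd": c.slow_sd,
                    "fast_mean": c.fast_mean,
                    "fast_sd": c.fast_sd,
                    "n_fields": c.n_fields,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_comparison_csv(comparisons: dict[str, GroupComparison], path) -> None:
    rows = [{"comparison": k} | dataclasses.asdict(v) for k, v in comparisons.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ground_truth_csv(truth, path) -> None:
    rows = []
    for i, c in enumerate(truth.cells):
        rows.append(
            {
                "cell_id": i + 1,
                "is_switcher": c.is_switcher,
                "true_slow_amplitude": c.true_slow_amplitude,
                "true_switch_time_s": c.true_switch_time_s,
                "slow_onset_s": c.slow_onset_s,
                "n_osc_events": len(c.osc_event_times_s),
                "osc_event_times_s": ";".join(f"{t:.3f}" for t in c.osc_event_times_s),
                "osc_event_amplitudes": ";".join(
                    f"{a:.4f}" for a in c.osc_event_amplitudes
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path,
    config: dict,
    seed: int,
    outputs: list[str | Path],
    stage_params: dict | None = None,
) -> None:
    from . import __version__

    manifest = {
        "software": {"name": "entrace", "version": __version__},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "stage_params": stage_params or {},
        "outputs": {
            str(Path(p).name): file_digest(p) for p in outputs if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
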