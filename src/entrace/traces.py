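"""Per-cell F/F0 trace container shared by the imaging, synthetic and
analysis stages.

A :class:`TraceField` holds every cell trace from one imaging field (one
artery preparation at one agonist concentration) on a common time base.
Traces are dimensionless F/F0 — fluorescence divided by the mean over a
pre-stimulus baseline window — so a quiescent cell sits at 1.0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyFieldError, ParameterError

__all__ = ["TraceField", "write_trace_field_csv", "read_trace_field_csv"]


@dataclass
class TraceField:
    """All single-cell F/F0 traces from one field of view.

    Parameters
    ----------
    time_s:
        Sample times in seconds, shared by every trace.
    traces:
        Array of shape ``(n_cells, n_samples)``; dimensionless F/F0.
    group_label:
        Experimental group (e.g. ``"normotensive-like"``).
    concentration_nmol:
        Agonist concentration in nmol/L.
    f0_window:
        ``(start, stop)`` frame indices of the baseline window used for
        F0 normalisation (half-open, like a slice).
    """

    time_s: np.ndarray
    traces: np.ndarray
    group_label: str = ""
    concentration_nmol: float = float("nan")
    f0_window: tuple[int, int] = (0, 0)
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] != self.time_s.shape[0]:
            raise ParameterError(
                f"traces have {self.traces.shape[1]} samples but time base has "
                f"{self.time_s.shape[0]}"
            )
        if self.cell_ids is None:
            self.cell_ids = np.arange(1, self.n_cells + 1)
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.shape[0] != self.n_cells:
                raise ParameterError("cell_ids length does not match traces")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def frame_rate_hz(self) -> float:
        if self.n_samples < 2:
            raise ParameterError("need at least 2 samples to infer frame rate")
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def whole_field_average(self) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise mean and SEM across cells (the whole-field signal)."""
        if self.n_cells == 0:
            raise EmptyFieldError("cannot average an empty field")
        mean = self.traces.mean(axis=0)
        if self.n_cells == 1:
            return mean, np.zeros_like(mean)
        sem = self.traces.std(axis=0, ddof=1) / np.sqrt(self.n_cells)
        return mean, sem


def write_trace_field_csv(field_: TraceField, path) -> None:
    """Write a field to long-format CSV (cell_id, time_s, f_over_f0, ...)."""
    n_c, n_t = field_.traces.shape
    df = pd.DataFrame(
        {
            "cell_id": np.repeat(field_.cell_ids, n_t),
            "time_s": np.tile(field_.time_s, n_c),
            "f_over_f0": field_.traces.ravel(),
        }
    )
    df["group_label"] = field_.group_label
    df["concentration_nmol"] = field_.concentration_nmol
    df["f0_start"] = field_.f0_window[0]
    df["f0_stop"] = field_.f0_window[1]
    df.to_csv(path, index=False)


def read_trace_field_csv(path) -> TraceField:
    """Read a long-format trace CSV back into a :class:`TraceField`."""
    df = pd.read_csv(path)
    required = {"cell_id", "time_s", "f_over_f0"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"trace CSV missing column(s): {sorted(missing)}")
    cell_ids = df["cell_id"].unique()
    wide = df.pivot(index="cell_id", columns="time_s", values="f_over_f0")
    wide = wide.loc[cell_ids]  # preserve file order
    time_s = wide.columns.to_numpy(dtype=float)
    order = np.argsort(time_s)
    return TraceField(
        time_s=time_s[order],
        traces=wide.to_numpy()[:, order],
        group_label=str(df["group_label"].iloc[0]) if "group_label" in df else "",
        concentration_nmol=float(df["concentration_nmol"].iloc[0])
        if "concentration_nmol" in df
        else float("nan"),
        f0_window=(
            int(df["f0_start"].iloc[0]) if "f0_start" in df else 0,
            int(df["f0_stop"].iloc[0]) if "f0_stop" in df else 0,
        ),
        cell_ids=cell_ids,
    )
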