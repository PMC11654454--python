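"""Population-level aggregation: concentration-response curves,
max-normalised sensitivity curves, and Welch group comparisons.

The unit of replication is the field (one artery preparation), matching
how such experiments are replicated in practice: per-field component
amplitudes are averaged over cells first, then fields provide the n for
between-group statistics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import optimize, stats

from .classification import CellClassification
from .errors import EmptyFieldError, NormalizationError, ParameterError

__all__ = [
    "DoseResponse",
    "GroupComparison",
    "field_component_amplitudes",
    "build_dose_response",
    "normalize_to_max",
    "compare_groups",
    "fit_hill",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseResponse:
    """Mean +/- SD component amplitudes per concentration (over fields)."""

    concentrations_nmol: np.ndarray
    slow_mean: np.ndarray
    slow_sd: np.ndarray
    fast_mean: np.ndarray
    fast_sd: np.ndarray
    n_fields: np.ndarray
    group_label: str = ""


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Welch t test result."""

    statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def field_component_amplitudes(
    cells: list[CellClassification],
) -> tuple[float, float]:
    """Field-mean slow (sustained) and fast (oscillatory) amplitudes.

    Slow: mean sustained amplitude over cells.  Fast: mean over cells of
    each cell's mean oscillation-peak prominence, counting quiescent cells
    as 0 so silent cells dilute the field average rather than vanish.
    """
    if not cells:
        raise EmptyFieldError("cannot summarise an empty field")
    slow = float(np.mean([c.sustained_amplitude for c in cells]))
    fast = float(np.mean([c.mean_osc_amplitude for c in cells]))
    return slow, fast


def build_dose_response(
    entries: list[tuple[float, float, float]], group_label: str = ""
) -> DoseResponse:
    """Aggregate per-field (concentration, slow, fast) entries.

    Fields sharing a concentration are averaged together (a repeated
    concentration is merged, with a logged notice).  Output is sorted by
    concentration ascending.  A concentration represented by a single
    field gets SD 0 (flagged in the log).
    """
    if not entries:
        raise ParameterError("no fields supplied")
    arr = np.asarray(entries, dtype=float)
    concs = np.unique(arr[:, 0])
    slow_m, slow_s, fast_m, fast_s, ns = [], [], [], [], []
    for c in concs:
        rows = arr[arr[:, 0] == c]
        if rows.shape[0] > 1 and rows.shape[0] != arr.shape[0] // concs.size:
            log.info("concentration %g nmol/L: %d fields merged", c, rows.shape[0])
        ns.append(rows.shape[0])
        slow_m.append(rows[:, 1].mean())
        fast_m.append(rows[:, 2].mean())
        if rows.shape[0] > 1:
            slow_s.append(rows[:, 1].std(ddof=1))
            fast_s.append(rows[:, 2].std(ddof=1))
        else:
            log.warning("single field at %g nmol/L; SD reported as 0", c)
            slow_s.append(0.0)
            fast_s.append(0.0)
    return DoseResponse(
        concentrations_nmol=concs,
        slow_mean=np.array(slow_m),
        slow_sd=np.array(slow_s),
        fast_mean=np.array(fast_m),
        fast_sd=np.array(fast_s),
        n_fields=np.array(ns, dtype=int),
        group_label=group_label,
    )


def normalize_to_max(curve: DoseResponse) -> DoseResponse:
    """Divide each component by its own maximum over concentrations.

    The maximum point of each normalised component equals 1 exactly, so
    curves differing only by scale become identical — the sensitivity
    comparison.  Refuses a component whose maximum is not positive.
    """
    out = {}
    for comp in ("slow", "fast"):
        m = getattr(curve, f"{comp}_mean")
        peak = m.max()
        if peak <= 0:
            raise NormalizationError(
                f"{comp} component has non-positive maximum; cannot normalise"
            )
        out[f"{comp}_mean"] = m / peak
        out[f"{comp}_sd"] = getattr(curve, f"{comp}_sd") / peak
    return _dc_replace(curve, **out)


def compare_groups(a, b) -> GroupComparison:
    """Welch two-sided t test (unequal variances) on per-field values.

    Degenerate case: both groups constant with equal means gives t = 0,
    p = 1 by convention (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2 fields")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            log.warning("zero variance in both groups with equal means; p = 1")
            return GroupComparison(0.0, 1.0, float(a.size + b.size - 2),
                                   a.mean(), b.mean(), 0.0, 0.0, a.size, b.size)
        # identical within-group values but different means: effectively certain
        return GroupComparison(float("inf") if a.mean() > b.mean() else float("-inf"),
                               0.0, float(a.size + b.size - 2),
                               a.mean(), b.mean(), 0.0, 0.0, a.size, b.size)
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def _hill_curve(c, emax, ec50, h):
    return emax * c**h / (c**h + ec50**h)


def fit_hill(
    concentrations: np.ndarray, responses: np.ndarray
) -> tuple[float, float, float]:
    """Fit a Hill curve with bottom fixed at 0; returns (emax, ec50, h).

    Used for generative-parameter recovery checks, not by the pipeline
    itself.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    p0 = (r.max() if r.max() > 0 else 1.0, np.median(c), 1.5)
    popt, _ = optimize.curve_fit(
        _hill_curve, c, r, p0=p0,
        bounds=([0, c.min() / 100, 0.2], [np.inf, c.max() * 100, 10]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
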