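"""Asymmetric-least-squares decomposition of Ca2+ traces.

Each cell's F/F0 trace ``y`` is separated into a slow sustained component
``z`` (Ca2+ influx) and a fast oscillatory component ``r`` (store release)
via

    y(t) = z(t) * r(t),        r = y / z,

where ``z`` is the asymmetric least squares (ALS) smooth of ``y``: the
minimiser of

    sum_i w_i (y_i - z_i)^2 + lambda * sum_i (Delta^d z_i)^2

with sign-asymmetric weights ``w_i = p`` where ``y_i > z_i`` and ``1 - p``
otherwise, iterated to a fixed point.  A small ``p`` makes the smooth hug
the lower envelope of the trace, so upward oscillation transients are
rejected while the sustained rise is tracked; the ratio ``r`` then
fluctuates about 1 and carries the oscillations.

The penalised normal equations ``(W + lambda D^T D) z = W y`` are solved
with a banded Cholesky solver (the system matrix is symmetric positive
definite with bandwidth ``d``), so each iteration is O(n).

Numerical choices
-----------------
* ``lambda`` scales as the fourth power of the frame rate (for the default
  second-difference penalty), so the smoother's bandwidth is fixed in
  seconds rather than samples; the default corresponds to lambda = 20 at
  1 Hz.
* The trace is reflection-padded (default 10 s) on both ends before
  smoothing and the fit is truncated back, which suppresses the upward
  bias an oscillation right at a recording boundary would otherwise
  induce.  ``edge_pad_s = 0`` recovers natural boundary conditions.
* Weight iteration starts from all-ones weights and stops when the weight
  vector is unchanged, or after ``max_iterations`` (under measurement
  noise a handful of boundary weights may flip indefinitely; the fit
  itself is stable well before the cap).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded

from .errors import DecompositionError, ParameterError
from .traces import TraceField

__all__ = ["ALSParams", "DecomposedTrace", "als_fit", "decompose", "decompose_field"]

log = logging.getLogger(__name__)

#: lambda for a 1 Hz recording; scaled by frame_rate**4 (see ALSParams.for_frame_rate)
LAMBDA_AT_1HZ = 20.0


@dataclass(frozen=True)
class ALSParams:
    """Parameters of the ALS smoother.

    Defaults are expressed for the package's reference sampling rate of
    5 frames/s; use :meth:`for_frame_rate` to rescale ``smoothness_lambda``
    and the edge pad for other rates.
    """

    smoothness_lambda: float = LAMBDA_AT_1HZ * 5.0**4
    asymmetry_p: float = 0.002
    max_iterations: int = 10
    weight_tolerance: float = 0.0
    difference_order: int = 2
    edge_pad: int = 50  # reflection pad in samples (10 s at 5 Hz)

    def __post_init__(self):
        if not self.smoothness_lambda > 0:
            raise ParameterError("smoothness_lambda must be > 0")
        if not 0.0 < self.asymmetry_p < 1.0:
            raise ParameterError("asymmetry_p must be in (0, 1)")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.difference_order < 1:
            raise ParameterError("difference_order must be >= 1")
        if self.edge_pad < 0:
            raise ParameterError("edge_pad must be >= 0")

    @classmethod
    def for_frame_rate(cls, frame_rate_hz: float, edge_pad_s: float = 10.0, **kw) -> "ALSParams":
        """Build params with the smoothing bandwidth fixed in seconds."""
        if frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        order = kw.pop("difference_order", 2)
        lam = kw.pop("smoothness_lambda", LAMBDA_AT_1HZ * frame_rate_hz ** (2 * order))
        return cls(
            smoothness_lambda=lam,
            difference_order=order,
            edge_pad=int(round(edge_pad_s * frame_rate_hz)),
            **kw,
        )


@dataclass
class DecomposedTrace:
    """One cell's slow/fast separation.

    The reconstruction identity ``raw = slow * fast`` holds exactly at every
    sample by construction (``fast`` is defined as the elementwise ratio).
    """

    raw: np.ndarray
    slow: np.ndarray
    fast: np.ndarray
    converged: bool
    iterations_used: int


def _penalty_banded_upper(n: int, lam: float, order: int) -> np.ndarray:
    """Upper banded form (for ``solveh_banded``) of ``lam * D^T D``."""
    d = sparse.eye(n, format="csc")
    for _ in range(order):
        d = d[1:] - d[:-1]
    p = (lam * (d.T @ d)).todia()
    ab = np.zeros((order + 1, n))
    for off, data in zip(p.offsets, p.data):
        if off >= 0:
            ab[order - off] = data
    return ab


def _als_iterate(y: np.ndarray, params: ALSParams) -> tuple[np.ndarray, bool, int]:
    n = y.shape[0]
    ab0 = _penalty_banded_upper(n, params.smoothness_lambda, params.difference_order)
    w = np.ones(n)
    converged = False
    iterations = 0
    z = y
    for iterations in range(1, params.max_iterations + 1):
        ab = ab0.copy()
        ab[-1] += w
        z = solveh_banded(ab, w * y)
        w_new = np.where(y > z, params.asymmetry_p, 1.0 - params.asymmetry_p)
        if np.max(np.abs(w_new - w)) <= params.weight_tolerance:
            converged = True
            break
        w = w_new
    return z, converged, iterations


def als_fit(y: np.ndarray, params: ALSParams | None = None) -> np.ndarray:
    """ALS smooth of a series; returns the slow component ``z``.

    Raises on non-finite input or series shorter than
    ``difference_order + 2`` samples.  A fit that hits ``max_iterations``
    without the weights reaching a fixed point is still returned (and
    logged); use :func:`decompose` to inspect convergence.
    """
    z, _, _ = _als_fit_full(y, params or ALSParams())
    return z


def _als_fit_full(y: np.ndarray, params: ALSParams) -> tuple[np.ndarray, bool, int]:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ParameterError("als_fit expects a 1-D series")
    if not np.all(np.isfinite(y)):
        raise ParameterError("als_fit input contains non-finite values")
    if y.shape[0] < params.difference_order + 2:
        raise ParameterError(
            f"series of length {y.shape[0]} too short for difference order "
            f"{params.difference_order}"
        )
    pad = min(params.edge_pad, y.shape[0] - 1)
    if pad > 0:
        y_ext = np.concatenate([y[pad:0:-1], y, y[-2 : -pad - 2 : -1]])
    else:
        y_ext = y
    z, converged, iterations = _als_iterate(y_ext, params)
    if pad > 0:
        z = z[pad : pad + y.shape[0]]
    if not converged:
        log.info(
            "ALS weight iteration did not reach a fixed point in %d iterations",
            iterations,
        )
    return z, converged, iterations


def decompose(y: np.ndarray, params: ALSParams | None = None) -> DecomposedTrace:
    """Split an F/F0 trace into slow (ALS fit) and fast (ratio) components."""
    params = params or ALSParams()
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        idx = int(np.argmax(y <= 0))
        raise DecompositionError(f"F/F0 trace must be > 0; first offence at sample {idx}")
    slow, converged, iterations = _als_fit_full(y, params)
    if np.any(slow <= 0):
        idx = int(np.argmax(slow <= 0))
        raise DecompositionError(f"ALS fit non-positive at sample {idx}; cannot form ratio")
    fast = y / slow
    return DecomposedTrace(
        raw=y, slow=slow, fast=fast, converged=converged, iterations_used=iterations
    )


def decompose_field(
    field_: TraceField, params: ALSParams | None = None
) -> tuple[list[DecomposedTrace], ALSParams]:
    """Decompose every cell of a field.

    When ``params`` is omitted they are derived from the field's frame rate
    so the smoothing bandwidth is the same in seconds regardless of
    sampling.  Returns the per-cell decompositions and the params used
    (record them in the run manifest).
    """
    if params is None:
        params = ALSParams.for_frame_rate(field_.frame_rate_hz)
    decomposed = [decompose(tr, params) for tr in field_.traces]
    capped = sum(not d.converged for d in decomposed)
    if capped:
        log.warning(
            "%d of %d traces hit the %d-iteration weight cap (fit returned; "
            "under noise a few boundary weights may flip indefinitely)",
            capped, len(decomposed), params.max_iterations,
        )
    return decomposed, params
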