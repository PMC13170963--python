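"""Background (non-Faradaic) current estimation and subtraction.

A raw voltammogram is the sum of the Faradaic current of interest and a
slowly varying capacitive background.  Three estimators of that
background are provided:

``poly_baseline``
    Global least-squares polynomial (default degree 2), suited to the
    gentle drift of a CV trace.
``segmented_linear_baseline``
    A straight line per CV sweep, fitted to the pre-peak opening portion
    of the sweep and extrapolated across it.  This is the default CV
    baseline for peak quantification; the global polynomial serves as an
    alternative and as a drift diagnostic.
``als_baseline``
    Asymmetric least squares for DPV: the baseline z minimises

        sum_i w_i (y_i - z_i)^2  +  lam * sum_i (d2 z)_i^2

    where d2 is the second difference, and the weights are re-assigned
    each round as ``p`` for points above the current baseline and
    ``1 - p`` below.  Small ``p`` lets positive peaks float free of the
    fit while the smoothness penalty carries the baseline underneath
    them.  The first round uses uniform weights and therefore equals the
    symmetric Whittaker smoother.

The second-difference penalty assumes a near-uniform potential grid, the
usual case for instrument exports; grid irregularity is ignored by the
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import FitError, InputError, ParameterError, ValidationError
from .io import Voltammogram
from .preprocess import SweepSegmentation


class BaselineMethod(str, Enum):
    POLY = "poly"
    SEGMENTED_LINEAR = "segmented_linear"
    ALS = "als"


@dataclass(frozen=True)
class AlsParams:
    """Asymmetric least squares tuning parameters.

    lam : smoothness penalty weight; larger values give a stiffer
        baseline.  The effective smoothing half-width of the Whittaker
        penalty grows like lam**(1/4) samples, so lam must be large
        enough that the baseline stays stiff across the full support of
        a Faradaic peak.  The default 1e7 (half-width ~56 samples) suits
        DPV peaks whose Gaussian sigma spans on the order of 10-20 grid
        steps; softer backgrounds can drop to 1e5-1e6.
    p : asymmetry weight in (0, 1); points above the baseline get weight
        ``p``, points below get ``1 - p``.  Small values (0.01) push the
        baseline underneath positive peaks.
    max_iter : cap on reweighting rounds.
    tol : stop once the Euclidean norm of the weight-vector change drops
        to this value; 0 runs to an exact weight fixed point (or the
        iteration cap).
    """

    lam: float = 1e7
    p: float = 0.01
    max_iter: int = 50
    tol: float = 0.0

    def __post_init__(self):
        if not self.lam > 0:
            raise ParameterError(f"lam must be > 0, got {self.lam}")
        if not 0 < self.p < 1:
            raise ParameterError(f"p must be in (0, 1), got {self.p}")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.tol < 0:
            raise ParameterError("tol must be >= 0")


@dataclass(frozen=True)
class BaselineEstimate:
    """A fitted background plus the background-corrected signal.

    The reconstruction invariant ``input == baseline + corrected`` holds
    exactly: ``corrected`` is computed as input minus the fitted curve
    and ``baseline`` is then re-derived as input minus ``corrected``.
    """

    baseline: np.ndarray
    corrected: np.ndarray
    method: BaselineMethod
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _make_estimate(y: np.ndarray, fitted: np.ndarray, method: BaselineMethod,
                   params: dict, diagnostics: dict | None = None
                   ) -> BaselineEstimate:
    corrected = y - fitted
    baseline = y - corrected  # re-derivation keeps y == baseline + corrected
    return BaselineEstimate(baseline=baseline, corrected=corrected,
                            method=method, params=params,
                            diagnostics=diagnostics or {})


def poly_baseline(x: np.ndarray, y: np.ndarray, degree: int = 2
                  ) -> BaselineEstimate:
    """Least-squares polynomial background of the given degree.

    The abscissa is mapped to [-1, 1] internally for conditioning; the
    fitted values agree with the unscaled normal equations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 0:
        raise ParameterError(f"degree must be >= 0, got {degree}")
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    if len(x) < degree + 1:
        raise InputError(
            f"need at least {degree + 1} points for degree {degree}"
        )
    if np.ptp(x) == 0:
        raise FitError("all potentials identical: polynomial fit is degenerate")
    poly = np.polynomial.Polynomial.fit(x, y, deg=degree)
    fitted = poly(x)
    return _make_estimate(y, fitted, BaselineMethod.POLY, {"degree": degree})


def segmented_linear_baseline(v: Voltammogram, seg: SweepSegmentation,
                              edge_fraction: float = 0.2) -> BaselineEstimate:
    """Per-sweep linear background for a CV trace.

    Within each sweep a straight line is fitted to the opening
    ``edge_fraction`` of that sweep's points — the pre-peak region where
    the current is dominated by capacitive charging plus drift — and
    extrapolated across the whole sweep.  An empty reverse sweep reduces
    the fit to the forward sweep with a warning in the diagnostics.
    """
    if not 0 < edge_fraction <= 0.5:
        raise ParameterError(
            f"edge_fraction must be in (0, 0.5], got {edge_fraction}"
        )
    y = v.currents
    fitted = np.empty_like(y)
    warnings: list[str] = []
    for name, (lo, hi) in (("forward", seg.forward), ("reverse", seg.reverse)):
        if hi - lo == 0:
            warnings.append(f"empty {name} sweep: baseline from other sweep only")
            continue
        if hi - lo < 4:
            raise InputError(f"{name} sweep has fewer than 4 points")
        k = max(2, int(np.floor(edge_fraction * (hi - lo))))
        xs, ys = v.potentials[lo:lo + k], y[lo:lo + k]
        if np.ptp(xs) == 0:
            raise FitError(f"degenerate potentials in {name} sweep edge region")
        line = np.polynomial.Polynomial.fit(xs, ys, deg=1)
        fitted[lo:hi] = line(v.potentials[lo:hi])
    return _make_estimate(
        y, fitted, BaselineMethod.SEGMENTED_LINEAR,
        {"edge_fraction": edge_fraction},
        {"warnings": warnings} if warnings else {},
    )


def _second_difference(n: int) -> sp.csc_matrix:
    """Interior-row second-difference operator, shape (n-2, n)."""
    data = np.repeat([[1.0, -2.0, 1.0]], n - 2, axis=0).T
    return sp.diags_array(data, offsets=[0, 1, 2], shape=(n - 2, n)).tocsc()


def als_baseline(y: np.ndarray, params: AlsParams | None = None
                 ) -> BaselineEstimate:
    """Asymmetric least squares baseline (sparse Whittaker iteration).

    Each round solves ``(W + lam * D'D) z = W y`` with the current
    weights, then re-assigns ``w_i = p`` where ``y_i > z_i`` and
    ``1 - p`` elsewhere, starting from uniform weights.  Iteration stops
    at a weight fixed point, when the weight-change norm falls to
    ``tol``, or at ``max_iter`` rounds.  Diagnostics record the rounds
    used and the final weight-change norm.
    """
    params = params or AlsParams()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise InputError("ALS needs a 1-D series of at least 4 points")
    if not np.isfinite(y).all():
        raise ValidationError("non-finite value in ALS input")

    n = len(y)
    d2 = _second_difference(n)
    penalty = (params.lam * (d2.T @ d2)).tocsc()
    w = np.ones(n)
    z = y
    iterations = 0
    weight_change = np.inf
    for _ in range(params.max_iter):
        lhs = penalty + sp.diags_array(w, format="csc")
        z = splu(lhs).solve(w * y)
        iterations += 1
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        weight_change = float(np.linalg.norm(w_new - w))
        w = w_new
        if weight_change <= params.tol or weight_change == 0.0:
            break
    return _make_estimate(
        y, z, BaselineMethod.ALS,
        {"lam": params.lam, "p": params.p,
         "max_iter": params.max_iter, "tol": params.tol},
        {"iterations": iterations, "final_weight_change": weight_change},
    )


def subtract_baseline(y: np.ndarray, estimate: BaselineEstimate) -> np.ndarray:
    """Return the background-corrected signal for ``y``.

    ``y`` must be the series the estimate was computed from; the
    subtraction is exact elementwise.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(estimate.baseline):
        raise InputError(
            f"length mismatch: signal {len(y)} vs baseline "
            f"{len(estimate.baseline)}"
        )
    return estimate.corrected
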