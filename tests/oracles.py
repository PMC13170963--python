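"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives an expected result from first principles (dense
linear algebra, exhaustive scans, explicit per-window regression) and
deliberately shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def dense_als_iterations(y, lam, p, max_iter):
    """Asymmetric least squares by dense direct solves.

    Returns the list of baseline vectors after each reweighting round,
    following the same stopping rule as the package: uniform starting
    weights, stop at a weight fixed point or the iteration cap.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    d2 = np.diff(np.eye(n), n=2, axis=0)  # (n-2, n) second difference
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    baselines = []
    for _ in range(max_iter):
        z = np.linalg.solve(np.diag(w) + penalty, w * y)
        baselines.append(z)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return baselines


def whittaker_dense(y, lam, weights=None):
    """One symmetric Whittaker smooth: solve (W + lam D'D) z = W y densely."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    d2 = np.diff(np.eye(n), n=2, axis=0)
    return np.linalg.solve(np.diag(w) + lam * (d2.T @ d2), w * y)


def normal_equations_polyfit(x, y, degree):
    """Polynomial fit via raw (unscaled) normal equations; returns values."""
    x = np.asarray(x, dtype=float)
    vand = np.vander(x, degree + 1)
    beta = np.linalg.solve(vand.T @ vand, vand.T @ np.asarray(y, dtype=float))
    return vand @ beta


def savgol_window_value(y, i, window, degree):
    """Per-window least-squares value at the centre of a full interior window."""
    half = window // 2
    t = np.arange(-half, half + 1, dtype=float)
    coeffs = np.polyfit(t, np.asarray(y, dtype=float)[i - half:i + half + 1],
                        degree)
    return np.polyval(coeffs, 0.0)


def _plateau_maxima(y):
    """Strict local maxima, leftmost index of any plateau."""
    out = []
    n = len(y)
    for i in range(1, n - 1):
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append(i)
    return out


def _prominence(y, i):
    """Prominence by explicit valley search on both sides of peak i."""
    n = len(y)
    left_min = y[i]
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        left_min = min(left_min, y[j])
        j -= 1
    left_base = left_min if j >= 0 else min(y[: i + 1])
    right_min = y[i]
    j = i + 1
    while j < n and y[j] <= y[i]:
        right_min = min(right_min, y[j])
        j += 1
    right_base = right_min if j < n else min(y[i:])
    return y[i] - max(left_base, right_base)


def exhaustive_peaks(y, min_prominence, min_separation, polarity="both"):
    """Exhaustive peak detection: enumerate maxima, valley-search
    prominence, then greedy filtering by descending prominence."""
    y = np.asarray(y, dtype=float)
    signals = []
    if polarity in ("anodic", "both"):
        signals.append(y)
    if polarity in ("cathodic", "both"):
        signals.append(-y)
    accepted: set[int] = set()
    for sig in signals:
        cands = [(i, _prominence(sig, i)) for i in _plateau_maxima(sig)]
        cands = [(i, p) for i, p in cands if p >= min_prominence]
        cands.sort(key=lambda t: (-t[1], t[0]))
        kept: list[int] = []
        for i, _ in cands:
            if all(abs(i - k) >= min_separation for k in kept):
                kept.append(i)
        accepted.update(kept)
    return sorted(accepted)


def sign_change_turning_index(potentials, half_window=2):
    """Turning point by scanning majority-filtered signs of first diffs."""
    d = np.diff(np.asarray(potentials, dtype=float))
    n = len(d)
    filtered = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        filtered[i] = np.sign(np.sum(np.sign(d[lo:hi])))
    start_sign = filtered[0]
    for i in range(n):
        if filtered[i] == -start_sign:
            return i
    return n  # monotone
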