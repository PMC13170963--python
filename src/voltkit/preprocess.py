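"""Signal conditioning ahead of baseline estimation.

Covers the steps applied before any baseline is fitted: Savitzky-Golay
smoothing of the current series, exclusion of the initial DPV transient,
segmentation of a CV trace into forward and reverse sweeps, and
selection of the most stable scan from a repeated-scan CV series.

Smoothing is applied to currents only; the potential axis is never
filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import InputError, ParameterError
from .io import Mode, Voltammogram

#: Default fraction of DPV points dropped to discard the initial transient.
DEFAULT_TRIM_FRACTION = 0.05


@dataclass(frozen=True)
class SmoothingParams:
    """Savitzky-Golay window length (odd, samples) and polynomial order."""

    window_length: int = 11
    poly_order: int = 3

    def __post_init__(self):
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ParameterError(
                f"window_length must be odd and >= 3, got {self.window_length}"
            )
        if not 0 <= self.poly_order < self.window_length:
            raise ParameterError(
                f"poly_order must be in [0, window_length), got {self.poly_order}"
            )


@dataclass(frozen=True)
class SweepSegmentation:
    """Forward/reverse index ranges of a CV trace (half-open, contiguous)."""

    forward: tuple[int, int]
    reverse: tuple[int, int]
    turning_index: int
    warnings: tuple[str, ...] = ()


def savitzky_golay_smooth(y: np.ndarray, params: SmoothingParams | None = None
                          ) -> np.ndarray:
    """Smooth a current series with a Savitzky-Golay filter.

    Interior points take the centre value of the least-squares polynomial
    of degree ``poly_order`` fitted over the sliding window.  Near the
    ends the window is truncated to the valid one-sided range and the
    polynomial re-fitted there, so polynomial inputs of degree at most
    ``poly_order`` are reproduced exactly everywhere, edges included.
    """
    params = params or SmoothingParams()
    y = np.asarray(y, dtype=float)
    w, d = params.window_length, params.poly_order
    if len(y) < w:
        raise ParameterError(
            f"series of length {len(y)} shorter than window {w}"
        )
    out = savgol_filter(y, w, d, mode="interp")
    half = w // 2
    for i in list(range(half)) + list(range(len(y) - half, len(y))):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        t = np.arange(lo, hi) - i  # centred abscissa, exact small integers
        vand = np.vander(t, N=d + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(vand, y[lo:hi], rcond=None)
        out[i] = coef[0]
    return out


def trim_initial(v: Voltammogram, fraction: float | None = None) -> Voltammogram:
    """Drop the first ``floor(fraction * n)`` points of a trace.

    Used on DPV signals, whose opening samples carry a charging
    transient unrelated to the Faradaic response.  The number of removed
    points is recorded in the returned trace's metadata.
    """
    if fraction is None:
        fraction = DEFAULT_TRIM_FRACTION
    if not 0 <= fraction < 0.5:
        raise ParameterError(f"trim fraction must be in [0, 0.5), got {fraction}")
    k = int(np.floor(fraction * len(v)))
    if k == 0:
        return v.with_currents(v.currents, trimmed_points=0)
    return replace(
        v,
        potentials=v.potentials[k:],
        currents=v.currents[k:],
        meta={**v.meta, "trimmed_points": k, "trim_fraction": fraction},
    )


def split_sweeps(v: Voltammogram) -> SweepSegmentation:
    """Locate the potential reversal of a CV trace.

    The turning point is the global extremum of the potential series
    (maximum for an anodic-first sweep, minimum for cathodic-first),
    which is robust to sample-level jitter in the potential readback.
    A monotone potential yields an empty reverse range plus a warning.
    """
    if v.mode is not Mode.CV:
        raise ParameterError("split_sweeps expects a CV trace")
    p = v.potentials
    n = len(p)
    if n < 3:
        raise InputError("need at least 3 points to segment sweeps")

    anodic_first = np.mean(np.diff(p[: max(2, n // 2)])) >= 0
    turn = int(np.argmax(p)) if anodic_first else int(np.argmin(p))

    warnings: tuple[str, ...] = ()
    if turn >= n - 1 or turn == 0:
        turn = n - 1
        warnings = ("potential is monotone: no reverse sweep found",)
    return SweepSegmentation(
        forward=(0, turn + 1), reverse=(turn + 1, n),
        turning_index=turn, warnings=warnings,
    )


def select_stable_scan(scans: list[Voltammogram]) -> Voltammogram:
    """Pick the scan recorded under the most stable electrode conditions.

    Stability is scored as the mean absolute current difference from the
    following scan (the last scan is compared with its predecessor); the
    scan with the smallest score wins, earliest on ties.  With a single
    scan there is nothing to choose.
    """
    if not scans:
        raise InputError("no scans supplied")
    if len(scans) == 1:
        return scans[0]
    lengths = {len(s) for s in scans}
    if len(lengths) != 1:
        raise InputError("scans must share a common length to be compared")
    scores = []
    for i, s in enumerate(scans):
        other = scans[i + 1] if i < len(scans) - 1 else scans[i - 1]
        scores.append(float(np.mean(np.abs(s.currents - other.currents))))
    return scans[int(np.argmin(scores))]
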