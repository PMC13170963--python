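"""Peak detection on baseline-corrected signals and (v, c, b, d) features.

Every reported peak carries the four quantities used throughout
voltammetric analysis: the peak potential ``v``, the current at the peak
``c`` (read from the signal the baseline was fitted to), the baseline
level at the same index ``b``, and the response ``d = c - b`` — the
vertical peak-to-baseline distance that serves as the analytical
indicator.  By construction ``d`` equals the corrected signal at the
peak index.

Detection keeps strict local maxima (anodic) and minima (cathodic) whose
prominence — height above the higher of the two flanking valleys —
clears a threshold, then enforces a minimum index separation by keeping
peaks greedily in order of descending prominence.  Plateaus resolve to
their leftmost index.  The separation filter operates within each
polarity; an adjacent anodic/cathodic pair is a legitimate redox
couple, not a duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import peak_prominences

from .baseline import BaselineEstimate
from .errors import InputError, NoPeakError, ParameterError
from .io import Voltammogram


class Polarity(str, Enum):
    ANODIC = "anodic"      # oxidation: positive excursion
    CATHODIC = "cathodic"  # reduction: negative excursion
    BOTH = "both"


@dataclass(frozen=True)
class PeakSearchParams:
    """Noise-rejection knobs for peak detection.

    ``min_prominence`` in µA (see :func:`auto_min_prominence` for a
    data-driven choice), ``min_separation`` in samples, and which
    polarity to search.
    """

    min_prominence: float = 0.0
    min_separation: int = 1
    polarity: Polarity = Polarity.BOTH

    def __post_init__(self):
        if self.min_prominence < 0:
            raise ParameterError("min_prominence must be >= 0")
        if self.min_separation < 1:
            raise ParameterError("min_separation must be >= 1")


@dataclass(frozen=True)
class PeakFeature:
    """One detected peak: potential, current, baseline level, response."""

    v: float          # peak potential, V
    c: float          # current at the peak, µA
    b: float          # baseline level at the peak index, µA
    d: float          # response c - b, µA (negative for cathodic peaks)
    index: int
    polarity: Polarity
    prominence: float  # µA

    def to_dict(self) -> dict:
        return {"v": self.v, "c": self.c, "b": self.b, "d": self.d,
                "index": self.index, "polarity": self.polarity.value,
                "prominence": self.prominence}


def auto_min_prominence(corrected: np.ndarray) -> float:
    """Noise-adaptive prominence floor: 3x a robust noise sigma.

    The noise scale is estimated as 1.4826 * MAD of the first
    differences divided by sqrt(2) — differencing cancels the slowly
    varying signal and doubles the noise variance, and the MAD factor
    calibrates to a Gaussian sigma.
    """
    d = np.diff(np.asarray(corrected, dtype=float))
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    return 3.0 * sigma


def _strict_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus yield their leftmost index."""
    idx: list[int] = []
    n = len(y)
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return idx


def _detect_one_polarity(signal: np.ndarray, params: PeakSearchParams
                         ) -> list[int]:
    cand = _strict_maxima(signal)
    if not cand:
        return []
    prom = peak_prominences(signal, cand)[0]
    keep = [(c, p) for c, p in zip(cand, prom) if p >= params.min_prominence]
    # greedy separation filter, strongest prominence first (leftmost on ties)
    keep.sort(key=lambda t: (-t[1], t[0]))
    accepted: list[int] = []
    for c, _ in keep:
        if all(abs(c - a) >= params.min_separation for a in accepted):
            accepted.append(c)
    return sorted(accepted)


def detect_peaks(corrected: np.ndarray, params: PeakSearchParams | None = None
                 ) -> list[int]:
    """Detect peak indices on a baseline-corrected current series.

    Returns a sorted list of indices; empty when nothing clears the
    prominence floor.  Adding a constant to the signal does not change
    the result.
    """
    params = params or PeakSearchParams()
    y = np.asarray(corrected, dtype=float)
    if len(y) < 3:
        raise InputError("need at least 3 points to detect peaks")
    indices: set[int] = set()
    if params.polarity in (Polarity.ANODIC, Polarity.BOTH):
        indices.update(_detect_one_polarity(y, params))
    if params.polarity in (Polarity.CATHODIC, Polarity.BOTH):
        indices.update(_detect_one_polarity(-y, params))
    return sorted(indices)


def _prominence_at(corrected: np.ndarray, i: int) -> float:
    """Prominence of index ``i`` on whichever polarity it is a peak of.

    An index that is not an interior local extremum (possible for
    caller-supplied indices) gets prominence 0.
    """
    n = len(corrected)
    if not 0 < i < n - 1:
        return 0.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sig in (corrected, -corrected):
            if sig[i] >= sig[i - 1] and sig[i] >= sig[i + 1]:
                return float(peak_prominences(sig, [i])[0][0])
    return 0.0


def extract_features(v: Voltammogram, estimate: BaselineEstimate,
                     indices: list[int]) -> list[PeakFeature]:
    """Build (v, c, b, d) features for detected peak indices.

    ``v`` must be the trace the baseline was estimated on, so that
    ``d = c - b`` coincides with the corrected signal at each index.
    Zero response resolves to anodic by the ``d >= 0`` convention.
    """
    n = len(v)
    if len(estimate.baseline) != n:
        raise InputError("baseline estimate does not match trace length")
    features = []
    for i in indices:
        if not 0 <= i < n:
            raise InputError(f"peak index {i} out of range for trace of {n}")
        c = float(v.currents[i])
        b = float(estimate.baseline[i])
        d = c - b
        pol = Polarity.ANODIC if d >= 0 else Polarity.CATHODIC
        prom = _prominence_at(estimate.corrected, i)
        features.append(PeakFeature(
            v=float(v.potentials[i]), c=c, b=b, d=d,
            index=int(i), polarity=pol, prominence=prom,
        ))
    return features


def dominant_peak(features: list[PeakFeature]) -> PeakFeature:
    """The feature with the largest |d|; ties go to the lower potential.

    Raises :class:`NoPeakError` on an empty list so callers can report a
    non-detection distinctly from a processing failure.
    """
    if not features:
        raise NoPeakError("no peak detected")
    return min(features, key=lambda f: (-abs(f.d), f.v))
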