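"""End-to-end processing chains for single CV and DPV traces.

The DPV chain is: initial-transient trim, Savitzky-Golay smoothing,
asymmetric least squares baseline, peak detection on the corrected
signal, dominant-peak selection.  The CV chain is: sweep segmentation,
optional smoothing (off by default — CV grids are coarser and the peaks
broader), segmented-linear or polynomial baseline, then per-sweep peak
search: anodic peaks on the forward sweep, cathodic on the reverse.

Configuration objects collect every knob of the underlying modules so a
report can embed the complete effective parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseline import (AlsParams, BaselineEstimate, BaselineMethod,
                       als_baseline, poly_baseline, segmented_linear_baseline)
from .errors import NoPeakError, ParameterError
from .io import Voltammogram
from .peaks import (PeakFeature, PeakSearchParams, Polarity,
                    auto_min_prominence, detect_peaks, dominant_peak,
                    extract_features)
from .preprocess import (DEFAULT_TRIM_FRACTION, SmoothingParams,
                         SweepSegmentation, savitzky_golay_smooth,
                         select_stable_scan, split_sweeps, trim_initial)


@dataclass(frozen=True)
class DpvConfig:
    """Parameters of the DPV processing chain."""

    trim_fraction: float = DEFAULT_TRIM_FRACTION
    smooth: bool = True
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    als: AlsParams = field(default_factory=AlsParams)
    min_prominence: float | str = "auto"
    min_separation: int = 1

    def to_dict(self) -> dict:
        return {
            "trim": {"fraction": self.trim_fraction},
            "sg": {"enabled": self.smooth,
                   "window": self.smoothing.window_length,
                   "polyorder": self.smoothing.poly_order},
            "als": {"lam": self.als.lam, "p": self.als.p,
                    "max_iter": self.als.max_iter, "tol": self.als.tol},
            "peaks": {"min_prominence": self.min_prominence,
                      "min_separation": self.min_separation},
        }


@dataclass(frozen=True)
class CvConfig:
    """Parameters of the CV processing chain."""

    baseline_method: BaselineMethod = BaselineMethod.SEGMENTED_LINEAR
    poly_degree: int = 2
    edge_fraction: float = 0.2
    smooth: bool = False
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    scan_select: str = "stable"  # first | last | stable
    min_prominence: float | str = "auto"
    min_separation: int = 1

    def to_dict(self) -> dict:
        return {
            "cv": {"baseline": self.baseline_method.value,
                   "poly_degree": self.poly_degree,
                   "edge_fraction": self.edge_fraction,
                   "scan_select": self.scan_select},
            "sg": {"enabled": self.smooth,
                   "window": self.smoothing.window_length,
                   "polyorder": self.smoothing.poly_order},
            "peaks": {"min_prominence": self.min_prominence,
                      "min_separation": self.min_separation},
        }


@dataclass(frozen=True)
class DpvResult:
    trace: Voltammogram            # after trim
    processed: Voltammogram        # after trim + smoothing
    estimate: BaselineEstimate
    features: list[PeakFeature]
    peak: PeakFeature | None       # dominant peak, None on non-detection
    finding: str | None = None


@dataclass(frozen=True)
class CvResult:
    trace: Voltammogram
    processed: Voltammogram
    segmentation: SweepSegmentation
    estimate: BaselineEstimate
    features: list[PeakFeature]
    warnings: tuple[str, ...] = ()


def _resolve_prominence(setting: float | str, corrected: np.ndarray) -> float:
    if setting == "auto":
        return auto_min_prominence(corrected)
    if isinstance(setting, str):
        raise ParameterError(
            f"min_prominence must be a number or 'auto', got {setting!r}"
        )
    return float(setting)


def process_dpv(v: Voltammogram, config: DpvConfig | None = None) -> DpvResult:
    """Run the full DPV chain on one trace.

    A trace in which no peak clears the prominence floor yields a result
    with ``peak=None`` and an explanatory finding, not an exception.
    """
    config = config or DpvConfig()
    trimmed = trim_initial(v, config.trim_fraction)
    if config.smooth:
        processed = trimmed.with_currents(
            savitzky_golay_smooth(trimmed.currents, config.smoothing),
            smoothed=True,
        )
    else:
        processed = trimmed
    estimate = als_baseline(processed.currents, config.als)
    prom = _resolve_prominence(config.min_prominence, estimate.corrected)
    params = PeakSearchParams(min_prominence=prom,
                              min_separation=config.min_separation,
                              polarity=Polarity.BOTH)
    indices = detect_peaks(estimate.corrected, params)
    features = extract_features(processed, estimate, indices)
    try:
        peak = dominant_peak(features)
        finding = None
    except NoPeakError:
        peak, finding = None, "no peak detected"
    return DpvResult(trace=trimmed, processed=processed, estimate=estimate,
                     features=features, peak=peak, finding=finding)


def process_cv(v: Voltammogram | list[Voltammogram],
               config: CvConfig | None = None) -> CvResult:
    """Run the full CV chain on one trace (or pick one from several scans)."""
    config = config or CvConfig()
    if isinstance(v, list):
        if config.scan_select == "first":
            v = v[0]
        elif config.scan_select == "last":
            v = v[-1]
        else:
            v = select_stable_scan(v)
    seg = split_sweeps(v)
    warnings = list(seg.warnings)
    if config.smooth:
        processed = v.with_currents(
            savitzky_golay_smooth(v.currents, config.smoothing), smoothed=True)
    else:
        processed = v
    if config.baseline_method is BaselineMethod.POLY:
        estimate = poly_baseline(processed.potentials, processed.currents,
                                 config.poly_degree)
    else:
        estimate = segmented_linear_baseline(processed, seg,
                                             config.edge_fraction)
    warnings += estimate.diagnostics.get("warnings", [])

    prom = _resolve_prominence(config.min_prominence, estimate.corrected)
    indices: list[int] = []
    for (lo, hi), polarity in ((seg.forward, Polarity.ANODIC),
                               (seg.reverse, Polarity.CATHODIC)):
        if hi - lo < 3:
            continue
        params = PeakSearchParams(min_prominence=prom,
                                  min_separation=config.min_separation,
                                  polarity=polarity)
        indices += [lo + i for i in detect_peaks(estimate.corrected[lo:hi],
                                                 params)]
    features = extract_features(processed, estimate, sorted(indices))
    return CvResult(trace=v, processed=processed, segmentation=seg,
                    estimate=estimate, features=features,
                    warnings=tuple(warnings))
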