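"""Threshold classification of the peak response and DPV comparison.

The response ``d`` (peak current minus baseline level, µA) is compared
with a user-supplied threshold: strictly above means a high
electrochemical response ("high_potential", result True), at or below
means a low response ("low_potential", result False).  The labels grade
electrochemical activity only — they are not a clinical diagnosis, and
no default threshold is shipped so that none is implied.

For DPV, a reference and a sample trace are processed independently
through the same chain and reported side by side together with
``delta_d``, the sample response minus the reference response.  The
reference does not set the threshold; it is analysed symmetrically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .errors import ParameterError, ValidationError
from .io import Mode, Voltammogram
from .peaks import PeakFeature, Polarity
from .pipeline import DpvConfig, DpvResult, process_dpv

LABEL_HIGH = "high_potential"
LABEL_LOW = "low_potential"


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the threshold rule for one response value."""

    d: float
    threshold: float
    label: str
    result: bool

    def to_dict(self) -> dict:
        return {"d": self.d, "threshold": self.threshold,
                "label": self.label, "result": self.result}

    @classmethod
    def from_dict(cls, payload: dict) -> "ClassificationResult":
        return cls(**payload)


def classify_response(d: float, threshold: float) -> ClassificationResult:
    """Apply the threshold rule: d > threshold is high, d <= threshold low."""
    if not (math.isfinite(d) and math.isfinite(threshold)):
        raise ValidationError("response and threshold must be finite")
    result = d > threshold
    return ClassificationResult(
        d=float(d), threshold=float(threshold),
        label=LABEL_HIGH if result else LABEL_LOW, result=result,
    )


@dataclass(frozen=True)
class TraceReport:
    """One trace's analysis: dominant peak, classification, provenance."""

    mode: str
    source_id: str
    peak: PeakFeature | None
    classification: ClassificationResult | None
    finding: str | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "source_id": self.source_id,
            "peak": self.peak.to_dict() if self.peak else None,
            "classification": (self.classification.to_dict()
                               if self.classification else None),
            "finding": self.finding,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TraceReport":
        peak = payload.get("peak")
        cls_ = payload.get("classification")
        return cls(
            mode=payload["mode"], source_id=payload["source_id"],
            peak=PeakFeature(**{**peak, "polarity": Polarity(peak["polarity"])})
            if peak else None,
            classification=ClassificationResult.from_dict(cls_) if cls_ else None,
            finding=payload.get("finding"),
        )


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side DPV reference/sample analysis."""

    reference: TraceReport
    sample: TraceReport
    delta_d: float | None  # sample d - reference d; None on non-detection
    threshold: float
    params: dict

    def to_dict(self) -> dict:
        return {"reference": self.reference.to_dict(),
                "sample": self.sample.to_dict(),
                "delta_d": self.delta_d, "threshold": self.threshold,
                "params": self.params}

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, payload: dict) -> "ComparisonReport":
        return cls(
            reference=TraceReport.from_dict(payload["reference"]),
            sample=TraceReport.from_dict(payload["sample"]),
            delta_d=payload["delta_d"], threshold=payload["threshold"],
            params=payload["params"],
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls.from_dict(json.loads(text))


def _trace_report(v: Voltammogram, result: DpvResult, threshold: float
                  ) -> TraceReport:
    classification = (classify_response(result.peak.d, threshold)
                      if result.peak is not None else None)
    return TraceReport(mode=Mode.DPV.value, source_id=v.source_id,
                       peak=result.peak, classification=classification,
                       finding=result.finding)


def compare_dpv(reference: Voltammogram, sample: Voltammogram,
                threshold: float, config: DpvConfig | None = None
                ) -> ComparisonReport:
    """Process reference and sample DPV traces and compare responses.

    Each trace runs through the full chain (trim, smooth, ALS baseline,
    dominant peak, classification) independently.  A non-detection in
    either trace is embedded as a finding in that trace's report and
    ``delta_d`` becomes None; processing never aborts on a missing peak.
    """
    if reference.mode is not Mode.DPV or sample.mode is not Mode.DPV:
        raise ParameterError("compare_dpv requires two DPV traces")
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    config = config or DpvConfig()
    ref_result = process_dpv(reference, config)
    sam_result = process_dpv(sample, config)
    delta = (sam_result.peak.d - ref_result.peak.d
             if ref_result.peak is not None and sam_result.peak is not None
             else None)
    return ComparisonReport(
        reference=_trace_report(reference, ref_result, threshold),
        sample=_trace_report(sample, sam_result, threshold),
        delta_d=delta, threshold=float(threshold), params=config.to_dict(),
    )
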