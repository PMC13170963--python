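"""Run configuration: JSON config files merged with CLI overrides.

A config file is a nested JSON object using the documented key groups::

    {
      "sg":    {"window": 11, "polyorder": 3, "enabled": true},
      "dpv":   {"trim_fraction": 0.05},
      "cv":    {"baseline": "segmented_linear", "poly_degree": 2,
                "edge_fraction": 0.2, "scan_select": "stable"},
      "als":   {"lam": 1e7, "p": 0.01, "max_iter": 50, "tol": 0.0},
      "peaks": {"min_prominence": "auto", "min_separation": 1}
    }

Precedence is CLI flag over config file over built-in default.  Unknown
keys are rejected before any computation starts.
"""

from __future__ import annotations

import json
from pathlib import Path

from .baseline import AlsParams, BaselineMethod
from .errors import ParameterError
from .pipeline import CvConfig, DpvConfig
from .preprocess import SmoothingParams

_KNOWN = {
    "sg": {"window", "polyorder", "enabled"},
    "dpv": {"trim_fraction"},
    "cv": {"baseline", "poly_degree", "edge_fraction", "scan_select"},
    "als": {"lam", "p", "max_iter", "tol"},
    "peaks": {"min_prominence", "min_separation"},
}


def load_config_file(path: str | Path | None) -> dict:
    if path is None:
        return {}
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParameterError(f"config file {path} is not valid JSON: {exc}")
    if not isinstance(payload, dict):
        raise ParameterError("config file must contain a JSON object")
    validate_keys(payload)
    return payload


def validate_keys(cfg: dict) -> None:
    for group, values in cfg.items():
        if group not in _KNOWN:
            raise ParameterError(f"unknown config group {group!r}")
        if not isinstance(values, dict):
            raise ParameterError(f"config group {group!r} must be an object")
        unknown = set(values) - _KNOWN[group]
        if unknown:
            raise ParameterError(
                f"unknown key(s) in {group!r}: {', '.join(sorted(unknown))}"
            )


def _merge(cfg: dict, overrides: dict) -> dict:
    merged = {g: dict(v) for g, v in cfg.items()}
    for dotted, value in overrides.items():
        if value is None:
            continue
        group, key = dotted.split(".", 1)
        merged.setdefault(group, {})[key] = value
    validate_keys(merged)
    return merged


def _smoothing(cfg: dict, default_enabled: bool
               ) -> tuple[bool, SmoothingParams]:
    sg = cfg.get("sg", {})
    params = SmoothingParams(window_length=int(sg.get("window", 11)),
                             poly_order=int(sg.get("polyorder", 3)))
    return bool(sg.get("enabled", default_enabled)), params


def dpv_config(cfg: dict | None = None, **overrides) -> DpvConfig:
    """Build a :class:`DpvConfig` from a nested mapping plus overrides.

    Overrides use dotted keys, e.g. ``**{"als.lam": 1e6}``.
    """
    merged = _merge(cfg or {}, overrides)
    enabled, sg = _smoothing(merged, default_enabled=True)
    als_cfg = merged.get("als", {})
    peaks = merged.get("peaks", {})
    prom = peaks.get("min_prominence", "auto")
    return DpvConfig(
        trim_fraction=float(merged.get("dpv", {}).get("trim_fraction", 0.05)),
        smooth=enabled,
        smoothing=sg,
        als=AlsParams(lam=float(als_cfg.get("lam", 1e7)),
                      p=float(als_cfg.get("p", 0.01)),
                      max_iter=int(als_cfg.get("max_iter", 50)),
                      tol=float(als_cfg.get("tol", 0.0))),
        min_prominence=prom if prom == "auto" else float(prom),
        min_separation=int(peaks.get("min_separation", 1)),
    )


def cv_config(cfg: dict | None = None, **overrides) -> CvConfig:
    """Build a :class:`CvConfig` from a nested mapping plus overrides."""
    merged = _merge(cfg or {}, overrides)
    enabled, sg = _smoothing(merged, default_enabled=False)
    cv = merged.get("cv", {})
    peaks = merged.get("peaks", {})
    prom = peaks.get("min_prominence", "auto")
    try:
        method = BaselineMethod(cv.get("baseline", "segmented_linear"))
    except ValueError:
        raise ParameterError(
            f"cv.baseline must be 'segmented_linear' or 'poly', "
            f"got {cv.get('baseline')!r}"
        )
    scan_select = cv.get("scan_select", "stable")
    if scan_select not in ("first", "last", "stable"):
        raise ParameterError(
            f"cv.scan_select must be first|last|stable, got {scan_select!r}"
        )
    return CvConfig(
        baseline_method=method,
        poly_degree=int(cv.get("poly_degree", 2)),
        edge_fraction=float(cv.get("edge_fraction", 0.2)),
        smooth=enabled,
        smoothing=sg,
        scan_select=scan_select,
        min_prominence=prom if prom == "auto" else float(prom),
        min_separation=int(peaks.get("min_separation", 1)),
    )
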