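"""Seeded synthetic voltammograms with known ground truth.

Every stage of the toolkit is testable without instrument data: the
generators emulate the morphology of real traces — a Gaussian Faradaic
peak on a smooth background — with closed-form ground truth returned
alongside.  A DPV trace is a single positive Gaussian peak on a linear
drift plus an exponentially decaying initial transient; a CV trace is a
triangular potential sweep with an anodic Gaussian on the forward leg, a
cathodic (negative) Gaussian on the reverse leg, a capacitive offset
whose sign flips with sweep direction, and a common linear drift.
Gaussian peak shapes are a deliberate simplification over
electrochemical theory shapes; they give exact ground truth for
recovery experiments but do not reproduce the asymmetric tailing of
real diffusion-limited peaks.

Defaults describe a realistic screen-printed-electrode measurement:
currents of a few µA over a fraction-of-a-volt window, the 5 mV
potential step typical of DPV step increments and CV exports, peak
amplitude 5 µA with 0.1 µA noise (signal-to-noise ratio 50).
All randomness flows from each generator dataclass's ``seed`` field
through ``numpy``'s default generator, so traces are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io import Mode, Voltammogram, write_voltammogram


@dataclass(frozen=True)
class DpvSpec:
    """Generating parameters of a synthetic DPV trace (V, µA units)."""

    v_start: float = 0.0
    v_end: float = 0.6
    n_points: int = 121
    peak_center: float = 0.3
    peak_amplitude: float = 5.0
    peak_width: float = 0.05        # Gaussian sigma, V
    bg_intercept: float = 1.0       # µA
    bg_slope: float = 2.0           # µA/V
    bg_decay_amplitude: float = 3.0  # initial transient, µA
    bg_decay_rate: float = 30.0     # 1/V
    noise_sigma: float = 0.1        # µA
    seed: int = 0

    def __post_init__(self):
        if not self.v_start < self.v_end:
            raise ParameterError("v_start must be below v_end")
        if self.n_points < 16:
            raise ParameterError("n_points must be >= 16")
        if not self.peak_width > 0:
            raise ParameterError("peak_width must be > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class CvSpec:
    """Generating parameters of a synthetic CV trace (V, µA units)."""

    v_min: float = -0.2
    v_max: float = 0.8
    n_per_sweep: int = 201
    anodic_center: float = 0.3
    anodic_amplitude: float = 5.0
    anodic_width: float = 0.08
    cathodic_center: float = 0.2
    cathodic_amplitude: float = 5.0
    cathodic_width: float = 0.08
    capacitive_offset: float = 1.0  # µA; sign flips with sweep direction
    drift_slope: float = 2.0        # µA/V
    noise_sigma: float = 0.1        # µA
    seed: int = 0

    def __post_init__(self):
        if not self.v_min < self.v_max:
            raise ParameterError("v_min must be below v_max")
        if self.n_per_sweep < 8:
            raise ParameterError("n_per_sweep must be >= 8")
        if self.anodic_amplitude < 0 or self.cathodic_amplitude < 0:
            raise ParameterError("amplitudes must be >= 0")
        if self.anodic_width <= 0 or self.cathodic_width <= 0:
            raise ParameterError("widths must be > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a trace."""

    spec: dict                 # generating parameters
    background: np.ndarray     # background current without peak or noise, µA
    peak_signal: np.ndarray    # pure peak term(s), µA
    peak_index: int            # on-grid index of the (anodic) peak centre


def _gauss(v: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((v - center) ** 2) / (2.0 * width ** 2))


def simulate_dpv(spec: DpvSpec | None = None
                 ) -> tuple[Voltammogram, GroundTruth]:
    """Generate one DPV trace; deterministic for a given seed."""
    spec = spec or DpvSpec()
    v = np.linspace(spec.v_start, spec.v_end, spec.n_points)
    background = (spec.bg_intercept + spec.bg_slope * v
                  + spec.bg_decay_amplitude
                  * np.exp(-spec.bg_decay_rate * (v - spec.v_start)))
    peak = spec.peak_amplitude * _gauss(v, spec.peak_center, spec.peak_width)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, spec.n_points)
    trace = Voltammogram(v, background + peak + noise, mode=Mode.DPV,
                         source_id=f"synthetic-dpv-seed{spec.seed}")
    truth = GroundTruth(spec=asdict(spec), background=background,
                        peak_signal=peak,
                        peak_index=int(np.argmin(np.abs(v - spec.peak_center))))
    return trace, truth


def simulate_cv(spec: CvSpec | None = None
                ) -> tuple[Voltammogram, GroundTruth]:
    """Generate one triangular-sweep CV trace; deterministic per seed."""
    spec = spec or CvSpec()
    fwd = np.linspace(spec.v_min, spec.v_max, spec.n_per_sweep)
    rev = fwd[::-1][1:]  # the apex potential appears once
    v = np.concatenate([fwd, rev])
    anodic = spec.anodic_amplitude * _gauss(fwd, spec.anodic_center,
                                            spec.anodic_width)
    cathodic = spec.cathodic_amplitude * _gauss(rev, spec.cathodic_center,
                                                spec.cathodic_width)
    background = np.concatenate([
        spec.capacitive_offset + spec.drift_slope * fwd,
        -spec.capacitive_offset + spec.drift_slope * rev,
    ])
    peaks = np.concatenate([anodic, -cathodic])
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, len(v))
    trace = Voltammogram(v, background + peaks + noise, mode=Mode.CV,
                         source_id=f"synthetic-cv-seed{spec.seed}")
    truth = GroundTruth(
        spec=asdict(spec), background=background, peak_signal=peaks,
        peak_index=int(np.argmin(np.abs(fwd - spec.anodic_center))),
    )
    return trace, truth


# Per-fixture seed offsets: a master seed plus fixed offsets keeps the
# catalogue stable if entries are appended later.
_FIXTURE_OFFSETS = {
    "dpv_clean": 11,
    "dpv_reference": 23,
    "dpv_sample": 31,
    "cv_drift": 47,
    "cv_monotone": 59,
    "dpv_no_header": 61,
}


def make_fixture_suite(out_dir: str | Path, master_seed: int = 0) -> dict:
    """Write a catalogue of CSV fixtures plus a JSON ground-truth manifest.

    The catalogue covers the cases the reader and pipelines must face:
    a clean DPV trace, a reference/sample DPV pair with amplitudes 2 and
    8 µA over a shared background at 0.05 µA noise, a drifting CV trace,
    a degenerate monotone-potential "CV" trace, and a header-free file
    variant.  Reproducible byte-for-byte from ``master_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: int(master_seed) + off
             for name, off in _FIXTURE_OFFSETS.items()}

    entries: dict[str, dict] = {}

    def _emit(name: str, trace: Voltammogram, truth: GroundTruth | None,
              header: bool = True) -> None:
        path = out / f"{name}.csv"
        if header:
            write_voltammogram(trace, path)
        else:
            lines = [f"{p:.9f},{c:.9f}"
                     for p, c in zip(trace.potentials, trace.currents)]
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        entries[name] = {
            "file": path.name,
            "mode": trace.mode.value,
            "has_header": header,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            "ground_truth": truth.spec if truth else None,
        }

    trace, truth = simulate_dpv(DpvSpec(seed=seeds["dpv_clean"],
                                        noise_sigma=0.0))
    _emit("dpv_clean", trace, truth)

    ref_spec = DpvSpec(seed=seeds["dpv_reference"], peak_amplitude=2.0,
                       noise_sigma=0.05)
    sam_spec = DpvSpec(seed=seeds["dpv_sample"], peak_amplitude=8.0,
                       noise_sigma=0.05)
    for name, spec in (("dpv_reference", ref_spec), ("dpv_sample", sam_spec)):
        trace, truth = simulate_dpv(spec)
        _emit(name, trace, truth)

    trace, truth = simulate_cv(CvSpec(seed=seeds["cv_drift"]))
    _emit("cv_drift", trace, truth)

    # degenerate: monotone ramp labelled CV — must trip the sweep warning
    ramp_v = np.linspace(0.0, 1.0, 50)
    rng = np.random.default_rng(seeds["cv_monotone"])
    ramp = Voltammogram(ramp_v, 1.0 + 2.0 * ramp_v + rng.normal(0, 0.05, 50),
                        mode=Mode.CV, source_id="synthetic-cv-monotone")
    _emit("cv_monotone", ramp, None)

    trace, truth = simulate_dpv(DpvSpec(seed=seeds["dpv_no_header"]))
    _emit("dpv_no_header", trace, truth, header=False)

    manifest = {"master_seed": int(master_seed), "fixtures": entries}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest
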