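"""Annotated voltammogram plots: signal, baseline, peak marker, response.

Each plot shows the processed current trace, the fitted baseline curve,
a marker at every detected peak (v, c) and a dashed vertical segment of
length d from the baseline level up (or down) to the peak — the same
annotations used to verify baseline estimation and peak detection by
eye.  Static image output only.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import CvResult, DpvResult  # noqa: E402


def _annotate(ax, potentials, result):
    ax.plot(potentials, result.processed.currents, lw=1.0, color="C0",
            label="signal")
    ax.plot(potentials, result.estimate.baseline, lw=1.0, color="C1",
            ls="--", label="baseline")
    for f in result.features:
        ax.plot([f.v], [f.c], "v" if f.polarity.value == "cathodic" else "^",
                color="C3", ms=7)
        ax.plot([f.v, f.v], [f.b, f.c], color="C3", ls=":", lw=1.2)
    ax.set_xlabel("potential (V)")
    ax.set_ylabel("current (µA)")
    ax.legend(loc="best", fontsize=8)


def plot_dpv(result: DpvResult, dest: str | Path, title: str = "DPV analysis"
             ) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    _annotate(ax, result.processed.potentials, result)
    if result.peak is not None:
        ax.annotate(f"d = {result.peak.d:.3f} µA",
                    xy=(result.peak.v, result.peak.c),
                    xytext=(5, 5), textcoords="offset points", fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(dest, dpi=120)
    plt.close(fig)
    return Path(dest)


def plot_cv(result: CvResult, dest: str | Path, title: str = "CV analysis"
            ) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    _annotate(ax, result.processed.potentials, result)
    ax.set_title(title)
    fig.tight_layout()
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(dest, dpi=120)
    plt.close(fig)
    return Path(dest)
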