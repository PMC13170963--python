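"""Reading, validating and writing potential-current datasets.

A voltammogram is stored on disk as a plain comma-separated file whose
first column is the applied potential in volts and second column the
measured current in microamps, optionally preceded by a single header
line.  Values are kept in the units found in the file; nothing is
rescaled on read.

Restrictions (documented, not silently worked around): the delimiter is
a comma unless another is passed explicitly, and locale decimal commas
are not supported.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from enum import Enum
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

from .errors import InputError, ParseError, ValidationError

Source = Union[str, PathLike, IO[str]]

CSV_HEADER = "potential_V,current_uA"


class Mode(str, Enum):
    """Measurement mode of a voltammogram."""

    CV = "CV"
    DPV = "DPV"


@dataclass(frozen=True)
class Voltammogram:
    """An ordered series of (potential, current) points.

    Parameters
    ----------
    potentials : array of applied potential, volts.
    currents : array of measured current, microamps, same length.
    mode : :class:`Mode`, cyclic or differential pulse voltammetry.
    source_id : free-text provenance label (file name, instrument id).
    scan_index : which CV scan this trace is, when several were recorded.
    meta : processing breadcrumbs (e.g. number of trimmed points).
    """

    potentials: np.ndarray
    currents: np.ndarray
    mode: Mode
    source_id: str = ""
    scan_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.potentials, dtype=float)
        c = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "potentials", p)
        object.__setattr__(self, "currents", c)
        if p.ndim != 1 or c.ndim != 1:
            raise ValidationError("potential and current series must be 1-D")
        if len(p) != len(c):
            raise ValidationError(
                f"length mismatch: {len(p)} potentials vs {len(c)} currents"
            )
        if len(p) < 2:
            raise InputError("a voltammogram needs at least 2 points")
        if not (np.isfinite(p).all() and np.isfinite(c).all()):
            raise ValidationError("non-finite value in voltammogram")

    def __len__(self) -> int:
        return len(self.potentials)

    def with_currents(self, currents: np.ndarray, **meta) -> "Voltammogram":
        """Copy of this trace with a replaced current series."""
        return replace(self, currents=np.asarray(currents, dtype=float),
                       meta={**self.meta, **meta})


@dataclass(frozen=True)
class DatasetBundle:
    """One measurement's worth of input data.

    CV analyses use a single trace.  DPV comparisons pair a sample trace
    with a reference trace measured under the same conditions.
    """

    primary: Voltammogram
    reference: Voltammogram | None = None


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is ``'error'`` or ``'warning'``."""

    severity: str
    code: str
    message: str


def _looks_numeric(cells: Iterable[str]) -> bool:
    try:
        for cell in cells:
            float(cell)
    except (TypeError, ValueError):
        return False
    return True


def read_voltammogram(
    source: Source,
    mode: Mode | str,
    *,
    delimiter: str = ",",
    source_id: str | None = None,
) -> Voltammogram:
    """Read a potential-current CSV into a :class:`Voltammogram`.

    The first column is taken as potential (V), the second as current
    (µA); extra columns are ignored.  A single non-numeric first line is
    treated as a header and skipped; a numeric first line is data.  Row
    order in the file is preserved exactly.
    """
    mode = Mode(mode)
    if source_id is None:
        source_id = str(source) if isinstance(source, (str, PathLike)) else "<stream>"

    if isinstance(source, (str, PathLike)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    if not text.strip():
        raise InputError(f"empty input: {source_id}")

    try:
        frame = pd.read_csv(
            _io.StringIO(text), sep=delimiter, header=None, dtype=str,
            skip_blank_lines=True, skipinitialspace=True, engine="python",
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed CSV in {source_id}: {exc}") from exc

    if frame.shape[1] < 2:
        raise InputError(
            f"{source_id}: need at least 2 columns (potential, current), "
            f"got {frame.shape[1]}"
        )

    header_rows = 0
    first = frame.iloc[0, :2].tolist()
    if not _looks_numeric(first):
        header_rows = 1
    body = frame.iloc[header_rows:, :2]
    if len(body) < 2:
        raise InputError(f"{source_id}: fewer than 2 data rows")

    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(np.isnan(values))
    if bad[0].size:
        r, c = int(bad[0][0]), int(bad[1][0])
        row_in_file = r + header_rows + 1  # 1-based, counting the header line
        cell = body.iat[r, c]
        detail = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
        raise ParseError(
            f"{source_id}: {detail} at row {row_in_file}, column {c + 1}",
            row=row_in_file,
        )
    if not np.isfinite(values).all():
        raise ValidationError(f"{source_id}: non-finite value in data")

    return Voltammogram(values[:, 0], values[:, 1], mode=mode, source_id=source_id)


def write_voltammogram(v: Voltammogram, dest: str | PathLike) -> None:
    """Write a voltammogram as CSV with header ``potential_V,current_uA``.

    Fixed-point formatting with nine decimals keeps the read-write round
    trip within 1e-9 absolute on both columns.
    """
    lines = [CSV_HEADER]
    lines += [f"{p:.9f},{c:.9f}" for p, c in zip(v.potentials, v.currents)]
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_bundle(
    bundle: DatasetBundle, *, comparison_requested: bool = False
) -> list[Finding]:
    """Check a dataset bundle for format and completeness problems.

    Returns findings rather than raising: callers decide whether a
    warning is acceptable.  An empty list means the bundle is clean.
    """
    findings: list[Finding] = []
    primary = bundle.primary

    if primary.mode is Mode.DPV:
        if comparison_requested and bundle.reference is None:
            findings.append(Finding(
                "error", "missing-reference",
                "DPV comparison requested but no reference dataset supplied",
            ))
        dp = np.diff(primary.potentials)
        if not (np.all(dp > 0) or np.all(dp < 0)):
            findings.append(Finding(
                "warning", "non-monotone-potential",
                "DPV potential series is not strictly monotonic",
            ))
    else:  # CV
        if bundle.reference is not None:
            findings.append(Finding(
                "error", "unexpected-reference",
                "CV bundles do not carry a reference dataset",
            ))
        dp = np.diff(primary.potentials)
        if np.all(dp >= 0) or np.all(dp <= 0):
            findings.append(Finding(
                "warning", "no-sweep-reversal",
                "CV potential is monotone: no sweep reversal found",
            ))

    if bundle.reference is not None and bundle.reference.mode is not primary.mode:
        findings.append(Finding(
            "error", "mode-mismatch",
            "reference and primary datasets have different modes",
        ))
    return findings
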