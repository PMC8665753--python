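"""Spectrum CSV input/output and the JSON session format.

Spectra arrive as two-column CSV (m/z, intensity) as exported by vendor
software (MassLynx, Xcalibur).  On load the rows are sorted by m/z,
duplicate m/z bins are collapsed by summing, and intensities are normalized
to percent of base peak (max = 100) unless disabled.

A *session* is a self-contained, shareable record of an analysis: the raw
spectrum as loaded, the ordered processing log (replayable bit-for-bit),
the assigned charge series, and free-text annotations — serialized as a
versioned JSON document.  Unknown top-level keys in a loaded document are
preserved on re-save for forward compatibility.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, IO, Iterable, Mapping, Union

import numpy as np

from .assign import ChargeSeries
from .exceptions import SessionSchemaError, SpectrumFormatError
from .preprocess import ProcessingStep, apply_steps
from .spectrum import Spectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "Session",
    "save_session",
    "load_session",
    "export_series_table",
    "FORMAT_VERSION",
]

#: Session schema version.  Major mismatch on load is an error.
FORMAT_VERSION = "1.0"

PathLike = Union[str, Path]


def _parse_rows(lines: Iterable[str]) -> tuple[list[float], list[float]]:
    mz: list[float] = []
    inten: list[float] = []
    reader = csv.reader(lines)
    n_seen = 0
    for lineno, row in enumerate(reader, start=1):
        cells = [c.strip() for c in row]
        if not cells or all(c == "" for c in cells):
            continue  # blank line
        if len(cells) != 2:
            raise SpectrumFormatError(
                f"expected 2 columns, found {len(cells)}", line=lineno
            )
        try:
            x, y = float(cells[0]), float(cells[1])
        except ValueError:
            if lineno == 1:
                continue  # a single header row is tolerated and skipped
            raise SpectrumFormatError(
                f"non-numeric values {cells[0]!r}, {cells[1]!r}", line=lineno
            ) from None
        mz.append(x)
        inten.append(y)
        n_seen += 1
    if n_seen == 0:
        raise SpectrumFormatError("no data rows found")
    if n_seen < 2:
        raise SpectrumFormatError(f"need at least 2 data rows, found {n_seen}")
    return mz, inten


def read_spectrum_csv(source: Union[PathLike, IO[str]], normalize: bool = True) -> Spectrum:
    """Read a two-column (m/z, intensity) CSV into a :class:`Spectrum`.

    One header row is tolerated (skipped iff either of its cells fails
    numeric parsing).  Rows are sorted ascending by m/z; duplicate m/z bins
    are collapsed by summing their intensities (centroided exports can
    repeat bins).  With ``normalize`` (default) intensities are scaled so
    the base peak equals 100.
    """
    if hasattr(source, "read"):
        mz, inten = _parse_rows(source)
    else:
        with open(source, "r", newline="") as fh:
            mz, inten = _parse_rows(fh)
    mz_arr = np.asarray(mz, dtype=float)
    in_arr = np.asarray(inten, dtype=float)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, in_arr = mz_arr[order], in_arr[order]
    # collapse duplicate m/z bins by summing
    uniq, inverse = np.unique(mz_arr, return_inverse=True)
    if uniq.size != mz_arr.size:
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, in_arr)
        mz_arr, in_arr = uniq, summed
    s = Spectrum(mz_arr, in_arr)
    return s.normalized() if normalize else s


def write_spectrum_csv(s: Spectrum, path: Union[PathLike, IO[str]],
                       header: bool = True) -> None:
    """Write a spectrum as two-column CSV (inverse of :func:`read_spectrum_csv`)."""

    def _write(fh: IO[str]) -> None:
        if header:
            fh.write("m/z,intensity\n")
        for x, y in zip(s.mz, s.intensity):
            fh.write(f"{x:.10g},{y:.10g}\n")

    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w", newline="") as fh:
            _write(fh)


@dataclass
class Session:
    """A complete, replayable analysis record.

    ``raw_spectrum`` is the spectrum as loaded (post-normalization);
    replaying ``processing`` on it reproduces the working spectrum
    deterministically.  ``extra`` holds unknown top-level keys from a
    loaded document, written back verbatim on save.
    """

    raw_spectrum: Spectrum
    processing: list[ProcessingStep] = field(default_factory=list)
    series: list[ChargeSeries] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)
    format_version: str = FORMAT_VERSION
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.series]
        if len(set(names)) != len(names):
            raise SessionSchemaError(f"series names must be unique, got {names}")

    @property
    def working_spectrum(self) -> Spectrum:
        """The processed spectrum: the processing log replayed on the raw data."""
        return apply_steps(self.raw_spectrum, self.processing)

    def add_series(self, series: ChargeSeries) -> None:
        if any(s.name == series.name for s in self.series):
            raise SessionSchemaError(f"series name {series.name!r} already in session")
        self.series.append(series)

    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = dict(self.extra)
        doc.update(
            {
                "format_version": self.format_version,
                "raw_spectrum": {
                    "mz": self.raw_spectrum.mz.tolist(),
                    "intensity": self.raw_spectrum.intensity.tolist(),
                },
                "processing": [st.to_dict() for st in self.processing],
                "series": [se.to_dict() for se in self.series],
                "annotations": dict(self.annotations),
            }
        )
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "Session":
        required = ["format_version", "raw_spectrum", "processing", "series",
                    "annotations"]
        missing = [k for k in required if k not in doc]
        if missing:
            raise SessionSchemaError("session document is incomplete", missing=missing)
        version = str(doc["format_version"])
        major = version.split(".", 1)[0]
        if major != FORMAT_VERSION.split(".", 1)[0]:
            raise SessionSchemaError(
                f"unsupported session format_version {version!r} "
                f"(this package reads major version {FORMAT_VERSION.split('.')[0]})"
            )
        raw = doc["raw_spectrum"]
        if not isinstance(raw, Mapping) or "mz" not in raw or "intensity" not in raw:
            raise SessionSchemaError(
                "raw_spectrum must be an object with keys mz and intensity",
                missing=[k for k in ("mz", "intensity")
                         if not isinstance(raw, Mapping) or k not in raw],
            )
        extra = {k: v for k, v in doc.items() if k not in required}
        return cls(
            raw_spectrum=Spectrum(np.asarray(raw["mz"], dtype=float),
                                  np.asarray(raw["intensity"], dtype=float)),
            processing=[ProcessingStep.from_dict(st) for st in doc["processing"]],
            series=[ChargeSeries.from_dict(se) for se in doc["series"]],
            annotations=dict(doc["annotations"]),
            format_version=version,
            extra=extra,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.raw_spectrum == other.raw_spectrum
            and self.processing == other.processing
            and self.series == other.series
            and self.annotations == other.annotations
            and self.format_version == other.format_version
            and self.extra == other.extra
        )


def save_session(session: Session, path: Union[PathLike, IO[str]]) -> None:
    """Write a session as UTF-8 JSON.  ``repr``-precision floats round-trip."""
    doc = session.to_dict()
    if hasattr(path, "write"):
        json.dump(doc, path, indent=1)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


def load_session(path: Union[PathLike, IO[str]]) -> Session:
    """Read a session JSON document (see :meth:`Session.from_dict` for checks)."""
    if hasattr(path, "read"):
        doc = json.load(path)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    if not isinstance(doc, Mapping):
        raise SessionSchemaError("session file must contain a JSON object")
    return Session.from_dict(doc)


#: Fixed header of the per-series summary table.
SERIES_TABLE_HEADER = ("name", "n_peaks", "charge_min", "charge_max",
                       "mass_Da", "uncertainty_Da")


def export_series_table(session: Session, path: Union[PathLike, IO[str]]) -> None:
    """Write a TSV summary, one row per assigned series, in insertion order."""

    def _write(fh: IO[str]) -> None:
        fh.write("\t".join(SERIES_TABLE_HEADER) + "\n")
        for se in session.series:
            fh.write(
                f"{se.name}\t{len(se.peaks)}\t{se.charge_min}\t{se.charge_max}"
                f"\t{se.mass:.2f}\t{se.uncertainty:.2f}\n"
            )

    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            _write(fh)
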