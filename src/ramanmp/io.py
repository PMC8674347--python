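"""Text-format readers and writers for spectra, maps, libraries, reports.

Two map dialects are supported:

``csv``
    Header ``x,y,wn1,...,wnN`` where the wavenumber columns are named by
    their cm⁻¹ value; one row per pixel.

``labspec_ascii``
    Tab-separated export in the style of point-by-point mapping software:
    the first row carries the wavenumber axis with the first two cells
    empty, every following row is ``x<TAB>y<TAB>intensities...``.

Maps may be arbitrary masked subsets of the lattice (the scanned regions
need not be rectangles).  Analytical reports are written as JSON with
per-class counts, per-particle records (including a representative
spectrum), the QC block and full provenance.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Iterable

import numpy as np

from .spectra import (
    CLASSES,
    DEFAULT_FILTER_AREA_MM2,
    LabelError,
    SpectralMap,
    Spectrum,
    TrainingLibrary,
)


class FormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


def _fmt(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips,
    # which keeps write->read bit-identical
    return repr(float(x))


def _infer_step(positions: list[tuple[float, float]]) -> float:
    vals = np.array(
        sorted({p[0] for p in positions}) + sorted({p[1] for p in positions})
    )
    diffs = []
    for axis in (sorted({p[0] for p in positions}), sorted({p[1] for p in positions})):
        a = np.diff(np.asarray(axis))
        diffs.extend(a[a > 0].tolist())
    if not diffs:
        return 1.0  # single pixel: pitch is arbitrary
    return float(min(diffs))


def _build_map(
    axis: np.ndarray,
    rows: list[tuple[float, float, np.ndarray]],
    analyzed_fraction: float,
    filter_area: float,
) -> SpectralMap:
    axis = np.asarray(axis, dtype=float)
    positions = [(x, y) for x, y, _ in rows]
    step = _infer_step(positions)
    spectra = [
        Spectrum(axis, inten, position=(x, y)) for x, y, inten in rows
    ]
    return SpectralMap(
        spectra,
        step=step,
        analyzed_fraction=analyzed_fraction,
        filter_area=filter_area,
    )


def read_map(
    path: str | os.PathLike,
    dialect: str = "csv",
    analyzed_fraction: float = 1.0,
    filter_area: float = DEFAULT_FILTER_AREA_MM2,
) -> SpectralMap:
    """Read a point-by-point map export.

    The lattice step is inferred as the minimal positive coordinate
    difference; all spectra share one wavenumber axis object.

    Raises
    ------
    FormatError
        On ragged rows (the message names the 1-based line number) or an
        unknown dialect.
    LatticeError, DuplicatePositionError
        From :class:`SpectralMap` validation.
    """
    if dialect not in ("csv", "labspec_ascii"):
        raise FormatError(f"unsupported dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    head = lines[0].split(sep)
    if dialect == "csv":
        if len(head) < 3 or head[0] != "x" or head[1] != "y":
            raise FormatError(f"{path}: line 1: expected header x,y,wn1,...")
        axis = np.array([float(c) for c in head[2:]])
    else:
        if len(head) < 3 or head[0].strip() or head[1].strip():
            raise FormatError(
                f"{path}: line 1: expected two empty cells then the wavenumber axis"
            )
        axis = np.array([float(c) for c in head[2:]])
    width = len(axis) + 2
    rows: list[tuple[float, float, np.ndarray]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != width:
            raise FormatError(
                f"{path}: line {lineno}: expected {width} fields, got {len(cells)}"
            )
        try:
            x, y = float(cells[0]), float(cells[1])
            inten = np.array([float(c) for c in cells[2:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
        rows.append((x, y, inten))
    return _build_map(axis, rows, analyzed_fraction, filter_area)


def write_map(map_: SpectralMap, path: str | os.PathLike, dialect: str = "csv") -> None:
    """Write a map in the csv or labspec_ascii dialect (losslessly)."""
    if dialect not in ("csv", "labspec_ascii"):
        raise FormatError(f"unsupported dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    axis = map_.spectra[0].wavenumbers if map_.spectra else np.array([])
    with _atomic_open(path) as fh:
        if dialect == "csv":
            fh.write("x,y," + ",".join(_fmt(w) for w in axis) + "\n")
        else:
            fh.write("\t\t" + "\t".join(_fmt(w) for w in axis) + "\n")
        for s in map_.spectra:
            cells = [_fmt(s.position[0]), _fmt(s.position[1])]
            cells += [_fmt(v) for v in s.intensities]
            fh.write(sep.join(cells) + "\n")


def read_library(path: str | os.PathLike) -> TrainingLibrary:
    """Read a training library: csv with a ``label`` column then intensity
    columns named by their wavenumber."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    head = lines[0].split(",")
    if head[0] != "label" or len(head) < 2:
        raise FormatError(f"{path}: line 1: expected header label,wn1,...")
    axis = np.array([float(c) for c in head[1:]])
    entries = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(",")
        if len(cells) != len(axis) + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {len(axis) + 1} fields, "
                f"got {len(cells)}"
            )
        label = cells[0]
        if label not in CLASSES:
            raise LabelError(
                f"{path}: line {lineno}: unknown class label {label!r}; "
                f"allowed: {sorted(CLASSES)}"
            )
        inten = np.array([float(c) for c in cells[1:]])
        entries.append(Spectrum(axis, inten, label=label))
    return TrainingLibrary(entries)


def write_library(lib: TrainingLibrary, path: str | os.PathLike) -> None:
    axis = lib.entries[0].wavenumbers
    with _atomic_open(path) as fh:
        fh.write("label," + ",".join(_fmt(w) for w in axis) + "\n")
        for s in lib.entries:
            fh.write(s.label + "," + ",".join(_fmt(v) for v in s.intensities) + "\n")


def write_report(report, path: str | os.PathLike) -> None:
    """Write an analytical report as deterministic JSON.

    ``report`` is anything with a ``to_dict()`` method (a
    :class:`~ramanmp.quantify.QuantReport`) or a plain dict.  Keys are
    sorted and no timestamps are embedded, so identical runs produce
    byte-identical files.
    """
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    with _atomic_open(path) as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


class _atomic_open:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)

    def __enter__(self):
        d = os.path.dirname(self.path) or "."
        fd, self.tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        self.fh = os.fdopen(fd, "w", encoding="utf-8", newline="\n")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False
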