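"""Core in-memory containers for Raman map analysis.

A filter surface is scanned point by point on a regular lattice (typically
5 µm pitch); each lattice point yields one Raman spectrum over a wavenumber
axis.  The containers here hold single spectra, whole maps, and labeled
training libraries for the polymer classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed class inventory of the pixel classifier: nine polymers, the
#: stearate decoy class (glove residue, Raman signal close to PE) and the
#: non-microplastic class (digestion residue, cellulose, silicon filter
#: background).
CLASSES: tuple[str, ...] = (
    "NMP",
    "PA",
    "PE",
    "PES",
    "PLA",
    "PMMA",
    "PP",
    "PS",
    "PTFE",
    "PU",
    "stearate",
)

#: Acquisition window of the instrument, cm⁻¹.
ACQ_RANGE: tuple[float, float] = (550.0, 2000.0)

#: Default filter geometry: restricted filtration area on the silicon
#: filter, mm².
DEFAULT_FILTER_AREA_MM2: float = 14.0


class SpectrumError(ValueError):
    """Raised when a spectrum violates its structural invariants."""


class LatticeError(ValueError):
    """Raised when a map position does not lie on the sampling lattice."""


class DuplicatePositionError(ValueError):
    """Raised when two spectra in one map share a lattice position."""


class LabelError(ValueError):
    """Raised when a training label is outside the closed class set."""


@dataclass
class Spectrum:
    """One wavenumber/intensity trace, optionally anchored on the map grid.

    Parameters
    ----------
    wavenumbers : array of float
        Strictly increasing Raman shifts in cm⁻¹.
    intensities : array of float
        Detector counts (arbitrary units), finite, same length as the axis.
    position : tuple of float, optional
        ``(x, y)`` in µm relative to the map corner.
    label : str, optional
        Class label (training data only).
    meta : dict
        Free-form provenance and flags (e.g. ``degenerate``).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    position: tuple[float, float] | None = None
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise SpectrumError(
                f"axis length {len(self.wavenumbers)} != "
                f"intensity length {len(self.intensities)}"
            )
        if len(self.wavenumbers) and np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectrumError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumError("non-finite intensities are not allowed")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    @property
    def degenerate(self) -> bool:
        """True if flagged as constant/empty (bypasses classification)."""
        return bool(self.meta.get("degenerate", False))

    def replace(self, **kw) -> "Spectrum":
        """Return a copy with selected fields replaced."""
        out = {
            "wavenumbers": self.wavenumbers,
            "intensities": self.intensities,
            "position": self.position,
            "label": self.label,
            "meta": dict(self.meta),
        }
        out.update(kw)
        return Spectrum(**out)


@dataclass
class SpectralMap:
    """A regular-grid collection of positioned spectra.

    ``step`` is the lattice pitch in µm; ``analyzed_fraction`` is the
    fraction of the total filter area actually covered by the map(s), used
    for extrapolating counts to the whole filter; ``filter_area`` is the
    total filtration area in mm².
    """

    spectra: list[Spectrum]
    step: float
    analyzed_fraction: float = 1.0
    filter_area: float = DEFAULT_FILTER_AREA_MM2

    #: relative tolerance for the on-lattice check
    LATTICE_RTOL = 1e-6

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise LatticeError(f"step must be positive, got {self.step}")
        if not (0.0 < self.analyzed_fraction <= 1.0):
            raise ValueError(
                f"analyzed_fraction must be in (0, 1], got {self.analyzed_fraction}"
            )
        seen: set[tuple[int, int]] = set()
        tol = self.LATTICE_RTOL * self.step
        ox, oy = self.origin
        for s in self.spectra:
            if s.position is None:
                raise LatticeError("map spectra must carry a position")
            ij = []
            for v, o in zip(s.position, (ox, oy)):
                k = round((v - o) / self.step)
                if abs((v - o) - k * self.step) > tol:
                    raise LatticeError(
                        f"position {s.position} is off the {self.step} µm lattice"
                    )
                ij.append(k)
            key = (ij[0], ij[1])
            if key in seen:
                raise DuplicatePositionError(f"duplicate position {s.position}")
            seen.add(key)

    @property
    def origin(self) -> tuple[float, float]:
        """Lattice origin: the minimal (x, y) over all spectra, else (0, 0)."""
        if not self.spectra:
            return (0.0, 0.0)
        xs = [s.position[0] for s in self.spectra]
        ys = [s.position[1] for s in self.spectra]
        return (min(xs), min(ys))

    def __len__(self) -> int:
        return len(self.spectra)

    def lattice_index(self, position: tuple[float, float]) -> tuple[int, int]:
        """Integer lattice coordinates of a position relative to the origin."""
        ox, oy = self.origin
        return (
            round((position[0] - ox) / self.step),
            round((position[1] - oy) / self.step),
        )

    @property
    def analyzed_area_mm2(self) -> float:
        """Area actually scanned: one step² cell per pixel, in mm²."""
        return len(self.spectra) * (self.step * 1e-3) ** 2


@dataclass
class TrainingLibrary:
    """Labeled spectra for training the pixel classifier.

    All labels must come from :data:`CLASSES`; a usable library has at
    least two classes and at least two spectra per present class.
    """

    entries: list[Spectrum]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for s in self.entries:
            if s.label not in CLASSES:
                raise LabelError(
                    f"unknown class label {s.label!r}; allowed: {sorted(CLASSES)}"
                )
            counts[s.label] = counts.get(s.label, 0) + 1
        if len(counts) < 2:
            raise LabelError(
                f"a training library needs at least 2 classes, got {sorted(counts)}"
            )
        low = {c: n for c, n in counts.items() if n < 2}
        if low:
            raise LabelError(f"classes with fewer than 2 spectra: {sorted(low)}")

    @property
    def classes(self) -> list[str]:
        """Sorted list of classes present in the library."""
        return sorted({s.label for s in self.entries})

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.entries:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)
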