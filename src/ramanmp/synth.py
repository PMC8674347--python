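"""Synthetic Raman spectra, training libraries and filter-map scenes.

The generator emulates what the instrument records on a digested-filter
surface: polymer spectra are sums of narrow vibrational bands riding on a
broad fluorescence baseline with intensity-dependent (shot-like) noise;
maps are regular 5 µm lattices over the filter with randomly placed
polymer particles, elongated non-plastic fibers, organic-residue
background and randomly "missed" pixels (acquisition desynchronization),
which appear as constant, information-free spectra.

The shipped peak tables use canonical polymer Raman band positions (e.g.
PE C–C stretches near 1062/1129 cm⁻¹, the PS ring-breathing line at
1001 cm⁻¹); stearate is deliberately PE-like, mirroring the real-world
confusion between glove-residue stearates and polyethylene.  All tables
are overridable by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ACQ_RANGE, CLASSES, SpectralMap, Spectrum, TrainingLibrary

#: Per-class vibrational bands as (center cm⁻¹, width cm⁻¹, relative height).
#: Widths are Gaussian sigmas.  NMP uses broad humps (fluorescent organic
#: residue and silicon-filter background); stearate is derived from the PE
#: band pattern with small shifts plus two extra weak bands.
PEAK_TABLES: dict[str, list[tuple[float, float, float]]] = {
    "PE": [(1062, 4, 0.55), (1129, 4, 0.65), (1295, 5, 1.0), (1440, 8, 0.8)],
    "PP": [
        (809, 4, 0.9),
        (841, 4, 1.0),
        (973, 4, 0.5),
        (1152, 5, 0.35),
        (1330, 5, 0.3),
        (1458, 7, 0.55),
    ],
    "PS": [
        (620, 4, 0.3),
        (1001, 3, 1.0),
        (1031, 4, 0.45),
        (1155, 5, 0.2),
        (1450, 6, 0.25),
        (1583, 5, 0.2),
        (1602, 4, 0.6),
    ],
    "PA": [
        (1128, 5, 0.5),
        (1235, 6, 0.3),
        (1296, 5, 0.45),
        (1440, 8, 1.0),
        (1635, 7, 0.6),
    ],
    "PMMA": [
        (601, 5, 0.5),
        (812, 5, 1.0),
        (966, 5, 0.35),
        (1450, 8, 0.6),
        (1728, 7, 0.55),
    ],
    "PES": [
        (633, 5, 0.35),
        (857, 5, 0.65),
        (1096, 5, 0.5),
        (1117, 5, 0.45),
        (1286, 5, 0.6),
        (1614, 5, 1.0),
        (1727, 6, 0.55),
    ],
    "PTFE": [(732, 4, 1.0), (1217, 6, 0.25), (1301, 5, 0.3), (1381, 5, 0.35)],
    "PU": [
        (1249, 6, 0.4),
        (1444, 7, 0.5),
        (1533, 6, 0.6),
        (1616, 5, 1.0),
        (1701, 7, 0.45),
    ],
    "PLA": [
        (873, 5, 1.0),
        (1042, 4, 0.4),
        (1128, 5, 0.3),
        (1293, 5, 0.35),
        (1454, 7, 0.5),
        (1769, 6, 0.45),
    ],
    "stearate": [
        (891, 4, 0.25),
        (1063, 4, 0.6),
        (1130, 4, 0.65),
        (1296, 5, 0.95),
        (1441, 8, 0.85),
        (1562, 6, 0.15),
    ],
    "NMP": [(700, 60, 0.3), (970, 50, 0.5), (1350, 70, 0.6), (1590, 60, 0.7)],
}

#: Default acquisition axis: 2 cm⁻¹ pitch over the instrument window.
DEFAULT_AXIS = np.arange(ACQ_RANGE[0], ACQ_RANGE[1] + 1e-9, 2.0)

#: Default ranges for the random polynomial baseline coefficients, in units
#: of the pure-signal amplitude, over a [0, 1]-normalized axis.
DEFAULT_BASELINE_RANGES: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (-2.0, 2.0),
    (-2.0, 2.0),
)


class SceneError(ValueError):
    """Raised for unrealizable scene specifications (e.g. overlapping
    particles of different classes, which would make the truth ambiguous)."""


def band_profile(
    axis: np.ndarray,
    peaks: list[tuple[float, float, float]],
    lineshape: str = "gaussian",
) -> np.ndarray:
    """Sum of spectral lines over an axis. ``lineshape`` ∈ {gaussian, lorentzian}."""
    y = np.zeros_like(axis, dtype=float)
    for center, width, height in peaks:
        d = axis - center
        if lineshape == "gaussian":
            y += height * np.exp(-0.5 * (d / width) ** 2)
        elif lineshape == "lorentzian":
            y += height / (1.0 + (d / width) ** 2)
        else:
            raise ValueError(f"unknown lineshape {lineshape!r}")
    return y


def generate_spectrum(
    cls: str,
    snr: float = 20.0,
    baseline_coeffs: tuple[float, ...] = (),
    seed: int | np.random.Generator = 0,
    axis: np.ndarray | None = None,
    peak_table: dict[str, list[tuple[float, float, float]]] | None = None,
    lineshape: str = "gaussian",
) -> Spectrum:
    """One labeled synthetic spectrum on the acquisition axis.

    The trace is band sum + polynomial baseline + shot-like noise whose
    standard deviation scales as sqrt(local intensity) and is ``1/snr`` of
    the pure-signal amplitude at the brightest point.  ``snr = inf`` gives
    a noiseless trace.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = DEFAULT_AXIS if axis is None else np.asarray(axis, dtype=float)
    table = PEAK_TABLES if peak_table is None else peak_table
    signal = band_profile(axis, table[cls], lineshape)
    amp = float(signal.max()) if signal.size else 1.0
    amp = amp if amp > 0 else 1.0
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = np.zeros_like(axis)
    for k, c in enumerate(baseline_coeffs):
        baseline += c * amp * t**k
    total = signal + baseline
    if np.isfinite(snr):
        lo = float(total.min())
        rel = (total - lo + 0.1 * amp) / (total.max() - lo + 0.1 * amp)
        noise = rng.normal(0.0, amp / snr, size=axis.shape) * np.sqrt(rel)
    else:
        noise = 0.0
    return Spectrum(axis, total + noise, label=cls, meta={"snr": float(snr)})


def generate_training_library(
    classes: tuple[str, ...] = CLASSES,
    n_per_class: int = 50,
    snr_range: tuple[float, float] = (3.0, 30.0),
    seed: int = 0,
    baseline_ranges: tuple[tuple[float, float], ...] = DEFAULT_BASELINE_RANGES,
    peak_table: dict | None = None,
) -> TrainingLibrary:
    """Balanced labeled library spanning a wide range of signal quality.

    Each spectrum draws its SNR uniformly from ``snr_range`` and its
    baseline polynomial coefficients uniformly from ``baseline_ranges``,
    so the library mixes clean and very noisy traces the way a curated
    instrument library does.  Pure function of its arguments and ``seed``.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for cls in classes:
        for _ in range(n_per_class):
            snr = rng.uniform(*snr_range)
            coeffs = tuple(rng.uniform(lo, hi) for lo, hi in baseline_ranges)
            entries.append(
                generate_spectrum(
                    cls, snr=snr, baseline_coeffs=coeffs, seed=rng,
                    peak_table=peak_table,
                )
            )
    return TrainingLibrary(entries)


@dataclass(frozen=True)
class ParticleSpec:
    """One planted particle: class, disc diameter (µm), optional fixed
    position (µm); ``None`` means place uniformly at random."""

    cls: str
    diameter_um: float
    position: tuple[float, float] | None = None


@dataclass
class SceneSpec:
    """Description of a synthetic filter scene.

    ``width_um`` × ``height_um`` is the scanned window (a map is a lattice
    of pitch ``step`` over it); ``analyzed_fraction`` records how much of
    the whole filter that window represents; particles below
    ``min_separation_um`` edge-to-edge would merge under the gap rule, so
    random placement enforces it.
    """

    width_um: float = 400.0
    height_um: float = 400.0
    step: float = 5.0
    filter_area: float = 14.0
    analyzed_fraction: float = 0.5
    particles: list[ParticleSpec] = field(default_factory=list)
    fibers: int = 0
    dropout_prob: float = 0.0
    preserve_connectivity: bool = True
    snr_range: tuple[float, float] = (5.0, 30.0)
    baseline_ranges: tuple[tuple[float, float], ...] = DEFAULT_BASELINE_RANGES
    min_separation_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob < 1.0):
            raise SceneError("dropout_prob must be in [0, 1)")
        for ps in self.particles:
            if ps.diameter_um < self.step:
                raise SceneError(
                    f"particle diameter {ps.diameter_um} µm below the "
                    f"{self.step} µm lattice pitch cannot be resolved"
                )
        if self.min_separation_um is None:
            self.min_separation_um = 3.0 * self.step


@dataclass
class TruthParticle:
    """Ground-truth particle: class, member lattice pixels, area (µm²)."""

    cls: str
    pixels: set[tuple[int, int]]
    area_um2: float


@dataclass
class MapTruth:
    """Per-pixel ground truth of a generated scene."""

    pixel_labels: dict[tuple[int, int], str]
    particles: list[TruthParticle]
    fiber_pixels: set[tuple[int, int]]
    dropout_pixels: set[tuple[int, int]]


def rasterize_disc(
    center: tuple[float, float], diameter: float, step: float, nx: int, ny: int
) -> set[tuple[int, int]]:
    """Lattice pixels whose centers lie strictly inside the disc."""
    r = diameter / 2.0
    cx, cy = center
    i0 = max(0, int(np.floor((cx - r) / step)))
    i1 = min(nx - 1, int(np.ceil((cx + r) / step)))
    j0 = max(0, int(np.floor((cy - r) / step)))
    j1 = min(ny - 1, int(np.ceil((cy + r) / step)))
    out = set()
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            if (i * step - cx) ** 2 + (j * step - cy) ** 2 < r * r:
                out.add((i, j))
    return out


def _gap_components(pixels: set[tuple[int, int]], max_gap: int = 2):
    """Connected components under Chebyshev lattice distance ≤ max_gap."""
    remaining = set(pixels)
    comps = []
    offsets = [
        (di, dj)
        for di in range(-max_gap, max_gap + 1)
        for dj in range(-max_gap, max_gap + 1)
        if (di, dj) != (0, 0)
    ]
    while remaining:
        seedpx = remaining.pop()
        comp = {seedpx}
        stack = [seedpx]
        while stack:
            i, j = stack.pop()
            for di, dj in offsets:
                q = (i + di, j + dj)
                if q in remaining:
                    remaining.remove(q)
                    comp.add(q)
                    stack.append(q)
        comps.append(comp)
    return comps


def generate_map(scene: SceneSpec) -> tuple[SpectralMap, MapTruth]:
    """Rasterize a scene into a spectral map plus its ground truth.

    Particles become discs of same-class pixels; fibers become thick random
    polylines of NMP; every remaining pixel gets an NMP background
    spectrum.  Dropout pixels receive a constant (degenerate) spectrum but
    keep their true label in the truth record.  With
    ``preserve_connectivity`` the dropout mask is repaired so that no
    ground-truth particle is split or erased under the gap-2 rule.
    """
    rng = np.random.default_rng(scene.seed)
    step = scene.step
    nx = int(np.floor(scene.width_um / step)) + 1
    ny = int(np.floor(scene.height_um / step)) + 1

    # --- place particles -------------------------------------------------
    placed: list[tuple[ParticleSpec, tuple[float, float]]] = []

    def far_enough(pos, diam):
        for ps, c in placed:
            d = np.hypot(pos[0] - c[0], pos[1] - c[1])
            if d < (diam + ps.diameter_um) / 2.0 + scene.min_separation_um:
                return False
        return True

    for ps in scene.particles:
        if ps.position is not None:
            placed.append((ps, ps.position))
        else:
            r = ps.diameter_um / 2.0
            for _ in range(10_000):
                pos = (
                    rng.uniform(r, scene.width_um - r),
                    rng.uniform(r, scene.height_um - r),
                )
                if far_enough(pos, ps.diameter_um):
                    placed.append((ps, pos))
                    break
            else:
                raise SceneError(
                    f"could not place a {ps.diameter_um} µm particle without "
                    "violating the minimum separation; scene too crowded"
                )

    pixel_labels: dict[tuple[int, int], str] = {}
    truth_particles: list[TruthParticle] = []
    for ps, pos in placed:
        px = rasterize_disc(pos, ps.diameter_um, step, nx, ny)
        if not px:
            # sub-resolution placement between lattice points: the particle
            # still occupies its nearest pixel
            px = {(int(round(pos[0] / step)), int(round(pos[1] / step)))}
        clash = {q for q in px if q in pixel_labels and pixel_labels[q] != ps.cls}
        if clash:
            raise SceneError(
                f"particles of different classes overlap at lattice {sorted(clash)[0]}"
            )
        for q in px:
            pixel_labels[q] = ps.cls
        truth_particles.append(TruthParticle(ps.cls, px, len(px) * step**2))

    # --- fibers: thick random polylines of NMP ---------------------------
    fiber_pixels: set[tuple[int, int]] = set()
    for _ in range(scene.fibers):
        x0 = rng.uniform(0, scene.width_um)
        y0 = rng.uniform(0, scene.height_um)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.15, 0.5) * min(scene.width_um, scene.height_um)
        half_w = rng.uniform(0.5, 1.5) * step
        x1, y1 = x0 + length * np.cos(ang), y0 + length * np.sin(ang)
        for i in range(nx):
            for j in range(ny):
                px, py = i * step, j * step
                # distance from pixel center to the segment
                vx, vy = x1 - x0, y1 - y0
                t = np.clip(((px - x0) * vx + (py - y0) * vy) / (vx**2 + vy**2), 0, 1)
                d = np.hypot(px - (x0 + t * vx), py - (y0 + t * vy))
                if d <= half_w and (i, j) not in pixel_labels:
                    fiber_pixels.add((i, j))
    for q in fiber_pixels:
        pixel_labels.setdefault(q, "NMP")

    # --- dropout mask ----------------------------------------------------
    all_px = [(i, j) for i in range(nx) for j in range(ny)]
    drop_mask = rng.random(len(all_px)) < scene.dropout_prob
    dropout = {q for q, m in zip(all_px, drop_mask) if m}
    if scene.preserve_connectivity and dropout:
        for tp in truth_particles:
            survive = tp.pixels - dropout
            if not survive or len(_gap_components(survive)) > 1:
                dropout -= tp.pixels  # un-drop: keep the particle intact

    # --- spectra ---------------------------------------------------------
    spectra = []
    for i in range(nx):
        for j in range(ny):
            q = (i, j)
            pos = (i * step, j * step)
            if q in dropout:
                level = rng.uniform(0, 100.0)
                s = Spectrum(
                    DEFAULT_AXIS,
                    np.full_like(DEFAULT_AXIS, level),
                    position=pos,
                    meta={"dropout": True},
                )
            else:
                cls = pixel_labels.get(q, "NMP")
                snr = rng.uniform(*scene.snr_range)
                coeffs = tuple(rng.uniform(lo, hi) for lo, hi in scene.baseline_ranges)
                s = generate_spectrum(cls, snr=snr, baseline_coeffs=coeffs, seed=rng)
                s = s.replace(position=pos, label=None)
            spectra.append(s)

    smap = SpectralMap(
        spectra,
        step=step,
        analyzed_fraction=scene.analyzed_fraction,
        filter_area=scene.filter_area,
    )
    truth = MapTruth(pixel_labels, truth_particles, fiber_pixels, dropout)
    return smap, truth
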