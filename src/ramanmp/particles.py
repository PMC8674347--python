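"""Gap-tolerant grouping of classified pixels into particles.

Neighboring pixels of the same polymer class are grouped into particles by
building, per class, a graph whose edges connect pixels at lattice
(Chebyshev) distance ≤ ``max_gap`` (default 2) and taking its connected
components.  The gap of 2 lets a particle "jump over" a single missed
pixel — an acquisition dropout — without splitting in two.  NMP pixels
form no particles.

Metrics per particle: area = n_pixels × step² (µm²); size = √area, the
side of the equal-area square (so the < 50 µm² "small" class corresponds
to size below ≈ 7 µm); a circular-equivalent diameter √(4A/π) is also
provided for comparison with sizing conventions in other studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .classify import PixelClassification
from .spectra import LatticeError

#: area threshold (µm²) below which a particle counts as "small"
SMALL_AREA_UM2 = 50.0


@dataclass
class Particle:
    """A connected group of same-class pixels with its size metrics."""

    label: str
    pixels: list[tuple[float, float]]  # absolute positions, µm
    area_um2: float = 0.0
    size_um: float = 0.0
    equivalent_diameter_um: float = 0.0
    small: bool = False
    centroid: tuple[float, float] = (0.0, 0.0)
    mean_confidence: float = 0.0
    representative_index: int | None = None  # spectrum index of the
    # highest-confidence member pixel

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def particle_metrics(p: Particle, step: float) -> Particle:
    """Fill area/size/centroid metrics in place and return the particle."""
    n = len(p.pixels)
    if n == 0:
        raise ValueError("a particle must own at least one pixel")
    p.area_um2 = n * step * step
    p.size_um = math.sqrt(p.area_um2)
    p.equivalent_diameter_um = math.sqrt(4.0 * p.area_um2 / math.pi)
    p.small = p.area_um2 < SMALL_AREA_UM2
    p.centroid = (
        sum(x for x, _ in p.pixels) / n,
        sum(y for _, y in p.pixels) / n,
    )
    return p


def _to_lattice(
    pixels: list[PixelClassification], step: float
) -> list[tuple[int, int]]:
    tol = 1e-6 * step
    out = []
    for px in pixels:
        ij = []
        for v in px.position:
            k = round(v / step)
            if abs(v - k * step) > tol:
                raise LatticeError(
                    f"pixel at {px.position} is off the {step} µm lattice"
                )
            ij.append(k)
        out.append((ij[0], ij[1]))
    return out


def cluster_particles(
    pixels: list[PixelClassification],
    step: float,
    max_gap: int = 2,
    exclude: frozenset[str] | set[str] = frozenset({"NMP"}),
    metric: str = "chebyshev",
    drop_review: bool = False,
) -> list[Particle]:
    """Group classified pixels into particles, class by class.

    Two pixels of the same class are connected when their lattice distance
    is at most ``max_gap`` (Chebyshev by default — diagonal steps count as
    1; ``metric="euclidean"`` measures straight-line distance in lattice
    units instead).  Each connected component becomes one particle.
    Classes in ``exclude`` (NMP by default) never form particles.  With
    ``drop_review``, review-flagged pixels are discarded beforehand.
    """
    if metric not in ("chebyshev", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    pool = [
        px
        for px in pixels
        if px.label not in exclude
        and not px.degenerate
        and not (drop_review and px.review)
    ]
    coords = _to_lattice(pool, step)

    by_class: dict[str, list[int]] = {}
    for k, px in enumerate(pool):
        by_class.setdefault(px.label, []).append(k)

    offsets = []
    for di in range(-max_gap, max_gap + 1):
        for dj in range(-max_gap, max_gap + 1):
            if (di, dj) == (0, 0):
                continue
            if metric == "euclidean" and di * di + dj * dj > max_gap * max_gap:
                continue
            offsets.append((di, dj))

    particles: list[Particle] = []
    for label in sorted(by_class):
        members = by_class[label]
        index = {coords[k]: k for k in members}
        g = nx.Graph()
        g.add_nodes_from(members)
        for k in members:
            i, j = coords[k]
            for di, dj in offsets:
                other = index.get((i + di, j + dj))
                if other is not None and other > k:
                    g.add_edge(k, other)
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            best = max(comp, key=lambda k: (pool[k].confidence, -k))
            p = Particle(
                label=label,
                pixels=[pool[k].position for k in comp],
                mean_confidence=sum(pool[k].confidence for k in comp) / len(comp),
                representative_index=pool[best].spectrum_index,
            )
            particles.append(particle_metrics(p, step))
    # deterministic order: by class, then centroid
    particles.sort(key=lambda p: (p.label, p.centroid))
    return particles
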