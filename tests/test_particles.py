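"""Gap-tolerant particle clustering against a brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramanmp as rm
from ramanmp.classify import PixelClassification


def px(i, j, label, step=5.0, conf=0.9):
    return PixelClassification(
        position=(i * step, j * step),
        label=label,
        confidence=conf,
        review=conf < 0.5,
        spectrum_index=None,
    )


def brute_force_partition(pixels, step, max_gap=2, exclude=frozenset({"NMP"})):
    """Quadratic transitive-closure oracle over all pixel pairs."""
    pool = [p for p in pixels if p.label not in exclude and not p.degenerate]
    n = len(pool)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if pool[a].label != pool[b].label:
                continue
            di = round((pool[a].position[0] - pool[b].position[0]) / step)
            dj = round((pool[a].position[1] - pool[b].position[1]) / step)
            if max(abs(di), abs(dj)) <= max_gap:
                parent[find(a)] = find(b)
    groups: dict[tuple, set] = {}
    for a in range(n):
        groups.setdefault((pool[a].label, find(a)), set()).add(pool[a].position)
    return {frozenset(v) for v in groups.values()}


class TestGapRule:
    def test_isolated_pixel_is_small_particle(self):
        (p,) = rm.cluster_particles([px(0, 0, "PE")], step=5.0)
        assert p.label == "PE" and p.area_um2 == 25.0 and p.small

    def test_gap_two_bridges_a_missed_pixel(self):
        parts = rm.cluster_particles([px(0, 0, "PE"), px(2, 0, "PE")], step=5.0)
        assert len(parts) == 1 and parts[0].n_pixels == 2

    def test_gap_three_splits(self):
        parts = rm.cluster_particles([px(0, 0, "PE"), px(3, 0, "PE")], step=5.0)
        assert len(parts) == 2

    def test_adjacent_different_classes_stay_separate(self):
        parts = rm.cluster_particles([px(0, 0, "PE"), px(1, 0, "PP")], step=5.0)
        assert sorted(p.label for p in parts) == ["PE", "PP"]

    def test_nmp_forms_no_particles(self):
        assert rm.cluster_particles([px(0, 0, "NMP"), px(1, 0, "NMP")], step=5.0) == []

    def test_diagonal_counts_as_one_in_chebyshev(self):
        parts = rm.cluster_particles([px(0, 0, "PE"), px(2, 2, "PE")], step=5.0)
        assert len(parts) == 1

    def test_euclidean_metric_is_stricter(self):
        pts = [px(0, 0, "PE"), px(2, 2, "PE")]  # distance √8 ≈ 2.83
        parts = rm.cluster_particles(pts, step=5.0, metric="euclidean")
        assert len(parts) == 2

    def test_off_lattice_pixel_raises(self):
        bad = PixelClassification((7.3, 0.0), "PE", 0.9, False)
        with pytest.raises(rm.LatticeError):
            rm.cluster_particles([bad], step=5.0)

    def test_drop_review_discards_flagged_pixels(self):
        pts = [px(0, 0, "PE", conf=0.9), px(1, 0, "PE", conf=0.2)]
        keep = rm.cluster_particles(pts, step=5.0)
        drop = rm.cluster_particles(pts, step=5.0, drop_review=True)
        assert keep[0].n_pixels == 2 and drop[0].n_pixels == 1


class TestMetrics:
    @pytest.mark.parametrize(
        "n, step, area, size, small",
        [
            (2, 5.0, 50.0, np.sqrt(50.0), False),  # 50 µm² is not < 50
            (1, 5.0, 25.0, 5.0, True),
            (4, 1.0, 4.0, 2.0, True),
        ],
    )
    def test_area_size_small(self, n, step, area, size, small):
        pts = [px(i, 0, "PE", step=step) for i in range(n)]
        (p,) = rm.cluster_particles(pts, step=step)
        assert p.area_um2 == area
        assert np.isclose(p.size_um, size)
        assert p.small is small

    def test_equivalent_diameter(self):
        (p,) = rm.cluster_particles([px(0, 0, "PE")], step=5.0)
        assert np.isclose(p.equivalent_diameter_um, np.sqrt(4 * 25 / np.pi))

    def test_representative_is_highest_confidence_member(self):
        pts = [
            PixelClassification((0.0, 0.0), "PE", 0.6, False, spectrum_index=0),
            PixelClassification((5.0, 0.0), "PE", 0.95, False, spectrum_index=1),
        ]
        (p,) = rm.cluster_particles(pts, step=5.0)
        assert p.representative_index == 1
        assert np.isclose(p.mean_confidence, (0.6 + 0.95) / 2)


def random_grid_pixels(rng, n_side, labels=("PE", "PP", "PS", "NMP", None)):
    pts = []
    for i in range(n_side):
        for j in range(n_side):
            lab = labels[rng.integers(len(labels))]
            if lab is not None:
                pts.append(px(i, j, lab))
    return pts


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n_side = int(rng.integers(3, 31))
            pts = random_grid_pixels(rng, n_side)
            got = {
                frozenset(p.pixels) for p in rm.cluster_particles(pts, step=5.0)
            }
            assert got == brute_force_partition(pts, step=5.0)

    def test_pixel_conservation(self):
        rng = np.random.default_rng(7)
        pts = random_grid_pixels(rng, 20)
        parts = rm.cluster_particles(pts, step=5.0)
        covered = [pos for p in parts for pos in p.pixels]
        eligible = [p.position for p in pts if p.label != "NMP"]
        assert sorted(covered) == sorted(eligible)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_gap_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        pts = random_grid_pixels(rng, 12)
        counts = [
            len(rm.cluster_particles(pts, step=5.0, max_gap=g)) for g in (1, 2, 3, 4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_dropout_robustness(self):
        """Deleting pixels that leave no same-particle gap above 2 keeps
        the particle count unchanged."""
        # a 5x1 PE bar: drop every other pixel -> gaps of 2 only
        pts = [px(i, 0, "PE") for i in range(5)]
        thinned = [pts[0], pts[2], pts[4]]
        assert len(rm.cluster_particles(pts, step=5.0)) == 1
        assert len(rm.cluster_particles(thinned, step=5.0)) == 1
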