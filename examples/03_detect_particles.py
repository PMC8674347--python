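"""Gap-tolerant particle detection on a hand-built pixel layout.

Same-class pixels at lattice (Chebyshev) distance ≤ 2 join one particle,
so a single missed pixel inside a particle does not split it; pixels at
distance 3 stay separate; NMP never forms particles.
"""

from ramanmp import cluster_particles
from ramanmp.classify import PixelClassification


def px(i, j, label, conf=0.9):
    return PixelClassification((5.0 * i, 5.0 * j), label, conf, conf < 0.5)


pixels = [
    px(0, 0, "PE"), px(2, 0, "PE"),      # gap of one missed pixel: one particle
    px(10, 0, "PE"),                      # far away: its own particle
    px(0, 5, "PP"), px(1, 5, "PP"),       # adjacent PP pair
    px(5, 5, "NMP"),                      # background: never a particle
]

for p in cluster_particles(pixels, step=5.0, max_gap=2):
    print(f"{p.label}: {p.n_pixels} px, area {p.area_um2:.0f} um^2, "
          f"size {p.size_um:.2f} um, small(<50 um^2)={p.small}")
print("-> 2 PE particles (the gap-2 rule bridged the missed pixel) and 1 PP; "
      "area is n_pixels x step^2.")
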