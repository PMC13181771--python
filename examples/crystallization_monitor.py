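"""Tracking order with <q> and RSF along a melting-like trajectory.

Builds a synthetic "melting" trajectory by adding rigid-molecule Gaussian
positional noise of growing amplitude to an ideal ice Ic crystal, then
computes the per-frame mean tetrahedrality and ring summation factor.  Both
metrics fall monotonically, with RSF responding over a wider range — the
reason it resolves crystal-growth kinetics and defect annealing more
sharply than tetrahedrality alone.
"""

import numpy as np

from ringorder import CrystalSpec, make_ice, order_timeseries

crystal = make_ice(CrystalSpec("Ic", (4, 4, 4), seed=8))
rng = np.random.default_rng(8)

frames = []
sigmas = [0.0, 0.15, 0.3, 0.5, 0.8, 1.2]
for k, sigma in enumerate(sigmas):
    f = crystal.copy()
    jitter = rng.normal(scale=sigma, size=(f.n_waters, 3)) if sigma else np.zeros((f.n_waters, 3))
    f.oxygen_positions = f.oxygen_positions + jitter
    f.hydrogen_positions = f.hydrogen_positions + jitter[:, None, :]
    f.frame_index = k
    frames.append(f)

records = order_timeseries(frames, max_ring=8)
print(f"{'frame':>6}{'noise(A)':>10}{'<q>':>8}{'RSF':>8}")
for sigma, r in zip(sigmas, records):
    print(f"{r.frame_index:>6}{sigma:>10.2f}{r.q_mean:>8.3f}{r.rsf:>8.3f}")
print(
    "\nAt zero noise both metrics sit at 1.0 (ideal crystal); RSF collapses\n"
    "faster than <q> as H-bonds break, mirroring its wider liquid-crystal\n"
    "response range."
)
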