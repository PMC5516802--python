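"""Quantify reproducibility between screens with the transition matrix.

Both screens are discretized into up/neutral/down calls; the 3x3
transition matrix cross-tabulates the calls over shared (miRNA, protein)
pairs, and the overlap statistic is the fraction of reference-screen
calls whose sign is preserved in the other screen.  Neutral-neutral
agreement is excluded: agreeing on "no change" is not a reproduced
change.
"""

import numpy as np

from mirscreen.concordance import transition_matrix
from mirscreen.preprocess import discretize, normalize
from mirscreen.screens import DiscreteScreen
from mirscreen.simulate import (
    SimulationConfig,
    simulate_primary_screen,
    simulate_secondary_screens,
)

config = SimulationConfig(seed=1)
primary, _ = simulate_primary_screen(config)
controls = [m for m in primary.mirna_ids if m.startswith("NTC-")]
norm = normalize(primary, controls, drop_controls=True)
disc1 = discretize(norm, z_threshold=2.5)  # stringent calls

# a screen agrees with itself completely ...
print(f"self-overlap: {transition_matrix(disc1, disc1).overlap:.2f}")

# ... and degrades gracefully under state-flip noise
rng = np.random.default_rng(0)
for eps in (0.05, 0.20):
    flip = rng.random(disc1.states.shape) < eps
    resample = rng.choice([-1, 0, 1], size=disc1.states.shape,
                          p=[0.02, 0.96, 0.02])
    noisy = DiscreteScreen(disc1.mirna_ids, disc1.protein_ids,
                           np.where(flip, resample, disc1.states), 2.5)
    print(f"overlap after {int(100 * eps)}% state-flip noise: "
          f"{transition_matrix(disc1, noisy).overlap:.2f}")

# against the independent rescreen of the same cell line the overlap
# reflects how much of the generative signal the two screens share:
# signature effects on shared total proteins replicate, phosphosite
# readouts are re-drawn from the cell line's signaling network
secondary = simulate_secondary_screens(config, flip_prob=0.05, seed=1)
disc2 = discretize(secondary.screens[0], z_threshold=2.5)
tm = transition_matrix(disc1, disc2)
print("\nscreen 1 vs rescreen, transition counts:")
print(tm.to_frame())
print(f"sign-preserved overlap: {tm.overlap:.2f} "
      f"(reverse direction {tm.overlap_reverse:.2f})")
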