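"""Mirrored-tile scoring of microglial reactivity.

Scores a symmetric noise section (null calibration) and a section with a
known fraction of activated ipsilesional tiles, and compares the measured
ipsi-contra high-tile ratio difference with the analytic expectation.
"""

import numpy as np

from strokequant import ReactivitySpec, generate_section_stack, score_section

# null: no lesion, no activation -> both hemispheres exchangeable
secs, _ = generate_section_stack(None, ReactivitySpec(), [0.0],
                                 image_shape=(400, 800), seed=7)
null = score_section(secs[1])
print("null section (no activation):")
print(f"  threshold = contra mean + 1.5 SD = {null.threshold:.2f} gray values")
print(f"  high-tile ratio ipsi {null.ratio_ipsi:.3f}, contra "
      f"{null.ratio_contra:.3f}, difference {null.ratio_diff:+.3f}")
print(f"  contra exceedance ~ P(Z > 1.5) = 0.0668 by construction")

# inject activation into 30% of ipsilesional tiles
f = 0.30
diffs = []
for seed in range(10):
    secs, truth = generate_section_stack(
        None, ReactivitySpec(activated_tile_fraction=f), [0.0],
        image_shape=(400, 800), seed=100 + seed)
    diffs.append(score_section(secs[1]).ratio_diff)
print(f"\nactivated fraction f = {f}:")
print(f"  mean ratio difference over 10 seeds: {np.mean(diffs):.3f}")
print(f"  analytic expectation f*(1-0.0668):  {f*(1-0.0668):.3f}")
print("-> the tile score recovers the injected activation level; the "
      "remaining gap is the finite-tile sampling error")
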