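"""Build the default 3D Gabor bank and inspect one kernel.

The bank has one scale and four (theta, omega) orientations.  Every kernel
is sampled on its support grid, mean-subtracted and L2-normalized, so its
taps sum to ~0 (zero-DC: constant scenes produce no response) and have unit
energy.
"""

import numpy as np

from gaborgist import build_default_bank

bank = build_default_bank()
print(f"bank size: {len(bank)} kernels")
for i, k in enumerate(bank):
    p = k.params
    print(
        f"kernel {i}: theta={p.theta:.3f} omega={p.omega:.3f} "
        f"taps={k.taps.shape} sum={k.taps.sum():+.2e} "
        f"l2={np.linalg.norm(k.taps):.6f}"
    )

# The (theta, omega) = (0, 0) kernel is purely spatial: its response to a
# static scene persists over time, while the temporally tilted kernels
# respond to content that moves.
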