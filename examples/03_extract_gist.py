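"""Extract the 256-dimensional spatiotemporal gist of a clip.

Each of the four filter responses is average-pooled over a 4x4x4 grid (64
cells); concatenating across the bank gives 4 x 64 = 256 values.  Because
the kernels are zero-DC, adding a constant intensity offset (turning the
ward lights up) leaves the descriptor unchanged.
"""

import numpy as np

from gaborgist import SynthConfig, build_default_bank, extract_gist, generate_normal_clip

bank = build_default_bank()
clip = generate_normal_clip(SynthConfig(n_frames=100), seed=3)
feature = extract_gist(clip, bank)
print(f"gist length: {len(feature)} (= {len(bank)} kernels x 64 cells)")
print(f"feature norm: {np.linalg.norm(feature.values):.4f}")

brighter = extract_gist(clip.data + 0.2, bank)
print(f"max |change| under +0.2 illumination offset: "
      f"{np.abs(brighter.values - feature.values).max():.2e}")
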