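"""Multivariate EMD keeps mode indices aligned across channels.

Generates a 12-channel motion whose channels share a 10 Hz and a 2 Hz
component with random phases, decomposes it with MEMD (64 Hammersley
projection directions), and shows that mode 1 carries every channel's
10 Hz part and mode 2 the 2 Hz part — the property that lets joints be
compared at a fixed mode index.
"""

import numpy as np

from mocap_hht.fixtures import make_preset
from mocap_hht.memd import memd_decompose

bundle = make_preset("two-tone", joint_count=3, seed=1)
s = bundle.motion.values
d = memd_decompose(s)
print(f"{s.shape[1]} channels x {s.shape[0]} frames -> {d.n_imfs} aligned IMFs + trend")

for ci, f in [(0, 10.0), (1, 2.0)]:
    rs = [
        abs(np.corrcoef(d.imfs[ci][:, ch], bundle.truth[ci][:, ch])[0, 1])
        for ch in range(s.shape[1])
    ]
    print(f"  IMF {ci + 1} vs planted {f:>4} Hz tone: "
          f"correlation {min(rs):.3f} (worst channel) .. {max(rs):.3f} (best)")

err = np.max(np.abs(d.reconstruct() - s)) / np.max(np.abs(s))
print(f"channel-wise completeness: {err:.2e} relative")
# Every channel's correlation should exceed 0.9 for both modes.
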