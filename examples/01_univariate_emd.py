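"""Sift a two-tone signal into its intrinsic mode functions.

Builds x(t) = sin(2*pi*10 t) + sin(2*pi*2 t) sampled at 120 Hz, decomposes
it with univariate EMD, and checks each emitted mode against the IMF
definition and the planted tones.
"""

import numpy as np

from mocap_hht.emd import decompose, is_imf

fs = 120.0
t = np.arange(0, 4, 1 / fs)
hi = np.sin(2 * np.pi * 10 * t)
lo = np.sin(2 * np.pi * 2 * t)
x = hi + lo

d = decompose(x)
print(f"{d.n_imfs} IMFs extracted from {x.size} samples")
for j, (c, truth) in enumerate(zip(d.imfs, [hi, lo]), start=1):
    ok, diag = is_imf(c)
    r = np.corrcoef(c, truth)[0, 1]
    print(
        f"  IMF {j}: is_imf={ok} "
        f"(extrema={diag['n_extrema']}, zero-crossings={diag['n_zero_crossings']}), "
        f"correlation with planted tone = {r:.3f}"
    )
err = np.max(np.abs(d.reconstruct() - x))
print(f"completeness: max |sum(IMFs) + residual - x| = {err:.2e}")
# IMF 1 should carry the 10 Hz tone and IMF 2 the 2 Hz tone, each with
# correlation > 0.95; the reconstruction error is at float rounding.
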