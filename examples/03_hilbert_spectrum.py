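"""Instantaneous frequency and amplitude of decomposed modes.

Runs the Hilbert transform on each MEMD mode of the two-tone fixture,
smooths the frequency with WAFA, and prints the per-mode average
frequencies alongside the exported Hilbert spectrum.
"""

import numpy as np

from mocap_hht.fixtures import make_preset
from mocap_hht.hsa import build_spectrum, instantaneous_freq_amp, wafa_smooth
from mocap_hht.memd import memd_decompose

fs = 120.0
bundle = make_preset("two-tone", joint_count=3, seed=1)
d = memd_decompose(bundle.motion.values)

print(f"spectral cap: fs/4 = {fs / 4:g} Hz")
for j in range(d.n_imfs):
    tr = instantaneous_freq_amp(d.imfs[j][:, 0], fs)
    _, avg = wafa_smooth(tr)
    print(f"  IMF {j + 1}: WAFA average frequency = {avg:5.2f} Hz, "
          f"mean amplitude = {np.mean(tr.amplitude[tr.valid]):.2f} deg")

spec = build_spectrum(d, fs, bundle.motion.channel_labels, ["joint01:Xrotation"])
print(f"Hilbert spectrum of joint01:Xrotation: {len(spec.table)} "
      f"(time, frequency, amplitude) points, all <= {spec.f_max:g} Hz")
# The averages should sit near the planted 10 Hz and 2 Hz; amplitudes are
# in the source units (degrees).
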