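"""Full framework on a BVH file: decompose, read out, reconstruct.

Writes a synthetic BVH, runs all five stages, prints an event table, a
left/right-style correlation table and per-mode RMS magnitudes, then
reconstructs the motion from all modes plus the trend and verifies the
round trip.
"""

import tempfile
from pathlib import Path

import numpy as np

from mocap_hht import pipeline
from mocap_hht.fixtures import write_fixture_bundle
from mocap_hht.pipeline import EventQuery

with tempfile.TemporaryDirectory() as tmp:
    files = write_fixture_bundle(tmp, "two-tone", joint_count=3, seed=1)
    d = pipeline.run_framework(files["bvh"])
    print(f"{d.source.n_channels} channels -> {d.n_imfs} IMFs + trend, "
          f"completeness {d.completeness_error():.2e}")

    print("\nPer-IMF readout at t = 2.0 s, joint01 (freq Hz / amplitude deg):")
    print(pipeline.spectrum_at_event(d, "joint01", EventQuery("mid", 2.0))
          .to_string(index=False))

    print("\nPer-IMF correlation between joint01 and joint02:")
    print(pipeline.imf_correlations(d, "joint01", "joint02").to_string(index=False))

    print("\nPer-IMF RMS magnitude at joint01 (deg):")
    print(pipeline.imf_rms(d, "joint01").to_string(index=False))

    rec = pipeline.reconstruct_motion(d)  # all modes + trend
    err = np.max(np.abs(rec.values - d.source.values))
    print(f"\nreconstruct(all IMFs + trend) round trip: max error {err:.2e}")
# The event frequencies should match the planted 10 Hz / 2 Hz tones; RMS
# magnitudes approach amplitude/sqrt(2); the round trip is exact to rounding.
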