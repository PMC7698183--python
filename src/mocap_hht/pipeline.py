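"""End-to-end framework: BVH in, decomposed motions and spectra out.

The five stages are (1) assemble the analysis matrix — root position plus
every joint's Euler angles, (2) decompose it with multivariate EMD into
aligned modes plus a trend, (3) write each mode (and the trend) back out as
motion data, (4) transform each mode to instantaneous amplitude/frequency
via the Hilbert transform and smooth the frequency with WAFA, and
(5) compute the frequency-domain readouts: per-mode spectra, event tables,
left/right correlations and per-mode RMS magnitudes.

All readouts are pure functions of the stored decomposition: recomputing a
table never re-runs EMD.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bvh_io import MotionMatrix, Skeleton, assemble_channels, read_bvh
from .emd import SiftConfig
from .hsa import (
    HilbertSpectrum,
    InstantaneousTrack,
    WafaConfig,
    build_spectrum,
    instantaneous_freq_amp,
    wafa_smooth,
)
from .memd import DecompositionND, hammersley_directions, memd_decompose

__all__ = [
    "MotionDecomposition",
    "EventQuery",
    "run_framework",
    "decompose_motion",
    "reconstruct_motion",
    "spectrum_at_event",
    "imf_correlations",
    "imf_rms",
]

log = logging.getLogger("mocap_hht")


@dataclass
class EventQuery:
    """A labelled instant to read the spectrum at (e.g. 'Impact', 'Top')."""

    label: str
    time: float  # seconds

    def frame(self, frame_interval: float, n_frames: int) -> int:
        idx = int(round(self.time / frame_interval))
        if not (0 <= idx < n_frames):
            raise ValueError(
                f"event {self.label!r} at {self.time} s is outside the motion "
                f"(duration {(n_frames - 1) * frame_interval:.3f} s)"
            )
        return idx


@dataclass
class MotionDecomposition:
    """A decomposed motion: per-mode matrices, trend, and provenance."""

    skeleton: Skeleton
    source: MotionMatrix            # canonical analysis matrix (assembled)
    decomposition: DecompositionND
    sift_config: SiftConfig
    wafa_config: WafaConfig
    n_directions: int

    @property
    def n_imfs(self) -> int:
        return self.decomposition.n_imfs

    @property
    def fs(self) -> float:
        return self.source.sampling_rate

    def imf_motion(self, j: int) -> MotionMatrix:
        """Mode j (1-based) as a motion matrix."""
        return self.source.replace_values(self.decomposition.imfs[j - 1])

    @property
    def trend_motion(self) -> MotionMatrix:
        return self.source.replace_values(self.decomposition.residual)

    def completeness_error(self) -> float:
        """Max reconstruction error relative to the input's max magnitude."""
        err = np.max(np.abs(self.decomposition.reconstruct() - self.source.values))
        scale = max(np.max(np.abs(self.source.values)), 1.0)
        return float(err / scale)

    def track(self, j: int, channel: str) -> InstantaneousTrack:
        """Instantaneous amplitude/frequency of mode j on one channel."""
        col = self.source.channel_labels.index(channel)
        return instantaneous_freq_amp(
            self.decomposition.imfs[j - 1][:, col], self.fs, j, channel
        )

    def spectrum(self, channels: list[str] | None = None) -> HilbertSpectrum:
        return build_spectrum(
            self.decomposition, self.fs, self.source.channel_labels, channels
        )

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Store modes, trend, labels and the config snapshot in one .npz."""
        meta = {
            "frame_interval": self.source.frame_interval,
            "channel_labels": self.source.channel_labels,
            "sift_config": dataclasses.asdict(self.sift_config),
            "wafa_m": self.wafa_config.m,
            "n_directions": self.n_directions,
            "skeleton": [
                {
                    "name": j.name,
                    "parent": j.parent,
                    "offset": list(j.offset),
                    "channels": list(j.channels),
                    "is_end_site": j.is_end_site,
                }
                for j in self.skeleton.joints
            ],
        }
        arrays = {f"imf_{i}": c for i, c in enumerate(self.decomposition.imfs)}
        np.savez_compressed(
            path,
            source=self.source.values,
            residual=self.decomposition.residual,
            meta=json.dumps(meta),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MotionDecomposition":
        from .bvh_io import Joint

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            n = len([k for k in z.files if k.startswith("imf_")])
            imfs = [z[f"imf_{i}"] for i in range(n)]
            residual = z["residual"]
            source = MotionMatrix(
                z["source"], meta["frame_interval"], meta["channel_labels"]
            )
        skeleton = Skeleton([
            Joint(
                d["name"], d["parent"], np.array(d["offset"]),
                tuple(d["channels"]), d["is_end_site"],
            )
            for d in meta["skeleton"]
        ])
        sc = SiftConfig(**meta["sift_config"])
        return cls(
            skeleton, source, DecompositionND(imfs, residual),
            sc, WafaConfig(meta["wafa_m"]), meta["n_directions"],
        )


def decompose_motion(
    skeleton: Skeleton,
    motion: MotionMatrix,
    sift_config: SiftConfig | None = None,
    wafa_config: WafaConfig | None = None,
    n_directions: int = 64,
    unwrap: bool = True,
) -> MotionDecomposition:
    """Stages 1-2 on an in-memory skeleton/motion pair."""
    sift_config = sift_config or SiftConfig()
    wafa_config = wafa_config or WafaConfig()
    analysis = assemble_channels(skeleton, motion, unwrap=unwrap)
    t0 = time.perf_counter()
    directions = hammersley_directions(analysis.n_channels, n_directions)
    decomp = memd_decompose(analysis.values, sift_config, directions)
    md = MotionDecomposition(
        skeleton, analysis, decomp, sift_config, wafa_config, n_directions
    )
    log.info(
        "decomposed %d channels x %d frames into %d IMFs + trend in %.1f s "
        "(completeness residual %.2e)",
        analysis.n_channels, analysis.n_frames, decomp.n_imfs,
        time.perf_counter() - t0, md.completeness_error(),
    )
    return md


def run_framework(
    bvh_path: str | Path,
    sift_config: SiftConfig | None = None,
    wafa_config: WafaConfig | None = None,
    n_directions: int = 64,
    unwrap: bool = True,
) -> MotionDecomposition:
    """Full pipeline from a BVH file; deterministic for a fixed config."""
    skeleton, motion = read_bvh(bvh_path)
    log.info(
        "read %s: %d joints, %d channels, %d frames at %.0f Hz",
        bvh_path, len(skeleton.joint_names()), motion.n_channels,
        motion.n_frames, motion.sampling_rate,
    )
    return decompose_motion(
        skeleton, motion, sift_config, wafa_config, n_directions, unwrap
    )


def reconstruct_motion(
    d: MotionDecomposition,
    imf_band: list[int] | None = None,
    include_trend: bool = True,
) -> MotionMatrix:
    """Sum a band of modes (1-based indices), optionally plus the trend.

    The trend is the time-varying posture; a mode band without it is a pure
    oscillation about zero and only renders as motion once the trend is
    added back.  The full band plus trend reproduces the input exactly (to
    rounding).
    """
    if imf_band is None:
        imf_band = list(range(1, d.n_imfs + 1))
    bad = [j for j in imf_band if not (1 <= j <= d.n_imfs)]
    if bad:
        raise IndexError(f"IMF indices out of range 1..{d.n_imfs}: {bad}")
    if not imf_band and not include_trend:
        log.warning("empty band without trend: returning zero motion")
    values = np.zeros_like(d.source.values)
    for j in imf_band:
        values = values + d.decomposition.imfs[j - 1]
    if include_trend:
        values = values + d.decomposition.residual
    return d.source.replace_values(values)


def _joint_rotation_tracks(
    d: MotionDecomposition, joint: str, j: int
) -> list[InstantaneousTrack]:
    cols = d.skeleton.rotation_columns(joint, d.source.channel_labels)
    labels = [d.source.channel_labels[c] for c in cols]
    return [d.track(j, lab) for lab in labels]


def _nearest_valid(frame: int, valid: np.ndarray) -> tuple[int, bool]:
    if valid[frame]:
        return frame, False
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        raise ValueError("track has no valid frames")
    return int(idx[np.argmin(np.abs(idx - frame))]), True


def spectrum_at_event(
    d: MotionDecomposition,
    joint: str,
    q: EventQuery,
) -> pd.DataFrame:
    """Per-mode (frequency Hz, amplitude deg) at one event for one joint.

    Frequency is the WAFA-smoothed value at the event frame, aggregated
    over the joint's three rotation axes by amplitude-weighted mean;
    amplitude is the root-sum-square over the axes.  If the event frame is
    masked, the nearest valid frame is used and flagged.
    """
    frame = q.frame(d.source.frame_interval, d.source.n_frames)
    rows = []
    for j in range(1, d.n_imfs + 1):
        tracks = _joint_rotation_tracks(d, joint, j)
        freqs, amps, moved = [], [], False
        for tr in tracks:
            sm, _ = wafa_smooth(tr, d.wafa_config)
            k, shifted = _nearest_valid(frame, tr.valid & np.isfinite(sm))
            moved |= shifted
            freqs.append(sm[k])
            amps.append(tr.amplitude[k])
        freqs_a, amps_a = np.array(freqs), np.array(amps)
        w = amps_a.sum()
        f_agg = float(np.sum(freqs_a * amps_a) / w) if w > 0 else float("nan")
        a_agg = float(np.sqrt(np.sum(amps_a**2)))
        rows.append({
            "imf": j, "event": q.label, "frequency_hz": f_agg,
            "amplitude_deg": a_agg, "frame_shifted": moved,
        })
    return pd.DataFrame(rows)


def imf_correlations(
    d: MotionDecomposition,
    joint_a: str,
    joint_b: str,
) -> pd.DataFrame:
    """Pearson R between two joints' per-mode frequency and amplitude tracks.

    Tracks are aggregated over each joint's rotation axes the same way as
    event readouts (amplitude-weighted frequency, root-sum-square
    amplitude) and correlated over frames valid in both joints.  Constant
    tracks have undefined correlation and report NaN.
    """
    rows = []
    for j in range(1, d.n_imfs + 1):
        agg = {}
        for name in (joint_a, joint_b):
            tracks = _joint_rotation_tracks(d, name, j)
            A = np.stack([t.amplitude for t in tracks])
            Fr = np.stack([wafa_smooth(t, d.wafa_config)[0] for t in tracks])
            w = A.sum(axis=0)
            freq = np.where(w > 0, np.sum(Fr * A, axis=0) / np.where(w > 0, w, 1), np.nan)
            amp = np.sqrt(np.sum(A**2, axis=0))
            valid = np.all([t.valid for t in tracks], axis=0) & np.isfinite(freq)
            agg[name] = (freq, amp, valid)
        fa, aa, va = agg[joint_a]
        fb, ab, vb = agg[joint_b]
        sel = va & vb
        rows.append({
            "imf": j,
            "r_frequency": _pearson(fa[sel], fb[sel]),
            "r_amplitude": _pearson(aa[sel], ab[sel]),
        })
    return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def imf_rms(d: MotionDecomposition, joint: str) -> pd.DataFrame:
    """Per-mode and trend RMS magnitude over a joint's rotation axes.

    For each frame, the root mean square of the component's values over the
    joint's rotation channels; reported as mean +- std over frames, in
    degrees.  This measures how much motion each mode carries at the joint.
    """
    cols = d.skeleton.rotation_columns(joint, d.source.channel_labels)
    rows = []
    components = [(f"IMF {j}", d.decomposition.imfs[j - 1]) for j in range(1, d.n_imfs + 1)]
    components.append(("Trend", d.decomposition.residual))
    for name, mat in components:
        per_frame = np.sqrt(np.mean(mat[:, cols] ** 2, axis=1))
        rows.append({
            "component": name,
            "rms_mean": float(per_frame.mean()),
            "rms_std": float(per_frame.std()),
        })
    return pd.DataFrame(rows)
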