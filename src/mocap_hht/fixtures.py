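"""Deterministic synthetic motion generators.

Every stage of the framework is testable offline against signals whose
oscillatory content is known exactly: a small set of AM/FM tone components
A*(1 + depth*sin(2*pi*rate*t))*cos(2*pi*f*t + phi) spread across channels
with per-channel random phases, a slow polynomial trend standing in for
posture, and optional Gaussian noise.  Component frequencies stay below a
quarter of the sampling rate so the planted ground truth remains
recoverable under the spectral cap, and "well-separated" presets keep a
factor >= 3 between component frequencies so the decomposition should
isolate each tone in its own mode.

All randomness flows through one seeded generator per call; the same seed
reproduces the same matrices bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bvh_io import Joint, MotionMatrix, Skeleton, write_bvh

__all__ = [
    "ComponentSpec",
    "make_skeleton",
    "make_signal",
    "write_fixture_bundle",
    "PRESETS",
]


@dataclass
class ComponentSpec:
    """One planted oscillatory component.

    ``channels=None`` means all channels.  Phases are drawn per channel
    unless ``phase`` pins them.  ``am_depth``/``am_rate`` give a slow
    sinusoidal amplitude modulation.
    """

    frequency: float  # Hz
    amplitude: float  # degrees (or source units)
    phase: float | None = None  # radians; None -> random per channel
    am_depth: float = 0.0
    am_rate: float = 0.0  # Hz
    channels: list[int] | None = None


def make_skeleton(joint_count: int) -> Skeleton:
    """Chain skeleton: a 6-channel root plus 3-rotation joints below it.

    ``joint_count`` counts rotating joints including the root, so the
    channel total is 3 + 3*joint_count (132 for 43 joints, the layout of a
    fully three-degree-of-freedom full-body skeleton).
    """
    if joint_count < 1:
        raise ValueError("need at least one joint")
    joints = [Joint(
        "root", None, np.zeros(3),
        ("Xposition", "Yposition", "Zposition", "Xrotation", "Yrotation", "Zrotation"),
    )]
    for i in range(1, joint_count):
        joints.append(Joint(
            f"joint{i:02d}", i - 1, np.array([0.0, 1.0, 0.0]),
            ("Xrotation", "Yrotation", "Zrotation"),
        ))
    joints.append(Joint(
        f"joint{joint_count - 1:02d}_End" if joint_count > 1 else "root_End",
        joint_count - 1, np.array([0.0, 1.0, 0.0]), (), is_end_site=True,
    ))
    return Skeleton(joints)


def make_signal(
    specs: list[ComponentSpec],
    n_channels: int,
    trend: list[float] | None = None,
    noise_sd: float = 0.0,
    fs: float = 120.0,
    duration: float = 4.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Multichannel signal with known components.

    Returns (frames x channels matrix, ground truth) where ground truth
    maps component index to its frames x channels contribution.  The trend
    polynomial (coefficients in ascending powers of time in seconds) and
    noise are added on top.  Fully reproducible from ``seed``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n_frames = int(round(duration * fs))
    if n_frames < 64:
        raise ValueError("duration * fs must be at least 64 frames")
    for s in specs:
        if s.frequency >= fs / 4.0:
            raise ValueError(
                f"component at {s.frequency} Hz is unrecoverable above fs/4 = {fs / 4} Hz"
            )
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fs

    total = np.zeros((n_frames, n_channels))
    truth: dict[int, np.ndarray] = {}
    for i, s in enumerate(specs):
        chans = list(range(n_channels)) if s.channels is None else s.channels
        comp = np.zeros((n_frames, n_channels))
        for ch in chans:
            phi = s.phase if s.phase is not None else rng.uniform(0, 2 * np.pi)
            env = s.amplitude * (1.0 + s.am_depth * np.sin(2 * np.pi * s.am_rate * t))
            comp[:, ch] = env * np.cos(2 * np.pi * s.frequency * t + phi)
        truth[i] = comp
        total += comp

    if trend:
        poly = sum(c * t**p for p, c in enumerate(trend))
        total += poly[:, None]
    if noise_sd > 0:
        total += rng.normal(0.0, noise_sd, total.shape)
    return total, truth


# ---------------------------------------------------------------------------
# presets

def _two_tone(n_channels: int) -> list[ComponentSpec]:
    return [
        ComponentSpec(frequency=10.0, amplitude=5.0),
        ComponentSpec(frequency=2.0, amplitude=10.0),
    ]


def _jump_like(n_channels: int) -> list[ComponentSpec]:
    # burst-localised high band over a sustained slow oscillation
    return [
        ComponentSpec(frequency=12.0, amplitude=3.0, am_depth=0.9, am_rate=0.25),
        ComponentSpec(frequency=1.5, amplitude=12.0),
    ]


def _gait_like(n_channels: int) -> list[ComponentSpec]:
    # shared periodic base; one channel carries an extra mid-band tone
    return [
        ComponentSpec(frequency=9.0, amplitude=2.0, channels=[0]),
        ComponentSpec(frequency=1.0, amplitude=15.0),
    ]


PRESETS = {
    "two-tone": {"components": _two_tone, "trend": [5.0, 2.0], "duration": 4.0},
    "jump-like": {"components": _jump_like, "trend": [10.0, 0.0, 0.5], "duration": 4.0},
    "gait-like": {"components": _gait_like, "trend": [0.0, 3.0], "duration": 4.0},
}


@dataclass
class FixtureBundle:
    skeleton: Skeleton
    motion: MotionMatrix
    truth: dict[int, np.ndarray]
    components: list[ComponentSpec]
    manifest: dict = field(default_factory=dict)


def make_preset(
    preset: str,
    joint_count: int = 3,
    fs: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float | None = None,
) -> FixtureBundle:
    """Build a named preset as an in-memory skeleton + motion + ground truth."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    skeleton = make_skeleton(joint_count)
    n_channels = skeleton.n_channels
    duration = duration if duration is not None else cfg["duration"]
    specs = cfg["components"](n_channels)
    values, truth = make_signal(
        specs, n_channels, trend=cfg["trend"], noise_sd=noise_sd,
        fs=fs, duration=duration, seed=seed,
    )
    motion = MotionMatrix(values, 1.0 / fs, skeleton.channel_labels)
    manifest = {
        "preset": preset,
        "joint_count": joint_count,
        "fs": fs,
        "duration": duration,
        "noise_sd": noise_sd,
        "seed": seed,
        "components": [
            {
                "frequency": s.frequency, "amplitude": s.amplitude,
                "phase": s.phase, "am_depth": s.am_depth, "am_rate": s.am_rate,
                "channels": s.channels,
            }
            for s in specs
        ],
    }
    return FixtureBundle(skeleton, motion, truth, specs, manifest)


def write_fixture_bundle(
    path: str | Path,
    preset: str,
    joint_count: int = 3,
    fs: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float | None = None,
) -> dict[str, Path]:
    """Write a preset to disk: BVH + ground-truth CSV + JSON manifest."""
    bundle = make_preset(preset, joint_count, fs, noise_sd, seed, duration)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "bvh": path / f"{preset}.bvh",
        "truth": path / f"{preset}_truth.csv",
        "manifest": path / f"{preset}_manifest.json",
    }
    write_bvh(bundle.skeleton, bundle.motion, files["bvh"])
    frames = bundle.motion.n_frames
    cols = {}
    for i, mat in bundle.truth.items():
        f = bundle.components[i].frequency
        for ch in range(mat.shape[1]):
            cols[f"component{i}_f{f:g}Hz_ch{ch}"] = mat[:, ch]
    pd.DataFrame(cols, index=np.arange(frames)).to_csv(files["truth"], index_label="frame")
    files["manifest"].write_text(json.dumps(bundle.manifest, indent=2) + "\n")
    return files
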