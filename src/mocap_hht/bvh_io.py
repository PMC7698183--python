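"""BVH (Biovision Hierarchy) reading, writing and channel assembly.

A BVH file holds a joint hierarchy (HIERARCHY section: ROOT/JOINT/End Site
nodes with OFFSET and CHANNELS declarations) and a MOTION section with one
row of channel values per frame.  The root contributes three position
channels plus rotations; every other joint contributes up to three Euler
rotation channels.  For a fully three-degree-of-freedom skeleton with J
rotating joints the channel count is 3 + 3*J (132 for the 43-joint CMU
skeleton sampled at 120 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Joint",
    "Skeleton",
    "MotionMatrix",
    "BvhParseError",
    "BvhIntegrityError",
    "read_bvh",
    "write_bvh",
    "assemble_channels",
]

_POSITION_CHANNELS = {"Xposition", "Yposition", "Zposition"}
_ROTATION_CHANNELS = {"Xrotation", "Yrotation", "Zrotation"}
_AXIS_OF = {
    "Xposition": "X", "Yposition": "Y", "Zposition": "Z",
    "Xrotation": "x", "Yrotation": "y", "Zrotation": "z",
}


class BvhParseError(ValueError):
    """Raised when the HIERARCHY section violates the BVH grammar."""


class BvhIntegrityError(ValueError):
    """Raised when the MOTION section disagrees with its own header."""


@dataclass
class Joint:
    """One node of the hierarchy.

    ``channels`` holds the declared channel names in file order (empty for
    End Sites).  ``is_end_site`` nodes are retained structurally but never
    contribute motion columns.
    """

    name: str
    parent: int | None
    offset: np.ndarray
    channels: tuple[str, ...] = ()
    is_end_site: bool = False


@dataclass
class Skeleton:
    """Ordered joint list; parents always precede children."""

    joints: list[Joint] = field(default_factory=list)

    def __post_init__(self) -> None:
        roots = [j for j in self.joints if j.parent is None and not j.is_end_site]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        for i, j in enumerate(self.joints):
            if j.parent is not None and not (0 <= j.parent < i):
                raise ValueError(f"joint {j.name!r}: parent index {j.parent} does not precede it")

    @property
    def channel_labels(self) -> list[str]:
        """Column labels in file declaration order, e.g. ``hip:Xposition``."""
        labels = []
        for j in self.joints:
            labels.extend(f"{j.name}:{ch}" for ch in j.channels)
        return labels

    @property
    def n_channels(self) -> int:
        return sum(len(j.channels) for j in self.joints)

    def joint_names(self, include_end_sites: bool = False) -> list[str]:
        return [j.name for j in self.joints if include_end_sites or not j.is_end_site]

    def rotation_columns(self, joint_name: str, labels: Sequence[str] | None = None) -> list[int]:
        """Column indices of a joint's rotation channels within ``labels``
        (defaults to the skeleton's own file-order labels)."""
        labels = list(labels) if labels is not None else self.channel_labels
        prefix = joint_name + ":"
        cols = [
            i for i, lab in enumerate(labels)
            if lab.startswith(prefix) and lab.split(":")[1] in _ROTATION_CHANNELS
        ]
        if not cols:
            raise KeyError(f"no rotation channels for joint {joint_name!r}")
        return cols


@dataclass
class MotionMatrix:
    """frames x channels motion data with a fixed frame interval.

    Positions are in file units, rotations in degrees.  Sampling rate is
    ``1 / frame_interval`` (120 Hz for CMU recordings).
    """

    values: np.ndarray
    frame_interval: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("motion values must be a frames x channels matrix")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.values.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def replace_values(self, values: np.ndarray) -> "MotionMatrix":
        return MotionMatrix(values, self.frame_interval, list(self.channel_labels))


# ---------------------------------------------------------------------------
# parsing


def _tokenize(text: str) -> list[tuple[int, str]]:
    toks: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for tok in line.split():
            toks.append((lineno, tok))
    return toks


class _TokenStream:
    def __init__(self, toks: list[tuple[int, str]]):
        self._toks = toks
        self._i = 0

    @property
    def lineno(self) -> int:
        if self._i < len(self._toks):
            return self._toks[self._i][0]
        return self._toks[-1][0] if self._toks else 0

    def peek(self) -> str | None:
        return self._toks[self._i][1] if self._i < len(self._toks) else None

    def next(self) -> str:
        if self._i >= len(self._toks):
            raise BvhParseError("unexpected end of file")
        tok = self._toks[self._i][1]
        self._i += 1
        return tok

    def expect(self, literal: str) -> None:
        tok = self.next()
        if tok != literal:
            raise BvhParseError(f"line {self.lineno}: expected {literal!r}, found {tok!r}")

    def rest(self) -> list[str]:
        out = [t for _, t in self._toks[self._i:]]
        self._i = len(self._toks)
        return out


def _parse_offset(ts: _TokenStream) -> np.ndarray:
    ts.expect("OFFSET")
    lineno = ts.lineno
    try:
        return np.array([float(ts.next()) for _ in range(3)])
    except ValueError as exc:
        raise BvhParseError(f"line {lineno}: non-numeric OFFSET value") from exc


def _parse_joint(ts: _TokenStream, parent: int | None, joints: list[Joint]) -> None:
    kind = ts.next()
    if kind not in ("ROOT", "JOINT", "End"):
        raise BvhParseError(f"line {ts.lineno}: expected ROOT/JOINT/End Site, found {kind!r}")
    if kind == "End":
        ts.expect("Site")
        name = joints[parent].name + "_End" if parent is not None else "End"
        ts.expect("{")
        offset = _parse_offset(ts)
        ts.expect("}")
        joints.append(Joint(name, parent, offset, (), is_end_site=True))
        return
    name = ts.next()
    ts.expect("{")
    offset = _parse_offset(ts)
    ts.expect("CHANNELS")
    try:
        n_ch = int(ts.next())
    except ValueError as exc:
        raise BvhParseError(f"line {ts.lineno}: CHANNELS count is not an integer") from exc
    channels = tuple(ts.next() for _ in range(n_ch))
    bad = [c for c in channels if c not in _POSITION_CHANNELS | _ROTATION_CHANNELS]
    if bad:
        raise BvhParseError(f"line {ts.lineno}: unknown channel name(s) {bad}")
    me = len(joints)
    joints.append(Joint(name, parent, offset, channels))
    while ts.peek() != "}":
        _parse_joint(ts, me, joints)
    ts.expect("}")


def read_bvh(path: str | Path) -> tuple[Skeleton, MotionMatrix]:
    """Parse a BVH file into a skeleton and its motion matrix.

    Columns follow the file's channel declaration order; frame count and
    frame time come from the MOTION header.  End Site nodes are kept in the
    skeleton but contribute no columns.

    Raises
    ------
    BvhParseError
        Malformed HIERARCHY section (the message names the offending line).
    BvhIntegrityError
        MOTION data row/column count disagrees with the declared header.
    """
    text = Path(path).read_text()
    ts = _TokenStream(_tokenize(text))
    ts.expect("HIERARCHY")
    joints: list[Joint] = []
    _parse_joint(ts, None, joints)
    skeleton = Skeleton(joints)

    ts.expect("MOTION")
    ts.expect("Frames:")
    try:
        n_frames = int(ts.next())
    except ValueError as exc:
        raise BvhParseError(f"line {ts.lineno}: frame count is not an integer") from exc
    ts.expect("Frame")
    ts.expect("Time:")
    try:
        frame_interval = float(ts.next())
    except ValueError as exc:
        raise BvhParseError(f"line {ts.lineno}: frame time is not a number") from exc

    data_tokens = ts.rest()
    n_ch = skeleton.n_channels
    expected = n_frames * n_ch
    if len(data_tokens) != expected:
        raise BvhIntegrityError(
            f"MOTION declares {n_frames} frames x {n_ch} channels = {expected} values, "
            f"found {len(data_tokens)}"
        )
    try:
        values = np.array(data_tokens, dtype=float).reshape(n_frames, n_ch)
    except ValueError as exc:
        raise BvhIntegrityError("non-numeric value in MOTION data") from exc
    motion = MotionMatrix(values, frame_interval, skeleton.channel_labels)
    return skeleton, motion


# ---------------------------------------------------------------------------
# writing


def write_bvh(
    skeleton: Skeleton,
    motion: MotionMatrix,
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write a skeleton + motion pair as a BVH file.

    ``precision`` controls the number of decimals in OFFSET and MOTION
    values; the emitted file round-trips through :func:`read_bvh` to that
    precision and loads in standard BVH viewers.
    """
    if motion.n_channels != skeleton.n_channels:
        raise ValueError(
            f"motion has {motion.n_channels} channels, skeleton declares {skeleton.n_channels}"
        )
    if motion.n_frames == 0:
        raise ValueError("cannot write a motion with zero frames")

    children: dict[int, list[int]] = {}
    for i, j in enumerate(skeleton.joints):
        if j.parent is not None:
            children.setdefault(j.parent, []).append(i)

    lines = ["HIERARCHY"]

    def fmt(x: float) -> str:
        return f"{x:.{precision}f}"

    def emit(idx: int, depth: int) -> None:
        j = skeleton.joints[idx]
        pad = "  " * depth
        if j.is_end_site:
            lines.append(f"{pad}End Site")
            lines.append(f"{pad}{{")
            lines.append(f"{pad}  OFFSET {' '.join(fmt(v) for v in j.offset)}")
            lines.append(f"{pad}}}")
            return
        kw = "ROOT" if j.parent is None else "JOINT"
        lines.append(f"{pad}{kw} {j.name}")
        lines.append(f"{pad}{{")
        lines.append(f"{pad}  OFFSET {' '.join(fmt(v) for v in j.offset)}")
        lines.append(f"{pad}  CHANNELS {len(j.channels)} {' '.join(j.channels)}")
        for c in children.get(idx, []):
            emit(c, depth + 1)
        lines.append(f"{pad}}}")

    root = next(i for i, j in enumerate(skeleton.joints) if j.parent is None)
    emit(root, 0)

    lines.append("MOTION")
    lines.append(f"Frames: {motion.n_frames}")
    # repr gives the shortest digit string that round-trips the float, so
    # 1/120 survives read(write(...)) exactly and fs-derived values (the
    # fs/4 spectral cap) stay exact
    lines.append(f"Frame Time: {motion.frame_interval!r}")
    for row in motion.values:
        lines.append(" ".join(fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# channel assembly


def assemble_channels(
    skeleton: Skeleton,
    motion: MotionMatrix,
    unwrap: bool = True,
) -> MotionMatrix:
    """Reorder the raw motion matrix into the canonical analysis layout.

    Canonical order: root position X, Y, Z first, then each joint in
    hierarchy order with its rotations sorted as theta_x, theta_y, theta_z
    (whatever order the file declared them in).  With ``unwrap`` set
    (default), rotation channels are unwrapped so +-180/360 degree jumps do
    not manufacture spurious envelope extrema downstream.
    """
    labels = skeleton.channel_labels
    order: list[int] = []
    out_labels: list[str] = []

    root = next(j for j in skeleton.joints if j.parent is None)
    for axis in ("X", "Y", "Z"):
        ch = f"{axis}position"
        lab = f"{root.name}:{ch}"
        if lab in labels:
            order.append(labels.index(lab))
            out_labels.append(lab)

    for j in skeleton.joints:
        if j.is_end_site:
            continue
        for axis in ("X", "Y", "Z"):
            lab = f"{j.name}:{axis}rotation"
            if lab in labels:
                order.append(labels.index(lab))
                out_labels.append(lab)

    values = motion.values[:, order].copy()
    if unwrap:
        is_rot = np.array([lab.split(":")[1] in _ROTATION_CHANNELS for lab in out_labels])
        values[:, is_rot] = np.rad2deg(np.unwrap(np.deg2rad(values[:, is_rot]), axis=0))
    return MotionMatrix(values, motion.frame_interval, out_labels)
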