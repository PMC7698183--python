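"""Multivariate empirical mode decomposition (MEMD).

Univariate EMD applied channel-by-channel yields different mode counts per
channel, which breaks any cross-channel comparison at a fixed mode index.
MEMD instead treats the n channels as one signal s(t) in R^n, projects it
onto V quasi-uniform unit directions on the (n-1)-sphere (a deterministic
Hammersley low-discrepancy set), builds one n-dimensional spline envelope
per direction through the signal values at that projection's maxima, and
sifts with the mean of those envelopes:

    m(t) = (1/V) * sum_v e_v(t),    c <- c - m(t).

Minima of a projection are the maxima of the opposite direction, so a
direction set covering the whole sphere handles both envelope sheets.
Every channel receives the same number of modes by construction, which is
what allows per-mode comparisons between joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .emd import ResidualReached, SiftConfig, find_extrema, _mirror_extend

__all__ = [
    "DirectionSet",
    "DecompositionND",
    "hammersley_directions",
    "project",
    "multivariate_envelope_mean",
    "memd_decompose",
]

_PRIMES = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61, 67,
           71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113, 127, 131, 137, 139, 149]


@dataclass
class DirectionSet:
    """V unit vectors in R^n from the Hammersley construction."""

    vectors: np.ndarray  # V x n
    bases: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("direction vectors must be unit length")

    @property
    def V(self) -> int:
        return self.vectors.shape[0]

    @property
    def n(self) -> int:
        return self.vectors.shape[1]


def _radical_inverse(k: np.ndarray, base: int) -> np.ndarray:
    """Van der Corput radical inverse of integers k in the given base."""
    k = np.asarray(k, dtype=np.int64)
    out = np.zeros(k.shape, dtype=float)
    f = 1.0 / base
    while np.any(k > 0):
        out += f * (k % base)
        k = k // base
        f /= base
    return out


def _more_primes(count: int) -> list[int]:
    primes = list(_PRIMES)
    cand = primes[-1]
    while len(primes) < count:
        cand += 2
        if all(cand % p for p in primes if p * p <= cand):
            primes.append(cand)
    return primes[:count]


def hammersley_directions(n: int, V: int = 64) -> DirectionSet:
    """Quasi-uniform unit direction vectors on the (n-1)-sphere.

    The k-th Hammersley point in [0,1)^(n-1) has first coordinate k/V and
    remaining coordinates the radical inverse of k in successive prime
    bases 2, 3, 5, ...  Points map to the sphere through hyperspherical
    angles: the first n-2 coordinates scale to polar angles in [0, pi], the
    last to the azimuthal angle in [0, 2*pi).  Deterministic for fixed
    (n, V).
    """
    if n < 2:
        raise ValueError("need at least 2 channels; univariate signals use plain EMD")
    if V < 1:
        raise ValueError("V must be >= 1")
    k = np.arange(V)
    n_angles = n - 1
    u = np.empty((V, n_angles))
    u[:, 0] = (k + 0.5) / V
    bases = _more_primes(max(0, n_angles - 1))
    for j, b in enumerate(bases):
        u[:, j + 1] = _radical_inverse(k, b)

    theta = np.empty_like(u)
    theta[:, :-1] = np.pi * u[:, :-1]
    theta[:, -1] = 2.0 * np.pi * u[:, -1]

    vec = np.ones((V, n))
    for j in range(n_angles):
        vec[:, j] *= np.cos(theta[:, j])
        vec[:, j + 1:] *= np.sin(theta[:, j])[:, None]
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return DirectionSet(vec, tuple(bases))


@dataclass
class DecompositionND:
    """Aligned multivariate modes: each IMF is a frames x channels matrix."""

    imfs: list[np.ndarray] = field(default_factory=list)
    residual: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


def project(s: np.ndarray, directions: DirectionSet) -> np.ndarray:
    """Inner product of each frame with each direction: a V x frames array."""
    s = np.asarray(s, dtype=float)
    return directions.vectors @ s.T


def multivariate_envelope_mean(s: np.ndarray, directions: DirectionSet) -> np.ndarray:
    """Mean of the per-direction multivariate envelopes.

    For each direction v: locate the maxima of the scalar projection
    s(t).v, pass a component-wise natural cubic spline through the full
    n-dimensional signal values at those times (mirror boundary extension
    as in the univariate case), and evaluate it on every frame.  The
    returned mean averages over directions; directions whose projection has
    fewer than two maxima are dropped and the mean renormalised.

    Raises
    ------
    ResidualReached
        More than half the directions lack enough projection extrema.
    """
    s = np.asarray(s, dtype=float)
    n_frames = s.shape[0]
    t = np.arange(n_frames)
    proj = project(s, directions)

    total = np.zeros_like(s)
    kept = 0
    for v in range(directions.V):
        max_idx, _, _, _ = find_extrema(proj[v])
        if max_idx.size < 2:
            continue
        # mirror the extremum *times* about the ends; envelope knots carry
        # the full signal vector observed at those times
        ext_idx, _ = _mirror_extend(max_idx, proj[v][max_idx], n_frames)
        knots = s[_mirror_source(ext_idx, n_frames)]
        env = CubicSpline(ext_idx, knots, bc_type="natural", axis=0)(t)
        total += env
        kept += 1
    if kept < (directions.V + 1) // 2:
        raise ResidualReached(
            f"only {kept}/{directions.V} directions have enough projection extrema"
        )
    return total / kept


def _mirror_source(ext_idx: np.ndarray, n: int) -> np.ndarray:
    """Map mirror-extended knot indices back to source frames in [0, n-1]."""
    src = np.abs(ext_idx)
    over = src > n - 1
    src[over] = 2 * (n - 1) - src[over]
    return src


def _vector_sd(c_old: np.ndarray, c_new: np.ndarray) -> float:
    denom = float(np.sum(c_old**2))
    if denom == 0.0:
        raise ZeroDivisionError("SD criterion undefined for zero-energy signal")
    return float(np.sum((c_old - c_new) ** 2)) / denom


def memd_decompose(
    s: np.ndarray,
    config: SiftConfig | None = None,
    directions: DirectionSet | None = None,
) -> DecompositionND:
    """Full MEMD of a frames x channels signal.

    Each prospective mode is sifted with the multivariate envelope mean
    until the SD criterion (applied to the frame-wise vector change) drops
    to ``sd_stop`` or the iteration cap; the finished mode is subtracted
    and extraction repeats until the running signal is a residual (too few
    projection extrema in most directions).  Deterministic: the Hammersley
    direction set is generated once per decomposition and reused for every
    mode.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2:
        raise ValueError("signal must be a frames x channels matrix")
    n_frames, n_chan = s.shape
    if n_frames < 5:
        raise ValueError("need at least 5 frames")
    if n_chan < 2:
        raise ValueError("univariate signals use emd.decompose")
    config = config or SiftConfig()
    if directions is None:
        directions = hammersley_directions(n_chan, 64)
    elif directions.n != n_chan:
        raise ValueError(f"direction set is {directions.n}-dimensional, signal has {n_chan}")

    imfs: list[np.ndarray] = []
    r = s.copy()
    while config.max_imfs is None or len(imfs) < config.max_imfs:
        try:
            c = _sift_to_mode(r, config, directions)
        except ResidualReached:
            break
        if np.allclose(c, 0):
            break
        imfs.append(c)
        r = r - c
    return DecompositionND(imfs=imfs, residual=r)


def _sift_to_mode(r: np.ndarray, config: SiftConfig, directions: DirectionSet) -> np.ndarray:
    c_old = r.copy()
    for _ in range(config.max_sift_iters):
        m = multivariate_envelope_mean(c_old, directions)
        c_new = c_old - m
        sd = _vector_sd(c_old, c_new)
        # vector analogue of the IMF envelope clause: the removed mean must
        # be small next to the candidate's peak frame-wise norm
        env_ok = (
            np.max(np.linalg.norm(m, axis=1))
            <= config.envelope_tol * np.max(np.linalg.norm(c_old, axis=1))
        )
        c_old = c_new
        if sd <= config.sd_stop and env_ok:
            break
    return c_old
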