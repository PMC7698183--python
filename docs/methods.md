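# Methods

## Model and assumptions

The package treats a motion-capture recording as a multivariate,
nonstationary signal s(t) ∈ ℝⁿ: the root joint's three positions plus three
Euler angles per joint, sampled at a fixed rate (1 / frame interval; 120 Hz
for typical full-body recordings). The working assumption of Hilbert
spectral analysis is that each analysed component is *pseudo monochromatic*
— locally of the form A(t)·cos(ω(t)·t) with A and ω varying slowly relative
to the oscillation itself. Raw joint angles violate this badly, which is why
the decomposition stage exists: empirical mode decomposition peels the
signal into intrinsic mode functions (IMFs) that satisfy the assumption
approximately, ordered fast to slow, plus a residual trend interpreted as
the time-varying posture. No parametric model of the skeleton dynamics is
assumed anywhere; the decomposition is entirely data-driven, and its
correctness criteria are structural (the IMF definition, completeness of the
reconstruction) rather than goodness-of-fit to a generative model.

## Sifting and its stopping rule

One sift subtracts the mean of the upper and lower natural cubic-spline
envelopes (through maxima and minima respectively). Two conditions end the
sift loop for a candidate mode, both required:

1. **SD criterion** — the normalised energy of the change,
   SD = Σₜ(c_old − c_new)² / Σₜ c_old², falls below `sd_stop` (default 0.25,
   inside the conventional 0.2–0.3 band). A per-sample-ratio variant is
   available (`sd_mode="pointwise"`) but is not the default: its summands
   diverge wherever c_old passes through zero.
2. **Envelope-mean condition** — the removed envelope mean is everywhere
   within `envelope_tol` (default 0.05) of the candidate's peak amplitude.
   Because c_old − c_new *is* the envelope mean, the SD threshold alone is
   satisfiable in one sift by a candidate whose bias is small in energy but
   visible pointwise; adding this clause makes emitted modes satisfy the
   second half of the IMF definition by construction. This mirrors the
   amplitude-ratio stopping rule long used in EMD practice.

Both are capped at `max_sift_iters` = 100. Mode extraction stops when the
running residual has fewer than three extrema (univariate) or when most
projection directions lack the two maxima a spline envelope needs
(multivariate). Everything is deterministic; there is no randomness in
either decomposition.

**Boundary handling.** Spline envelopes are extended past both record ends
by mirror-reflecting the two edge extrema about each endpoint. End effects
are the best-known artifact of envelope-based decomposition; mirroring keeps
them local (a few extremum spacings) but does not eliminate them, which is
why instantaneous readouts mask edge frames.

**Extrema conventions.** Strict sign changes of the first difference; a flat
plateau bounded by opposite slopes yields one extremum at its (floored)
midpoint. Zero crossings count sign changes between consecutive nonzero
samples, with a run of exact zeros between same-signed neighbours counted as
a single touch.

## Multivariate extension

Directions are generated from the Hammersley low-discrepancy set: point k of
V has first coordinate (k + ½)/V and remaining coordinates the radical
inverse of k in successive prime bases (2, 3, 5, …), mapped to the unit
(n−1)-sphere through hyperspherical angles (first n−2 coordinates scaled to
[0, π], last to [0, 2π)). The half-offset on the first coordinate avoids the
degenerate pole point at k = 0. For each direction the scalar projection's
*maxima* define the knot times of one n-dimensional envelope (component-wise
cubic splines through the full signal vectors at those times); minima need
no separate treatment because the minima of a projection are the maxima of
the antipodal direction, and the direction set covers the whole sphere. The
sift mean averages the surviving directions; directions whose projection has
fewer than two maxima are dropped and the mean renormalised, and when more
than half drop the signal is declared a residual. One direction set is
generated per decomposition and reused for every mode — the construction is
deterministic in (n, V), so regenerating it per mode would change nothing.

The SD criterion generalises by applying the same energy ratio to the
frame-wise vector change, and the envelope-mean condition to the frame-wise
Euclidean norm.

## Instantaneous estimates

The analytic signal is built in the frequency domain (one-sided spectrum),
not by quadrature of the principal-value integral. Amplitude is the complex
modulus; frequency is the central finite difference of the unwrapped
two-argument phase divided by 2πΔt, converted to Hz throughout because
every reported table is in Hz. The discrete double-differencing implicit in
this chain restricts the usable band to a quarter of the sampling rate, so
the spectral axis is capped at fs/4 (30 Hz at 120 Hz) and out-of-band
samples are clipped and flagged. First and last frames, and frames whose
amplitude is below 1e−12, are masked invalid and omitted from spectra.

## WAFA smoothing

The amplitude-weighted moving average uses a nominal odd window m with three
regimes: near the left edge the window is [1, k+(m−1)/2], in the interior
the full centred window, near the right edge [k−(m−1)/2, N]; the regime
boundaries are chosen so the three ranges partition [1, N] exactly and the
edge treatment is symmetric. The default m = 31 frames (~0.26 s at 120 Hz)
is a compromise: long enough to average over a cycle of the fast modes where
their amplitude is small and the raw frequency noisiest, short enough not to
displace event timing by more than ~0.1 s; it is exposed in `WafaConfig`.
The scalar per-mode "average frequency" is the amplitude-weighted mean of
the smoothed series over valid frames, computed per channel (an aggregated
variant across a joint's axes is available in the event readout, where
frequency aggregates by amplitude-weighted mean and amplitude by
root-sum-square — the one-number-per-joint convention used in event tables).

## Channel assembly

BVH files declare rotation channels in arbitrary per-joint order (often
Z X Y); the parser preserves file order for round-tripping, and the analysis
matrix reorders to a canonical layout — root position X, Y, Z, then each
joint's rotations as θx, θy, θz in hierarchy order — so column meaning never
depends on file idiosyncrasies. Rotation channels are unwrapped by default
(±180°/360° jumps removed): a wrap discontinuity would otherwise manufacture
spurious envelope extrema. End Site nodes are kept in the skeleton but carry
no channels. A fully 3-DOF skeleton with J rotating joints yields 3 + 3·J
analysis channels; 43 joints give 132.

## Readouts

- **Event tables**: WAFA-smoothed frequency and instantaneous amplitude per
  mode at a user-supplied event time (no automatic event detection), nearest
  valid frame used and flagged if the event falls on a masked frame.
- **Cross-joint correlations**: Pearson R between two joints' per-mode
  frequency tracks and amplitude tracks over jointly valid frames; constant
  tracks report NaN.
- **Per-mode RMS**: per-frame root mean square of a component over a joint's
  rotation axes, reported mean ± std across frames. No reference signal is
  subtracted — the statistic measures how much motion each mode carries, so
  a tone of amplitude a yields ≈ a/√2.

All readouts operate on a saved decomposition archive (one .npz holding
modes, trend, labels and the config snapshot) and never re-run EMD.

## Synthetic data

The fixture generator emulates the structure the decomposition targets: a
few AM/FM tone components with per-channel random phases (phases differ
across channels precisely to exercise MEMD's mode alignment), a polynomial
posture trend, and optional Gaussian noise. Defaults: 120 Hz sampling, 4 s
duration, tone frequencies separated by a factor ≥ 3 and below fs/4
(two-tone preset: 10 Hz at 5° and 2 Hz at 10°, linear 2°/s trend), noise
expressed relative to the smallest component amplitude. What it does *not*
emulate: kinematic coupling between joints, ground-contact discontinuities,
marker noise spectra, or mode mixing between closely spaced frequencies —
so passing tests demonstrate correct mechanics of the decomposition and
spectral chain, not robustness to every pathology of real recordings.
Real-data behaviour such as mode mixing (one mode carrying disparate
frequency content) remains possible and is not mitigated here.

## Numerical choices and limitations

- Natural spline boundary conditions; mirror extension of two edge extrema.
- Completeness is guaranteed structurally (modes are subtracted from the
  running signal), so reconstruction error is at float rounding (~1e−16
  relative) regardless of decomposition quality.
- The residual-sign bookkeeping follows the completeness identity
  x = Σcᵢ + r; the running residual is updated r ← r − c after each mode.
- Amplitude floor 1e−12 below which phase (hence frequency) is masked
  rather than computed.
- BVH output precision defaults to 6 decimals; the frame interval is
  written with shortest round-trip formatting so the sampling rate (and the
  fs/4 cap) survives write/read exactly.
- Test and acceptance problem sizes — 480-frame, 12-channel fixtures with
  V = 64 directions — were chosen as the smallest sizes that exercise ≥ 2
  well-separated modes across multiple joints; a full 132-channel
  decomposition runs the same code path and is covered by a short
  channel-accounting case.
- EMD has no convergence theory; the number of modes is data- and
  threshold-dependent (the two-tone fixture yields 2–3 modes depending on
  phase draws). Downstream code therefore never assumes a fixed mode count.
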