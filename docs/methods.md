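# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Signal model and geometry

Images live on square `N×N` grids with pixel indices centred on `N//2`;
k-space coordinates are in cycles/pixel with `|k| ≤ 0.5`. A radial spoke is
a full diameter: `points_per_spoke` samples span `[-0.5, +0.5)`
endpoint-exclusive, so an even count places one sample exactly at DC. The
spoke angle starts at 0° along +x and advances counter-clockwise by
`180°/GR` (GA) or `180°/(GR·NSli)` (SMS-GA), `GR = (1+√5)/2`. Spokes that
do not fill a complete frame are discarded so every frame has the same
duration.

CAIPIRINHA phases are `phase[n, i] = mod(2π·i·n/NSli, 2π)` with slice 0 as
the zero-phase reference; only inter-slice phase differences are physical,
and any global phase is absorbed by the coil maps. Over one period the
factors form a discrete Fourier basis across slices — the identity behind
both slice separation and the motion-averaged demodulation used for
calibration.

The acquisition model is steady-state complex magnetization weighted by
coil sensitivity: no relaxation, flip-angle, or off-resonance simulation,
i.i.d. circular complex Gaussian noise (no coil covariance), and all
spokes within a frame see one phantom state (no intra-frame motion blur).
Sequence timing (TR 2.5 ms, 128 points/spoke, 280 mm FOV) is carried as
metadata and fixes derived constants such as the 2.2 mm nominal pixel and
the 62.5/37.5/25 ms frame durations.

## NUFFT

The non-uniform transform is Kaiser–Bessel gridding on a 2× oversampled
FFT grid: deapodization, zero-padded centred FFT, and a sparse
interpolation matrix of separable kernel weights (width chosen from the
requested tolerance; width 8 at the default 1e-6, Beatty's β). The adjoint
applies the exact conjugate transpose of the same three steps, so
forward/adjoint pairs pass dot-product tests at machine level and both
directions agree with the brute-force Fourier sum to ~1e-7 relative on
test grids. Neither direction carries a `1/N²` factor; all normalization is
explicit at the call sites. Density compensation uses ramp (`|k_r|`)
weights with the DC sample given half the first ring's weight, normalized
to mean 1; where a quantitatively scaled gridding inverse is needed the
weights are rescaled by the sampled k-space area.

## Calibration-less sensitivity estimation

Following the compression-first pipeline order: (1) PCA coil compression —
SVD of the coil-by-sample matrix over the *entire* spoke series, no mean
centring (MR k-space is DC-dominated; centring would distort it); (2)
conjugate-phase demodulation per slice; (3) density-compensated adjoint
NUFFT of all spokes at once, which time-averages motion while the other
slices' contributions destructively interfere; (4) FFT to Cartesian
k-space, central 24×24 calibration block, ESPIRiT. ESPIRiT hyperparameters
default to kernel 6×6, singular-value threshold 0.01·σmax, eigenvalue
threshold 0.85, single map set; the pixelwise operator is scaled by `1/k²`
so its top eigenvalue is ≤ 1, and the per-pixel phase is fixed by rotating
coil 0 real-positive. Maps are zeroed where the eigenvalue falls below
threshold. On the desk fixture the estimated maps agree with ground truth
to better than 0.99 masked correlation (noiseless) and <0.06 normalized
error at the default noise level.

## Reconstruction

ADMM on the splitting `z = Tx`: warm-started inner CG for the x-update,
complex magnitude soft-thresholding `λ/ρ` for z, and residual balancing of
ρ (×/÷ τ=2 when one residual exceeds µ=10 times the other). Defaults:
50 outer iterations, 10 inner CG, ρ₀ = 0.1, stop at relative primal
residual < 1e-5; non-convergence returns the best iterate with a warning
flag and the full objective/residual trace.

Two normalization choices matter and are deliberate:

* **Operator scaling.** The encoding operator is scaled to unit spectral
  norm (power iteration, 12 steps, seeded). Without this, `ρ TᴴT` is
  negligible against `AᴴA` (norm ~10⁴ on desk fixtures), the inner systems
  are effectively unregularized and ill-conditioned, and λ loses meaning.
* **Data scaling.** y is scaled so the *data-consistent* density-compensated
  adjoint image has unit peak: the DCF image is first rescaled by the
  least-squares scalar `⟨A x_dc, y⟩/‖A x_dc‖²` to remove the gridding gain,
  then normalized to unit peak. λ = 4×10⁻² is therefore an
  intensity-relative weight that transfers across grid sizes, coil counts,
  and spoke counts. The scaling is undone on output.

With λ = 0 the ℓ1 term vanishes and the problem is plain least squares;
the splitting then converges extremely slowly (the x-update's fixed-point
contraction degrades as ρTᴴT dominates the small data-term eigenvalues),
so the solver bypasses it and runs warm-started CG on the data normal
equations — mathematically the same minimizer, reached directly.

ADMM is not a descent method; with inexact inner solves the objective
shows a ±3e-6 even/odd two-cycle near the plateau. With accurate inner
solves the trace is monotone after the first few iterations, which is how
the descent property test is run.

CG-SENSE solves the unregularized normal equations per frame (frames are
independent without the temporal term), 15 iterations by default. The
temporal median filter (default width 3) acts on magnitude with the centre
frame's phase reattached; edge frames use shrunken windows.

## Synthetic study conditions

The desk-scale fixture is a 64×64 grid, 3 slices, 8 coils, 40 frames of
25 spokes (128 points each), chosen so a full reconstruction runs in
minutes on one CPU. The phantom has a static head ellipse whose size,
orientation, intensity, marker constellation, and smooth random texture
differ per slice — deliberately, so that leakage of one slice into another
is measurable as a correlation margin — plus a brighter tongue ellipse
translating sinusoidally (default amplitude 6 px, period 20 frames,
roughly a 1–2 s protrusion/retraction at the modelled frame rate). Coil
maps are Gaussian lobes on a ring around the FOV with small linear phases,
hard low-passed to 1/8 of the grid bandwidth. Noise is specified as a
fraction of the RMS k-space sample magnitude; the default 0.05 produces
~3% image-domain noise relative to peak signal (image SNR ≈ 30, a
plausible 3 T FLASH level). Smaller grids (48, 4–6 coils, 64-point
readouts) are used where many reconstructions are compared (λ search,
spokes-per-frame sweep, GA vs SMS-GA), and iteration counts are reduced
there (15–30 outer) since the compared quantities stabilize well before
full convergence.

What passing these tests shows: the operators are exact, slice separation
works as the phase algebra predicts, the calibration-less map pipeline
recovers smooth sensitivities, and the solver recovers distinct moving
slices with quantified leakage. What they do not show: behaviour under
off-resonance, trajectory errors, coil coupling, through-plane motion, or
in vivo contrast — none of which the simulator models.

## Known limitations

* The simulator's noise is white across coils; correlated coil noise is
  future work.
* Ramp density compensation is approximate near DC; it is used only for
  calibration and normalization, never inside the iterative data term.
* The spokes-per-frame sweep simulates each frame length with the phantom
  stepped at that frame rate (motion period fixed in milliseconds), so the
  comparison isolates per-frame undersampling; intra-frame motion blur is
  outside the signal model and therefore not part of the comparison. The
  sweep is scored with the frame-independent CG-SENSE baseline: for the
  temporally regularized solver the error is governed largely by the
  *total* spoke count, not spokes/frame — at matched total spokes, many
  short frames reconstruct as well as or better than few long ones, which
  is precisely the temporal redundancy the regularization exploits — so
  the unregularized recon is the one whose error isolates the per-frame
  sampling density that the sweep varies.
* Median filtering on magnitude discards temporal phase consistency;
  displayed videos are magnitude, so this is cosmetic only.
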